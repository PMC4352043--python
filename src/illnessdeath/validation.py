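"""Validation experiments: PDE residual on survey data, incidence reconstruction.

Two checks separate discretization error from sampling error:

* the *difference surface* D compares the estimated cohort derivative of
  prevalence (central difference quotient over repeated cross-sections)
  against the PDE right-hand side built from person-year rate estimates —
  on noise-free analytic inputs D vanishes to finite-difference order, and
  on simulated survey data it scatters around zero;

* *incidence reconstruction* inverts the PDE for i (with r = 0 and known
  mortality) from two cross-sections of a simulated register and compares
  the result with the incidence that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lexis import (
    Cohort,
    cohort_difference_quotient,
    cross_sectional_prevalence,
    one_sided_pair_quotient,
    person_years_rates,
    prevalence_surface_from_surveys,
)
from .model import invert_incidence, pde_rhs
from .surfaces import PrevalenceSurface, RateSurface

__all__ = [
    "DifferenceSurface",
    "ReconstructionReport",
    "compute_difference_surface",
    "difference_surface_analytic",
    "summarize_difference",
    "stratify_difference_by_age",
    "reconstruct_incidence",
    "reconstruct_incidence_from_slices",
]


@dataclass
class DifferenceSurface:
    """Residual D = (difference quotient of p) - (PDE right-hand side) per node.

    Nodes where any required quantity is not estimable (zero person-years for
    a rate, or an empty age bin in a needed survey) carry NaN and are flagged
    invalid; summaries pool the valid nodes only.
    """

    t_values: np.ndarray
    a_values: np.ndarray
    D: np.ndarray  # shape (len(t_values), len(a_values)), NaN where invalid
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def valid_values(self) -> np.ndarray:
        return self.D[self.valid]

    def to_dataframe(self) -> pd.DataFrame:
        tt, aa = np.meshgrid(self.t_values, self.a_values, indexing="ij")
        return pd.DataFrame(
            {"t": tt.ravel(), "a": aa.ravel(), "D": self.D.ravel(), "valid": self.valid.ravel()}
        )


@dataclass
class ReconstructionReport:
    """Reconstructed vs true incidence by age, with error summaries."""

    ages: np.ndarray
    i_true: np.ndarray
    i_hat: np.ndarray  # NaN at singular/unestimable ages
    t_mid: float
    age_range: tuple[float, float]

    @property
    def abs_error(self) -> np.ndarray:
        return np.abs(self.i_hat - self.i_true)

    def _in_range(self) -> np.ndarray:
        lo, hi = self.age_range
        sel = (self.ages >= lo) & (self.ages <= hi) & np.isfinite(self.i_hat)
        return sel

    @property
    def max_abs_error(self) -> float:
        sel = self._in_range()
        if not sel.any():
            return float("nan")
        return float(np.max(self.abs_error[sel]))

    @property
    def median_abs_error(self) -> float:
        sel = self._in_range()
        if not sel.any():
            return float("nan")
        return float(np.median(self.abs_error[sel]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "i_true": self.i_true,
                "i_hat": self.i_hat,
                "abs_error": self.abs_error,
            }
        )


def compute_difference_surface(
    cohort: Cohort,
    t_range: tuple[int, int] = (95, 135),
    a_range: tuple[int, int] = (5, 85),
    h: float = 1.0,
    min_person_years: float = 0.5,
) -> DifferenceSurface:
    """PDE residual from survey estimates of a closed, irreversible-state cohort.

    Per node (t*, a*): prevalence from cross-sections, its cohort derivative
    by the central quotient with step ``h``, the rates i, m_A, m_B by the
    person-year method on the corner-anchored 1-year Lexis square
    ``[t*, t*+1) x [a*, a*+1)``, and

        D = difference quotient - pde_rhs(p, i, r=0, m_A, m_B).

    A rate entering a node must rest on at least ``min_person_years`` of
    exposure in its square (default 0.5); below that a single event yields
    an arbitrarily large rate that says nothing about the hazard, so the
    node is flagged invalid rather than poisoning the pooled summaries.
    """
    t0, t1 = int(t_range[0]), int(t_range[1])
    a0, a1 = int(a_range[0]), int(a_range[1])
    hh = int(round(h))
    if hh != h or hh < 1:
        raise ValueError("h must be a positive integer number of survey years")

    surveys = np.arange(t0 - hh, t1 + hh + 1)
    bins = np.arange(max(a0 - hh, 0), a1 + hh + 1)
    psurf = prevalence_surface_from_surveys(cohort, surveys, bins)

    window = (t0, t1 + 1, a0, a1 + 1)
    tab_i = person_years_rates(cohort, window, "incidence")
    tab_mA = person_years_rates(cohort, window, "mortality_A")
    tab_mB = person_years_rates(cohort, window, "mortality_B")

    t_vals = np.arange(t0, t1 + 1)
    a_vals = np.arange(a0, a1 + 1)
    D = np.full((t_vals.size, a_vals.size), np.nan)
    valid = np.zeros_like(D, dtype=bool)

    it0 = int(t0 - surveys[0])
    ia0 = int(a0 - bins[0])
    p_grid = psurf.p
    rate_i = np.where(tab_i.person_years >= min_person_years, tab_i.rate, np.nan)
    rate_mA = np.where(tab_mA.person_years >= min_person_years, tab_mA.rate, np.nan)
    rate_mB = np.where(tab_mB.person_years >= min_person_years, tab_mB.rate, np.nan)

    for kt in range(t_vals.size):
        for ka in range(a_vals.size):
            p_c = p_grid[it0 + kt, ia0 + ka]
            p_p = p_grid[it0 + kt + hh, ia0 + ka + hh]
            p_m = p_grid[it0 + kt - hh, ia0 + ka - hh]
            i_ = rate_i[kt, ka]
            mA_ = rate_mA[kt, ka]
            mB_ = rate_mB[kt, ka]
            if any(not np.isfinite(v) for v in (p_c, p_p, p_m, i_, mA_)):
                continue
            if p_c == 0.0:
                # the p*(mB - mA) term vanishes; an unestimable mB (no
                # state-B exposure in the square) does not invalidate the node
                mB_ = mA_
            elif not np.isfinite(mB_):
                continue
            dq = (p_p - p_m) / (2.0 * hh)
            D[kt, ka] = dq - pde_rhs(p_c, i_, 0.0, mA_, mB_)
            valid[kt, ka] = True

    return DifferenceSurface(t_values=t_vals.astype(float), a_values=a_vals.astype(float), D=D, valid=valid)


def difference_surface_analytic(
    p: PrevalenceSurface,
    i: RateSurface,
    mA: RateSurface,
    mB: RateSurface,
    h: float = 1.0,
) -> DifferenceSurface:
    """PDE residual with exact rates and a given prevalence surface.

    Bypasses estimation entirely: the difference quotient is taken on ``p``
    and the right-hand side uses the supplied rate surfaces at each node.
    Isolates the finite-difference error (O(h^2) for smooth surfaces) from
    sampling error.  Nodes within ``h`` of the surface edge are invalid.
    """
    t_vals = p.t_grid
    a_vals = p.a_grid
    D = np.full((t_vals.size, a_vals.size), np.nan)
    valid = np.zeros_like(D, dtype=bool)
    for kt, t in enumerate(t_vals):
        for ka, a in enumerate(a_vals):
            try:
                dq = cohort_difference_quotient(p, t, a, h)
            except KeyError:
                continue
            p_c = p.p[kt, ka]
            if not np.isfinite(p_c):
                continue
            D[kt, ka] = dq - pde_rhs(p_c, i(t, a), 0.0, mA(t, a), mB(t, a))
            valid[kt, ka] = True
    return DifferenceSurface(t_values=t_vals, a_values=a_vals, D=D, valid=valid)


def summarize_difference(D: DifferenceSurface) -> dict[str, float]:
    """Seven pooled order/moment statistics of the valid residuals.

    Returns min, first quartile, median, mean, third quartile, max and the
    sample standard deviation (ddof=1), pooling all valid nodes equally.
    """
    vals = D.valid_values()
    if vals.size == 0:
        raise ValueError("difference surface has no valid nodes")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "min": float(np.min(vals)),
        "q1": float(q1),
        "median": float(med),
        "mean": float(np.mean(vals)),
        "q3": float(q3),
        "max": float(np.max(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
    }


def stratify_difference_by_age(D: DifferenceSurface) -> pd.DataFrame:
    """Mean and SD of the residual per age stratum (pooled over survey years)."""
    rows = []
    for ka, a in enumerate(D.a_values):
        vals = D.D[:, ka][D.valid[:, ka]]
        if vals.size == 0:
            rows.append({"age": a, "mean": np.nan, "sd": np.nan, "n_valid": 0})
            continue
        rows.append(
            {
                "age": float(a),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                "n_valid": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def reconstruct_incidence(
    cohort: Cohort,
    t1: float,
    t2: float,
    mA: RateSurface,
    mB: RateSurface,
    ages,
    age_range: tuple[float, float] = (60.0, 90.0),
    i_true: RateSurface | None = None,
) -> ReconstructionReport:
    """Reconstruct the incidence of an irreversible state from two cross-sections.

    Prevalence slices at ``t1`` and ``t2`` give the cohort derivative at the
    midpoint year by the one-sided pair quotient; the PDE solved for i with
    r = 0 and the known mortality surfaces then yields, per age a,

        i_hat(a) = dp/(1 - p_bar) + p_bar * (m_B - m_A)(t_mid, a)

    with midpoint prevalence ``p_bar`` (mean of the two matched cohort
    observations).  Ages whose bins are empty or where ``p_bar`` is
    numerically 1 are flagged NaN and excluded from the error summaries.

    Survey prevalence lives on 1-year age bins; an observation in bin
    [j, j+1) represents the bin's midpoint age j + 0.5, so pass half-integer
    ``ages`` (e.g. 60.5, 61.5, ...) to line the quotient up exactly with the
    matched birth cohort in both surveys.
    """
    if t2 <= t1:
        raise ValueError("t2 must be later than t1")
    ages = np.asarray(ages, dtype=float)
    h = (t2 - t1) / 2.0
    t_mid = (t1 + t2) / 2.0

    lo_bins = np.unique(np.floor(ages - h).astype(int))
    hi_bins = np.unique(np.floor(ages + h).astype(int))
    early = cross_sectional_prevalence(cohort, t1, lo_bins)
    late = cross_sectional_prevalence(cohort, t2, hi_bins)

    i_hat = np.full(ages.size, np.nan)
    for k, a in enumerate(ages):
        try:
            p_e = early.at_age(np.floor(a - h))
            p_l = late.at_age(np.floor(a + h))
        except KeyError:
            continue
        if not (np.isfinite(p_e) and np.isfinite(p_l)):
            continue
        dp = (p_l - p_e) / (2.0 * h)
        p_bar = 0.5 * (p_e + p_l)
        if p_bar > 1.0 - 1e-9:
            continue  # singular cell, excluded
        i_hat[k] = dp / (1.0 - p_bar) + p_bar * (mB(t_mid, a) - mA(t_mid, a))

    if i_true is not None:
        true_vals = np.asarray(i_true(np.full(ages.size, t_mid), ages), dtype=float)
    else:
        true_vals = np.full(ages.size, np.nan)
    return ReconstructionReport(
        ages=ages, i_true=true_vals, i_hat=i_hat, t_mid=t_mid, age_range=age_range
    )


def reconstruct_incidence_from_slices(
    early,
    late,
    mA: RateSurface,
    mB: RateSurface,
    ages,
    age_range: tuple[float, float] = (60.0, 90.0),
    i_true: RateSurface | None = None,
) -> ReconstructionReport:
    """Incidence inversion from two prevalence slices with exact age nodes.

    The analytic counterpart of :func:`reconstruct_incidence`: the slices
    (typically forward-solved, noise-free prevalences) must carry nodes at
    ``ages - h`` (early) and ``ages + h`` (late) exactly, where
    ``h = (late.t - early.t)/2``.  Used to isolate the O(h^2)
    finite-difference error of the inversion.
    """
    if late.t <= early.t:
        raise ValueError("late must be the later survey")
    ages = np.asarray(ages, dtype=float)
    h = (late.t - early.t) / 2.0
    t_mid = (early.t + late.t) / 2.0
    i_hat = np.full(ages.size, np.nan)
    for k, a in enumerate(ages):
        dp = one_sided_pair_quotient(early, late, a)
        p_bar = 0.5 * (early.at_age(a - h) + late.at_age(a + h))
        if not np.isfinite(p_bar) or p_bar > 1.0 - 1e-9:
            continue
        i_hat[k] = invert_incidence(dp, p_bar, 0.0, mA(t_mid, a), mB(t_mid, a))
    if i_true is not None:
        true_vals = np.asarray(i_true(np.full(ages.size, t_mid), ages), dtype=float)
    else:
        true_vals = np.full(ages.size, np.nan)
    return ReconstructionReport(
        ages=ages, i_true=true_vals, i_hat=i_hat, t_mid=t_mid, age_range=age_range
    )
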