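"""Rate and prevalence estimation from person-level event data on the Lexis plane.

A person's life is a 45-degree segment on the (calendar time, age) plane from
(birth, 0) to (birth + death_age, death_age).  Rates are estimated by the
person-year method per time x age square of edge length one year: events in
the square divided by the time at risk accumulated inside it.  Lifelines are
half-open ``[birth, death)`` and squares are half-open
``[k, k+1) x [j, j+1)``, so every event lands in exactly one square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .surfaces import PrevalenceSlice, PrevalenceSurface

__all__ = [
    "Cohort",
    "LexisRateTable",
    "person_years_rates",
    "rate_standard_error",
    "cross_sectional_prevalence",
    "prevalence_surface_from_surveys",
    "cohort_difference_quotient",
    "one_sided_pair_quotient",
    "TRANSITIONS",
]

TRANSITIONS = ("incidence", "mortality_A", "mortality_B", "mortality_all")

COHORT_COLUMNS = ["birth_time", "diagnosis_age", "death_age"]


@dataclass
class Cohort:
    """A closed, fully observed population of person records.

    ``data`` holds one row per person with columns ``birth_time`` (calendar
    years), ``diagnosis_age`` (years, NaN if the person never enters state B)
    and ``death_age`` (years).  The population is closed: no migration, no
    loss to follow-up, every death age observed.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns {missing}")
        d = self.data
        if len(d) and (d["death_age"] <= 0).any():
            raise ValueError("death_age must be positive")
        diag = d["diagnosis_age"]
        bad = diag.notna() & ((diag < 0) | (diag > d["death_age"]))
        if bad.any():
            raise ValueError("diagnosis_age must lie in [0, death_age]")

    def __len__(self) -> int:
        return len(self.data)

    # -- CSV interface: "birth_time,diagnosis_age,death_age", empty = missing
    def to_csv(self, path) -> None:
        self.data[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "Cohort":
        df = pd.read_csv(path, usecols=COHORT_COLUMNS)
        return cls(df[COHORT_COLUMNS], meta=meta or {"source": str(Path(path))})


@dataclass
class LexisRateTable:
    """Per-square event counts, person-years, rates and standard errors.

    Square (k, j) covers ``[t_edges[k], t_edges[k]+1) x [a_edges[j], a_edges[j]+1)``.
    ``rate`` and ``se`` are NaN where person-years are zero (flagged
    undefined, never infinite).
    """

    t_edges: np.ndarray  # integer left edges, ascending
    a_edges: np.ndarray
    events: np.ndarray  # shape (len(t_edges), len(a_edges))
    person_years: np.ndarray
    transition: str = "incidence"

    def __post_init__(self):
        self.t_edges = np.asarray(self.t_edges)
        self.a_edges = np.asarray(self.a_edges)
        self.events = np.asarray(self.events, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.person_years > 0, self.events / self.person_years, np.nan)
        return r

    @property
    def se(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(self.person_years > 0, np.sqrt(self.events) / self.person_years, np.nan)
        return s

    def to_dataframe(self) -> pd.DataFrame:
        tt, aa = np.meshgrid(self.t_edges, self.a_edges, indexing="ij")
        return pd.DataFrame(
            {
                "t": tt.ravel(),
                "a": aa.ravel(),
                "events": self.events.ravel(),
                "person_years": self.person_years.ravel(),
                "rate": self.rate.ravel(),
                "se": self.se.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def rate_standard_error(events: float, person_years: float) -> float:
    """Poisson-count standard error of a person-year rate: sqrt(events)/PY.

    Undefined (NaN) when person-years are zero; zero-event squares get SE 0
    (no continuity correction).
    """
    if person_years <= 0:
        return float("nan")
    return float(np.sqrt(events) / person_years)


def _risk_interval(cohort: Cohort, transition: str):
    """Per-person at-risk age interval [a_in, a_out) and event age (NaN = none)."""
    d = cohort.data
    birth = d["birth_time"].to_numpy(dtype=float)
    death = d["death_age"].to_numpy(dtype=float)
    diag = d["diagnosis_age"].to_numpy(dtype=float)  # NaN where absent
    has_diag = ~np.isnan(diag)
    exit_A = np.where(has_diag, diag, death)

    if transition == "incidence":
        a_in, a_out = np.zeros_like(death), exit_A
        event_age = np.where(has_diag, diag, np.nan)
    elif transition == "mortality_A":
        a_in, a_out = np.zeros_like(death), exit_A
        event_age = np.where(has_diag, np.nan, death)
    elif transition == "mortality_B":
        a_in, a_out = diag.copy(), death
        a_in[~has_diag] = np.nan  # never at risk
        event_age = np.where(has_diag, death, np.nan)
    elif transition == "mortality_all":
        a_in, a_out = np.zeros_like(death), death
        event_age = death.copy()
    else:
        raise ValueError(f"unknown transition {transition!r}; one of {TRANSITIONS}")
    return birth, a_in, a_out, event_age


def person_years_rates(cohort: Cohort, window, transition: str) -> LexisRateTable:
    """Person-year rates per 1-year Lexis square inside ``window``.

    ``window = (t_min, t_max, a_min, a_max)`` with integer edges; squares are
    ``[k, k+1) x [j, j+1)`` for ``k in [t_min, t_max)``, ``j in [a_min, a_max)``.
    Time at risk is the exact length (in years of age = years of time) of each
    lifeline's 45-degree segment inside the square, restricted to the at-risk
    state for ``transition``; events are the transitions occurring inside.
    """
    if len(cohort) == 0:
        raise ValueError("cannot estimate rates from an empty cohort")
    t_min, t_max, a_min, a_max = window
    for v in window:
        if float(v) != int(v):
            raise ValueError("window edges must be aligned to integer years")
    t_min, t_max, a_min, a_max = (int(v) for v in window)
    if t_max <= t_min or a_max <= a_min:
        raise ValueError("window must be nonempty")

    t_edges = np.arange(t_min, t_max)
    a_edges = np.arange(a_min, a_max)
    nT, nA = t_edges.size, a_edges.size
    events = np.zeros((nT, nA))
    py = np.zeros((nT, nA))

    birth, a_in, a_out, event_age = _risk_interval(cohort, transition)
    at_risk = ~np.isnan(a_in)
    birth_r = birth[at_risk]
    in_r = a_in[at_risk]
    out_r = a_out[at_risk]

    # events: one scatter over the whole cohort
    has_ev = ~np.isnan(event_age)
    if has_ev.any():
        ev_a = event_age[has_ev]
        ev_t = birth[has_ev] + ev_a
        kk = np.floor(ev_t).astype(int) - t_min
        jj = np.floor(ev_a).astype(int) - a_min
        ok = (kk >= 0) & (kk < nT) & (jj >= 0) & (jj < nA)
        np.add.at(events, (kk[ok], jj[ok]), 1.0)

    # person-years: per time column k, each lifeline contributes an age
    # interval of length <= 1 that spans at most one integer age boundary
    for k in t_edges:
        lo = np.maximum(k - birth_r, in_r)
        hi = np.minimum(k + 1 - birth_r, out_r)
        sel = hi > lo
        if not sel.any():
            continue
        lo_s, hi_s = lo[sel], hi[sel]
        j0 = np.floor(lo_s).astype(int)
        split = np.minimum(hi_s, j0 + 1.0)
        col = np.zeros(nA)
        j0i = j0 - a_min
        ok0 = (j0i >= 0) & (j0i < nA)
        np.add.at(col, j0i[ok0], (split - lo_s)[ok0])
        rem = hi_s - split
        has_rem = rem > 0
        j1i = j0i[has_rem] + 1
        ok1 = (j1i >= 0) & (j1i < nA)
        np.add.at(col, j1i[ok1], rem[has_rem][ok1])
        py[k - t_min] += col

    return LexisRateTable(t_edges, a_edges, events, py, transition=transition)


def cross_sectional_prevalence(cohort: Cohort, t_survey: float, age_bins) -> PrevalenceSlice:
    """Mimic a cross-sectional survey at calendar time ``t_survey``.

    ``age_bins`` are integer left edges; bin a* covers exact ages
    ``[a*, a*+1)``.  A person is alive at the survey iff
    ``birth <= t_survey < birth + death_age`` (half-open lifeline: death at
    the survey instant counts as dead); they are in state B iff
    ``diagnosis_age <= age at survey`` (diagnosis at the instant counts).
    Bins with nobody alive carry NaN prevalence.
    """
    d = cohort.data
    birth = d["birth_time"].to_numpy(dtype=float)
    death = d["death_age"].to_numpy(dtype=float)
    diag = d["diagnosis_age"].to_numpy(dtype=float)
    if len(d) == 0 or t_survey < birth.min() or t_survey >= (birth + death).max():
        raise ValueError(f"survey time {t_survey} outside the data span")

    age_bins = np.asarray(age_bins, dtype=int)
    age = t_survey - birth
    alive = (birth <= t_survey) & (t_survey < birth + death)
    j = np.floor(age).astype(int)
    in_b = np.zeros_like(alive)
    in_b[alive] = ~np.isnan(diag[alive]) & (diag[alive] <= age[alive])

    lo, hi = age_bins.min(), age_bins.max()
    sel = alive & (j >= lo) & (j <= hi)
    n_alive = np.bincount(j[sel] - lo, minlength=hi - lo + 1)
    n_B = np.bincount(j[sel & in_b] - lo, minlength=hi - lo + 1)
    n_alive = n_alive[age_bins - lo]
    n_B = n_B[age_bins - lo]
    with np.errstate(invalid="ignore"):
        p = np.where(n_alive > 0, n_B / np.maximum(n_alive, 1), np.nan)
    return PrevalenceSlice(
        t=float(t_survey), ages=age_bins.astype(float), p=p,
        n_alive=n_alive.astype(float), n_state_B=n_B.astype(float),
    )


def prevalence_surface_from_surveys(cohort: Cohort, survey_times, age_bins) -> PrevalenceSurface:
    """Stack repeated cross-sections into a gridded prevalence surface."""
    survey_times = np.asarray(survey_times, dtype=float)
    age_bins = np.asarray(age_bins, dtype=int)
    p = np.full((survey_times.size, age_bins.size), np.nan)
    n_alive = np.zeros_like(p)
    n_B = np.zeros_like(p)
    for k, t in enumerate(survey_times):
        sl = cross_sectional_prevalence(cohort, t, age_bins)
        p[k] = sl.p
        n_alive[k] = sl.n_alive
        n_B[k] = sl.n_state_B
    return PrevalenceSurface(
        t_grid=survey_times, a_grid=age_bins.astype(float), p=p,
        n_alive=n_alive, n_state_B=n_B,
    )


def cohort_difference_quotient(p: PrevalenceSurface, t: float, a: float, h: float = 1.0) -> float:
    """Central difference quotient of prevalence along the cohort line.

    ``[p(t+h, a+h) - p(t-h, a-h)] / (2h)`` — the second-order approximation
    of the directional derivative (d/dt + d/da) p; exact for surfaces affine
    in (t + a).  Raises KeyError naming any missing node.
    """
    p_plus = p.at(t + h, a + h)
    p_minus = p.at(t - h, a - h)
    return (p_plus - p_minus) / (2.0 * h)


def one_sided_pair_quotient(p_early: PrevalenceSlice, p_late: PrevalenceSlice, a_mid: float) -> float:
    """Cohort derivative at the midpoint of two surveys.

    With surveys at t1 < t2 and ``h = (t2 - t1)/2``, returns
    ``[p_late(a_mid + h) - p_early(a_mid - h)] / (2h)``, centred at
    ``((t1+t2)/2, a_mid)`` on the cohort line through both observations.
    """
    if p_late.t <= p_early.t:
        raise ValueError("p_late must be the later survey")
    h = (p_late.t - p_early.t) / 2.0
    return (p_late.at_age(a_mid + h) - p_early.at_age(a_mid - h)) / (2.0 * h)
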