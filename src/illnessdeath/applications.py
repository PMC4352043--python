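"""Applied scenario pipelines built on the prevalence PDE.

Two reusable analyses:

* a **smoking scenario** — forward-modelling the age-specific prevalence of
  a habit from an initiation rate i, a cessation rate r, the general
  mortality m and an age-dependent relative mortality R = m_B/m_A, using the
  general-mortality form of the PDE along birth cohorts;

* a **sign-split attribution** for repeated cross-sectional surveys of a
  dichotomous trait (DHS-style, ages 15-49): a birth cohort's prevalence
  increase between two surveys is attributed entirely to the acquisition
  ("learning") rate i and a decrease entirely to the loss ("forgetting")
  rate r, assuming equal mortality in both states.  The rule is the exact
  inversion of the PDE under the constraint that only one of i, r is active
  on each cohort step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import pde_rhs_relative
from .surfaces import PrevalenceSlice, RateSurface

__all__ = [
    "SmokingScenario",
    "SurveyPrevalenceSeries",
    "AttributionTable",
    "relative_hazard_profile",
    "run_smoking_scenario",
    "dhs_attribution",
    "generate_synthetic_surveys",
]

#: default relative-hazard breakpoints: equal mortality below 40, ratio 2.5
#: at 60, declining to 1.5 at 80 and constant beyond (affine in between)
DEFAULT_RELATIVE_HAZARD = ((0.0, 1.0), (40.0, 1.0), (60.0, 2.5), (80.0, 1.5))


def relative_hazard_profile(a, spec=DEFAULT_RELATIVE_HAZARD):
    """Piecewise-affine relative mortality R(a) = m_B/m_A of the exposed.

    ``spec`` is a sequence of (age, ratio) knots; values between knots are
    affine-linear, values beyond the last knot are held constant.
    """
    a = np.asarray(a, dtype=float)
    knots = np.asarray([k[0] for k in spec])
    vals = np.asarray([k[1] for k in spec])
    out = np.interp(a, knots, vals)  # np.interp clamps outside the knot range
    return float(out) if out.ndim == 0 else out


def _default_initiation(a):
    """Initiation: steep logistic rise over ages 12-16, exponential decay after."""
    a = np.asarray(a, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(a - 14.0) / 0.8))
    decay = np.exp(-np.maximum(a - 16.0, 0.0) / 18.0)
    return 0.075 * rise * decay


def _default_cessation(a):
    """Cessation: zero below 18, bumps at 20 (post-teen quitting) and 60 (health advice)."""
    a = np.asarray(a, dtype=float)
    bump1 = 0.02 * np.exp(-0.5 * ((a - 20.0) / 2.5) ** 2)
    bump2 = 0.06 * np.exp(-0.5 * ((a - 60.0) / 10.0) ** 2)
    return np.where(a < 18.0, 0.0, bump1 + bump2)


@dataclass
class SmokingScenario:
    """Forward-model configuration for a smoked-prevalence projection.

    ``initiation`` and ``cessation`` are age profiles at ``t_ref``; the
    initiation rate carries a multiplicative secular trend
    ``(1 - secular_decline)`` per calendar year.  ``mortality`` is the
    general (all-state) mortality and ``relative_hazard_spec`` the R(a)
    knots.  The default rate shapes are parametric stand-ins chosen for
    qualitative plausibility, not fitted to any survey.
    """

    initiation: RateSurface = field(
        default_factory=lambda: RateSurface.from_age_function(_default_initiation, name="initiation")
    )
    cessation: RateSurface = field(
        default_factory=lambda: RateSurface.from_age_function(_default_cessation, name="cessation")
    )
    mortality: RateSurface = field(
        default_factory=lambda: RateSurface.from_age_function(
            lambda a: 2e-4 * np.exp(0.085 * np.asarray(a, float)), name="general_mortality"
        )
    )
    relative_hazard_spec: tuple = DEFAULT_RELATIVE_HAZARD
    secular_decline: float = 0.005  # initiation shrinks by 0.5% per calendar year
    t_ref: float = 1920.0

    def initiation_at(self, t, a):
        factor = (1.0 - self.secular_decline) ** (np.asarray(t, float) - self.t_ref)
        return self.initiation.func(t, a) * factor


def run_smoking_scenario(
    s: SmokingScenario,
    target_year: float,
    ages,
    step: float = 0.1,
) -> pd.DataFrame:
    """Prevalence by age in ``target_year`` under the scenario's rates.

    Each age's birth cohort is integrated from age 0 (prevalence 0 — nobody
    smokes at birth) to its age in the target year along its characteristic,
    using the general-mortality form of the PDE with R(a) from the scenario's
    relative-hazard profile and the secular trend applied to initiation.
    Returns a frame with columns ``age`` and ``prevalence``.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be nonnegative")
    prev = np.empty(ages.size)
    for k, a_target in enumerate(ages):
        birth = target_year - a_target
        p = 0.0
        n_steps = max(1, int(np.ceil(a_target / step))) if a_target > 0 else 0
        grid = np.linspace(0.0, a_target, n_steps + 1)

        def f(a, p_):
            t = birth + a
            p_ = min(max(p_, 0.0), 1.0)
            return pde_rhs_relative(
                p_,
                s.initiation_at(t, a),
                s.cessation.func(t, a),
                s.mortality.func(t, a),
                relative_hazard_profile(a, s.relative_hazard_spec),
            )

        for j in range(n_steps):
            a0 = grid[j]
            h = grid[j + 1] - a0
            k1 = f(a0, p)
            k2 = f(a0 + h / 2, p + h / 2 * k1)
            k3 = f(a0 + h / 2, p + h / 2 * k2)
            k4 = f(a0 + h, p + h * k3)
            p = min(max(p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0), 1.0)
        prev[k] = p
    return pd.DataFrame({"age": ages, "prevalence": prev})


@dataclass
class SurveyPrevalenceSeries:
    """Repeated cross-sections: one prevalence-by-age slice per survey year."""

    slices: dict[float, PrevalenceSlice]

    def years(self) -> list[float]:
        return sorted(self.slices)

    def __getitem__(self, year) -> PrevalenceSlice:
        return self.slices[year]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for y in self.years():
            sl = self.slices[y]
            n = sl.n_alive if sl.n_alive is not None else np.full(sl.ages.size, np.nan)
            for a, p, nn in zip(sl.ages, sl.p, n):
                rows.append({"survey_year": y, "age": a, "p": p, "n": nn})
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurveyPrevalenceSeries":
        slices = {}
        for y, grp in df.groupby("survey_year"):
            grp = grp.sort_values("age")
            slices[float(y)] = PrevalenceSlice(
                t=float(y),
                ages=grp["age"].to_numpy(dtype=float),
                p=grp["p"].to_numpy(dtype=float),
                n_alive=grp["n"].to_numpy(dtype=float) if "n" in grp else None,
            )
        return cls(slices)


@dataclass
class AttributionTable:
    """Learning/forgetting rates per (survey year, age), units per 1000 person-years.

    One row per cohort step between consecutive surveys, anchored at the
    early survey's (year, age) and carrying the step length ``delta_years``.
    Per cell at most one of the two rates is nonzero; singular cells
    (prevalence pinned at 0 or 1 against the sign of its change) are flagged.
    """

    data: pd.DataFrame  # year, age, delta_years, learning_per_1000py, forgetting_per_1000py, flag

    def __post_init__(self):
        both = (self.data["learning_per_1000py"] > 0) & (self.data["forgetting_per_1000py"] > 0)
        if both.any():
            raise ValueError("attribution must be mutually exclusive per cell")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")


def dhs_attribution(series: SurveyPrevalenceSeries, denominator: str = "midpoint") -> AttributionTable:
    """Sign-split attribution of cohort prevalence change to learning/forgetting.

    For each pair of consecutive surveys (y1, y2) with spacing D = y2 - y1
    and each age a observed at y1 with a + D observed at y2 (the same birth
    cohort), the cohort derivative is ``dp = (p2(a+D) - p1(a))/D`` and the
    midpoint prevalence ``p_bar = (p1 + p2)/2``.  With equal mortalities the
    PDE reduces to ``dp = (1-p) i - r p``; attributing an increase wholly to
    i and a decrease wholly to r gives

        dp > 0:  i = dp/(1 - p_bar),  r = 0
        dp < 0:  r = -dp/p_bar,       i = 0
        dp = 0:  i = r = 0.

    Rates are reported per 1000 person-years.  Cells with ``p_bar = 1`` and
    ``dp > 0`` (or ``p_bar = 0`` and ``dp < 0``) are singular and flagged.

    ``denominator`` selects the prevalence entering the denominators:
    ``"midpoint"`` (default, symmetric and second-order consistent with the
    centred quotient) or ``"endpoint"`` (the early survey's value).
    """
    if denominator not in ("midpoint", "endpoint"):
        raise ValueError("denominator must be 'midpoint' or 'endpoint'")
    years = series.years()
    if len(years) < 2:
        raise ValueError("attribution needs at least two surveys")
    rows = []
    for y1, y2 in zip(years[:-1], years[1:]):
        sl1, sl2 = series[y1], series[y2]
        delta = y2 - y1
        for a, p1 in zip(sl1.ages, sl1.p):
            try:
                p2 = sl2.at_age(a + delta)
            except KeyError:
                continue
            if not (np.isfinite(p1) and np.isfinite(p2)):
                continue
            dp = (p2 - p1) / delta
            p_bar = 0.5 * (p1 + p2) if denominator == "midpoint" else p1
            i_rate = r_rate = 0.0
            flag = ""
            if dp > 0:
                if p_bar >= 1.0 - 1e-12:
                    flag = "singular"
                else:
                    i_rate = dp / (1.0 - p_bar)
            elif dp < 0:
                if p_bar <= 1e-12:
                    flag = "singular"
                else:
                    r_rate = -dp / p_bar
            rows.append(
                {
                    "year": y1,
                    "age": a,
                    "delta_years": delta,
                    "learning_per_1000py": 1000.0 * i_rate,
                    "forgetting_per_1000py": 1000.0 * r_rate,
                    "flag": flag,
                }
            )
    return AttributionTable(pd.DataFrame(rows))


def generate_synthetic_surveys(
    i_true: RateSurface,
    r_true: RateSurface,
    survey_years,
    ages,
    n_per_cell: int | None = None,
    seed: int = 0,
    a_start: float = 10.0,
    step: float = 0.02,
) -> SurveyPrevalenceSeries:
    """Synthetic DHS-style survey series from known learning/forgetting rates.

    Forward-solves the equal-mortality PDE ``dp/da = (1-p) i - r p`` along
    each (survey year, age) node's birth cohort from age ``a_start``
    (prevalence 0), then, if ``n_per_cell`` is given, replaces each cell's
    prevalence by a binomial draw ``Binom(n_per_cell, p)/n_per_cell``;
    ``n_per_cell=None`` is the noise-off switch returning exact prevalences.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(ages, dtype=float)
    slices = {}
    for y in survey_years:
        p_vals = np.empty(ages.size)
        for k, a in enumerate(ages):
            birth = y - a
            n_steps = max(1, int(np.ceil((a - a_start) / step))) if a > a_start else 0
            grid = np.linspace(a_start, a, n_steps + 1)
            p = 0.0
            for j in range(n_steps):
                a0 = grid[j]
                h = grid[j + 1] - a0

                def f(aa, pp):
                    pp = min(max(pp, 0.0), 1.0)
                    t = birth + aa
                    return (1.0 - pp) * i_true.func(t, aa) - r_true.func(t, aa) * pp

                k1 = f(a0, p)
                k2 = f(a0 + h / 2, p + h / 2 * k1)
                k3 = f(a0 + h / 2, p + h / 2 * k2)
                k4 = f(a0 + h, p + h * k3)
                p = min(max(p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0), 1.0)
            p_vals[k] = p
        if n_per_cell is not None:
            counts = rng.binomial(n_per_cell, p_vals)
            p_obs = counts / n_per_cell
            n_arr = np.full(ages.size, float(n_per_cell))
        else:
            p_obs = p_vals
            n_arr = None
        slices[float(y)] = PrevalenceSlice(t=float(y), ages=ages.copy(), p=p_obs, n_alive=n_arr)
    return SurveyPrevalenceSeries(slices)
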