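"""Person-level event-data generators.

Two study populations are generated:

* a hypothetical-disease population (one million births over a century with
  rising life expectancy and rising lifetime disease risk), used to check
  that the estimated cohort derivative of prevalence matches the PDE
  right-hand side built from person-year rate estimates;

* a register population (457,500 males born 1900-1960) where diagnosis and
  death without disease compete, sampled by inverse-transform from the
  integrated total hazard, used to test incidence reconstruction from two
  cross-sections.

Parametric fixture rates (Gompertz mortality with a secular decline, a
dementia-like exponentially age-increasing incidence, and unimodal
learning/forgetting curves) stand in for external life-table and
register-study inputs, which are not shipped with the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .lexis import Cohort
from .surfaces import RateSurface

__all__ = [
    "Sim1Config",
    "RegisterConfig",
    "simulate_hypothetical",
    "sample_first_exit",
    "simulate_register",
    "make_fixture_rates",
]


def _config_hash(cfg) -> str:
    payload = repr(sorted(asdict(cfg).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Sim1Config:
    """Hypothetical-disease population on calendar span (0, 100).

    Defaults encode the study conditions: births uniform on (0, 100); a
    healthy newborn's life expectancy rises affine-linearly from 55 years at
    t=0 to 75 at t=100; the lifetime risk of the irreversible disease rises
    affine-linearly from 10% to 25%; disease shortens life by dLE ~ U(5, 10)
    years; diagnosis occurs X ~ U(0, 12) years before death.

    Healthy lifespans are drawn Normal(LE(birth), ``lifespan_sd``), truncated
    at 15 years, so that individual deaths scatter around the cohort's life
    expectancy; the default sd of 8 years puts realistic person-year
    exposure into the 70-89 age groups of the survey window.
    ``lifespan_sd = 0`` gives the degenerate variant where every healthy
    lifespan equals the life expectancy exactly.
    """

    n_persons: int = 1_000_000
    birth_window: tuple[float, float] = (0.0, 100.0)
    le_at_t0: float = 55.0
    le_at_t100: float = 75.0
    risk_at_t0: float = 0.10
    risk_at_t100: float = 0.25
    dle_range: tuple[float, float] = (5.0, 10.0)
    x_range: tuple[float, float] = (0.0, 12.0)
    lifespan_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not (0 <= self.risk_at_t0 <= 1 and 0 <= self.risk_at_t100 <= 1):
            raise ValueError("lifetime risks must lie in [0, 1]")
        for name in ("birth_window", "dle_range", "x_range"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"{name} must be an increasing interval")
        if self.le_at_t0 <= 0 or self.le_at_t100 <= 0:
            raise ValueError("life expectancies must be positive")
        if self.lifespan_sd < 0:
            raise ValueError("lifespan_sd must be nonnegative")


def simulate_hypothetical(cfg: Sim1Config) -> Cohort:
    """Generate the hypothetical-disease population.

    Per person, draws in a fixed order (birth, disease indicator, dLE, X,
    and — only in the stochastic variant — a lifespan perturbation), each as
    one vectorized pass, so results are reproducible byte-for-byte for a
    given (config, seed).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    b_lo, b_hi = cfg.birth_window
    span = b_hi - b_lo

    birth = rng.uniform(b_lo, b_hi, size=n)
    frac = (birth - b_lo) / span
    le = cfg.le_at_t0 + (cfg.le_at_t100 - cfg.le_at_t0) * frac
    risk = cfg.risk_at_t0 + (cfg.risk_at_t100 - cfg.risk_at_t0) * frac
    diseased = rng.uniform(size=n) < risk
    dle = rng.uniform(*cfg.dle_range, size=n)
    x = rng.uniform(*cfg.x_range, size=n)
    if cfg.lifespan_sd > 0:
        le = np.maximum(le + cfg.lifespan_sd * rng.standard_normal(n), 15.0)

    death = np.where(diseased, le - dle, le)
    diag = np.where(diseased, death - x, np.nan)
    # under the default parameters diagnosis ages are strictly positive;
    # the stochastic variant clips at 0 to keep records valid
    diag = np.where(diseased & (diag < 0), 0.0, diag)

    df = pd.DataFrame({"birth_time": birth, "diagnosis_age": diag, "death_age": death})
    meta = {"generator": "simulate_hypothetical", "seed": cfg.seed, "config_hash": _config_hash(cfg)}
    return Cohort(df, meta=meta)


def sample_first_exit(total_hazard, rng, a_max: float, size: int = 1, grid_step: float = 0.01):
    """Inverse-transform sample of first-event ages for a total hazard.

    Draws u ~ U(0, 1) and solves ``H(age) = -log(1 - u)`` where ``H`` is the
    cumulative hazard, precomputed by trapezoidal accumulation of
    ``total_hazard`` (an age -> hazard function) on a ``grid_step``-year grid
    over [0, a_max].  The root is found exactly on the piecewise-linear
    cumulative-hazard interpolant (monotone inversion via ``np.interp``).

    Returns ``(ages, censored)``: draws whose exponential quantile exceeds
    ``H(a_max)`` are censored at ``a_max``.
    """
    if a_max <= 0:
        raise ValueError("a_max must be positive")
    grid = np.arange(0.0, a_max + grid_step, grid_step)
    grid[-1] = min(grid[-1], a_max)
    hz = np.asarray(total_hazard(grid), dtype=float)
    if not np.all(np.isfinite(hz)) or np.any(hz < 0):
        raise ValueError("total hazard must be finite and nonnegative on [0, a_max]")
    H = cumulative_trapezoid(hz, grid, initial=0.0)
    u = rng.uniform(size=size)
    target = -np.log1p(-u)
    censored = target >= H[-1]
    # np.interp needs strictly increasing xp only where it matters; flat
    # stretches (zero hazard) return their left edge, the earliest valid root
    ages = np.interp(target, H, grid)
    ages[censored] = a_max
    return ages, censored


@dataclass
class RegisterConfig:
    """Register population: fixed births per year, competing diagnosis/death risks.

    Defaults: 7,500 persons per birth year 1900-1960 (457,500 in total),
    age-only dementia-like incidence, Gompertz background mortality with a
    secular decline, and diseased mortality ``m_B = R * m_A`` with R = 2.
    """

    birth_years: tuple[int, int] = (1900, 1960)  # inclusive
    persons_per_year: int = 7_500
    incidence: RateSurface | None = None
    mortality_A: RateSurface | None = None
    mortality_B: RateSurface | None = None
    a_max: float = 110.0
    grid_step: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.incidence is None:
            self.incidence = make_fixture_rates("dementia_like_incidence")
        if self.mortality_A is None:
            self.mortality_A = make_fixture_rates("gompertz_mortality")
        if self.mortality_B is None:
            mA = self.mortality_A
            self.mortality_B = RateSurface(
                lambda t, a: 2.0 * mA.func(t, a), t_bounds=mA.t_bounds,
                a_bounds=mA.a_bounds, name="mB=2*mA",
            )

    def validate(self) -> None:
        y0, y1 = self.birth_years
        if y1 < y0:
            raise ValueError("birth_years must be an increasing range")
        if self.persons_per_year <= 0:
            raise ValueError("persons_per_year must be positive")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")


def simulate_register(cfg: RegisterConfig) -> Cohort:
    """Generate the register population by competing-risks sampling.

    Per birth year: births are uniform within the year; the first exit from
    the healthy state is sampled by inverse transform from the integrated
    total hazard ``i + m_A`` along the cohort's mid-year characteristic; the
    event is a diagnosis with probability ``i/(i + m_A)`` at the exit age,
    otherwise a death.  Diagnosed persons draw their residual death age from
    ``m_B`` conditional on survival to the diagnosis age (a fresh exponential
    quantile added to the cumulative hazard already accrued).  The handful of
    draws exceeding ``a_max`` are recorded as deaths at ``a_max``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.birth_years
    years = np.arange(y0, y1 + 1)
    npz = cfg.persons_per_year
    grid = np.arange(0.0, cfg.a_max + cfg.grid_step, cfg.grid_step)

    births_all, diags_all, deaths_all = [], [], []
    for y in years:
        t_mid = y + 0.5
        i_g = np.asarray(cfg.incidence(t_mid + grid, grid), dtype=float)
        mA_g = np.asarray(cfg.mortality_A(t_mid + grid, grid), dtype=float)
        mB_g = np.asarray(cfg.mortality_B(t_mid + grid, grid), dtype=float)
        if not (np.all(np.isfinite(i_g)) and np.all(np.isfinite(mA_g)) and np.all(np.isfinite(mB_g))):
            raise ValueError("hazards must be finite over the sampled age range")
        H_tot = cumulative_trapezoid(i_g + mA_g, grid, initial=0.0)
        H_B = cumulative_trapezoid(mB_g, grid, initial=0.0)

        birth = rng.uniform(y, y + 1.0, size=npz)
        u = rng.uniform(size=npz)
        target = -np.log1p(-u)
        censored = target >= H_tot[-1]
        exit_age = np.interp(target, H_tot, grid)
        exit_age[censored] = cfg.a_max

        i_at = np.interp(exit_age, grid, i_g)
        tot_at = np.interp(exit_age, grid, i_g + mA_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_diag = np.where(tot_at > 0, i_at / tot_at, 0.0)
        is_diag = (~censored) & (rng.uniform(size=npz) < p_diag)

        diag = np.where(is_diag, exit_age, np.nan)
        death = exit_age.copy()
        if is_diag.any():
            hb0 = np.interp(diag[is_diag], grid, H_B)
            e2 = rng.exponential(size=int(is_diag.sum()))
            d_target = hb0 + e2
            d_cens = d_target >= H_B[-1]
            d_age = np.interp(d_target, H_B, grid)
            d_age[d_cens] = cfg.a_max
            death[is_diag] = np.maximum(d_age, diag[is_diag] + 1e-9)

        births_all.append(birth)
        diags_all.append(diag)
        deaths_all.append(death)

    df = pd.DataFrame(
        {
            "birth_time": np.concatenate(births_all),
            "diagnosis_age": np.concatenate(diags_all),
            "death_age": np.concatenate(deaths_all),
        }
    )
    meta = {"generator": "simulate_register", "seed": cfg.seed}
    return Cohort(df, meta=meta)


# ---------------------------------------------------------------------------
# parametric fixture rates

#: defaults for the register fixtures: a Gompertz background mortality with a
#: mild secular decline (0.2%/yr) and an incidence that is zero before age 60
#: and grows exponentially after it (doubling roughly every 6 years), the
#: canonical shape of late-life dementia incidence.
FIXTURE_DEFAULTS = {
    "gompertz_mortality": {"alpha": 4.5e-5, "beta": 0.085, "decline": 0.002, "t_ref": 1900.0},
    "dementia_like_incidence": {"c": 7e-4, "gamma": 0.12, "a0": 60.0},
    "dhs_like_learning": {"peak": 0.05, "a_peak": 22.0, "width": 8.0},
    "dhs_like_forgetting": {"peak": 0.04, "a_on": 38.0, "scale": 6.0},
}


def make_fixture_rates(kind: str, **params) -> RateSurface:
    """Parametric rate surfaces used as simulation inputs.

    ``gompertz_mortality``: ``m(t, a) = alpha * exp(beta*a) * exp(-decline*(t-t_ref))``.
    ``dementia_like_incidence``: ``i(a) = c * exp(gamma*(a-a0))`` for a >= a0, else 0.
    ``dhs_like_learning``: unimodal-in-age Gaussian bump peaking in the early 20s.
    ``dhs_like_forgetting``: zero before ``a_on``, saturating rise after it.
    """
    if kind not in FIXTURE_DEFAULTS:
        raise ValueError(f"unknown fixture kind {kind!r}; one of {sorted(FIXTURE_DEFAULTS)}")
    p = dict(FIXTURE_DEFAULTS[kind])
    unknown = set(params) - set(p)
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)} for fixture {kind!r}")
    p.update(params)
    if any(v < 0 for k, v in p.items() if k in ("alpha", "c", "peak", "width", "scale")):
        raise ValueError("scale parameters must be nonnegative")

    if kind == "gompertz_mortality":
        alpha, beta, decline, t_ref = p["alpha"], p["beta"], p["decline"], p["t_ref"]
        return RateSurface(
            lambda t, a: alpha * np.exp(beta * np.asarray(a, float))
            * np.exp(-decline * (np.asarray(t, float) - t_ref)),
            name=f"gompertz(alpha={alpha:g},beta={beta:g})",
        )
    if kind == "dementia_like_incidence":
        c, gamma, a0 = p["c"], p["gamma"], p["a0"]
        return RateSurface.from_age_function(
            lambda a: np.where(a >= a0, c * np.exp(gamma * (a - a0)), 0.0),
            name=f"dementia_like(c={c:g},gamma={gamma:g},a0={a0:g})",
        )
    if kind == "dhs_like_learning":
        peak, a_peak, width = p["peak"], p["a_peak"], p["width"]
        return RateSurface.from_age_function(
            lambda a: peak * np.exp(-0.5 * ((a - a_peak) / width) ** 2),
            name="dhs_like_learning",
        )
    # dhs_like_forgetting
    peak, a_on, scale = p["peak"], p["a_on"], p["scale"]
    return RateSurface.from_age_function(
        lambda a: np.where(a >= a_on, peak * (1.0 - np.exp(-(a - a_on) / scale)), 0.0),
        name="dhs_like_forgetting",
    )
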