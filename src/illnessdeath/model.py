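"""Core equations of the three-state (A/B/Dead) prevalence model.

The age-specific prevalence ``p(t, a)`` of state B obeys the one-dimensional
PDE along Lexis characteristics (cohort lines, direction (1, 1) in (t, a)):

    (d/dt + d/da) p = (1 - p) * (i - p * (m_B - m_A)) - r * p

with incidence ``i`` (A -> B), remission ``r`` (B -> A) and state-specific
mortalities ``m_A``, ``m_B``.  When only general mortality
``m = (1-p) m_A + p m_B`` and the mortality ratio ``R = m_B/m_A`` are known,
the equivalent form is

    (d/dt + d/da) p = (1 - p) * (i - m * p (R-1) / (p (R-1) + 1)) - r * p

For an irreversible state (r = 0) the unique solution is Keiding's integral

    p(t, a) = N / (1 + N),
    N = int_0^a i(t-d, a-d) exp(- int_0^d Psi(t-d+s, a-d+s) ds) dd,
    Psi = m_B - m_A - i.

This module houses the right-hand sides, characteristic/surface solvers, the
two-compartment (S, C) system they derive from, the Keiding integral as an
independent oracle, and the algebraic inversions of the PDE for i and r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

from .surfaces import (
    CohortTrajectory,
    DomainError,
    PrevalenceSurface,
    RateSet,
    RateSurface,
)

__all__ = [
    "pde_rhs",
    "pde_rhs_relative",
    "general_mortality",
    "solve_prevalence_cohort",
    "solve_prevalence_surface",
    "solve_SC_system",
    "keiding_prevalence",
    "invert_incidence",
    "invert_remission",
    "SingularInversionError",
]

#: guard for the algebraic inversions near the poles p=1 (incidence) / p=0 (remission)
SINGULAR_EPS = 1e-9


class SingularInversionError(ZeroDivisionError):
    """Rate inversion attempted at (or numerically at) a singular prevalence."""


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("prevalence p must lie in [0, 1]")
    return p


def pde_rhs(p, i, r, mA, mB):
    """Right-hand side of the prevalence PDE (state-specific mortality form).

    Returns the per-year change of prevalence along the cohort line:
    ``(1-p) * (i - p*(mB - mA)) - r*p``.  All hazards are per person-year.
    """
    p = _check_p(p)
    i, r, mA, mB = (np.asarray(x, dtype=float) for x in (i, r, mA, mB))
    if np.any(i < 0) or np.any(r < 0) or np.any(mA < 0) or np.any(mB < 0):
        raise DomainError("hazards must be nonnegative")
    out = (1.0 - p) * (i - p * (mB - mA)) - r * p
    return float(out) if out.ndim == 0 else out


def pde_rhs_relative(p, i, r, m, R):
    """Right-hand side in the general-mortality form.

    Uses ``m = (1-p) m_A + p m_B`` and ``R = m_B/m_A`` instead of the
    state-specific mortalities: ``(1-p)*(i - m*p*(R-1)/(p*(R-1)+1)) - r*p``.
    Agrees with :func:`pde_rhs` exactly when (m, R) are computed from
    (p, m_A, m_B).
    """
    p = _check_p(p)
    i, r, m, R = (np.asarray(x, dtype=float) for x in (i, r, m, R))
    if np.any(i < 0) or np.any(r < 0) or np.any(m < 0):
        raise DomainError("hazards must be nonnegative")
    if np.any(R <= 0):
        raise DomainError("relative mortality R must be positive")
    denom = p * (R - 1.0) + 1.0
    # denom > 0 is guaranteed for p in [0,1], R > 0; assert against misuse
    if np.any(denom <= 0):
        raise DomainError("p*(R-1)+1 must be positive")
    out = (1.0 - p) * (i - m * p * (R - 1.0) / denom) - r * p
    return float(out) if out.ndim == 0 else out


def general_mortality(p, mA, mB):
    """Population (general) mortality ``m = (1-p) m_A + p m_B``."""
    p = _check_p(p)
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    out = (1.0 - p) * mA + p * mB
    return float(out) if out.ndim == 0 else out


def _rhs_from_rateset(rates: RateSet, t, a, p):
    """Evaluate the PDE right-hand side under either mortality parameterization."""
    i = rates.i(t, a)
    r = rates.r(t, a)
    if rates.tag == "state_specific":
        return pde_rhs(p, i, r, rates.m_A(t, a), rates.m_B(t, a))
    return pde_rhs_relative(p, i, r, rates.m(t, a), rates.R(t, a))


def solve_prevalence_cohort(
    rates: RateSet,
    t0: float,
    a0: float,
    p0: float,
    a_end: float,
    step: float = 0.1,
) -> CohortTrajectory:
    """Integrate the prevalence PDE along one cohort characteristic.

    The characteristic through ``(t0, a0)`` is ``t = t0 + (a - a0)``; along it
    the PDE is the ODE ``dp/da = rhs(p; rates(t0 + a - a0, a))``, solved with
    classic fixed-step 4th-order Runge-Kutta from ``a0`` to ``a_end``.  If the
    characteristic leaves the rate domain before ``a_end`` it is clipped there
    and the trajectory is flagged ``truncated``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise DomainError("p0 must lie in [0, 1]")
    if a_end < a0:
        raise ValueError("a_end must be >= a0")
    if step <= 0:
        raise ValueError("step must be positive")
    if not rates.contains(t0, a0):
        raise DomainError(f"characteristic start (t={t0}, a={a0}) outside rate domain")

    truncated = False
    a_stop = a_end
    if not rates.contains(t0 + (a_end - a0), a_end):
        # clip to the last in-domain age along the characteristic
        lo, hi = a0, a_end
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if rates.contains(t0 + (mid - a0), mid):
                lo = mid
            else:
                hi = mid
        a_stop = lo
        truncated = True

    n_steps = max(1, int(np.ceil((a_stop - a0) / step - 1e-12))) if a_stop > a0 else 0
    ages = a0 + np.arange(n_steps + 1) * step
    if n_steps:
        ages[-1] = a_stop  # land exactly on the endpoint
    p_vals = np.empty(n_steps + 1)
    p_vals[0] = p0

    def f(a, p):
        return _rhs_from_rateset(rates, t0 + (a - a0), a, min(max(p, 0.0), 1.0))

    p = p0
    for k in range(n_steps):
        a = ages[k]
        h = ages[k + 1] - a
        k1 = f(a, p)
        k2 = f(a + h / 2, p + h / 2 * k1)
        k3 = f(a + h / 2, p + h / 2 * k2)
        k4 = f(a + h, p + h * k3)
        p = p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        # RK4 can overshoot [0,1] by O(step^5) at the boundary; project back
        p = min(max(p, 0.0), 1.0)
        p_vals[k + 1] = p

    return CohortTrajectory(t0=t0, ages=ages, p_values=p_vals, truncated=truncated)


def solve_prevalence_surface(
    rates: RateSet,
    t_grid,
    a_grid,
    boundary_p_at_age0=None,
    step: float = 0.1,
) -> PrevalenceSurface:
    """Solve the PDE on a (t, a) grid, characteristic by characteristic.

    Each output node (t, a) is reached by integrating along its cohort line
    from the youngest in-domain age.  ``boundary_p_at_age0(t_birth)`` gives the
    initial prevalence where the characteristic starts at the domain's minimum
    age (default: 0 everywhere — nobody holds the property at birth);
    characteristics entering through the domain's left time edge also start at
    the boundary value evaluated at their entry point.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)
    if boundary_p_at_age0 is None:
        boundary_p_at_age0 = lambda t: 0.0

    a_min_dom = max(rates.i.a_bounds[0], 0.0)
    t_min_dom = rates.i.t_bounds[0]

    p = np.full((t_grid.size, a_grid.size), np.nan)
    # group nodes by characteristic identifier c = t - a
    cs = np.round(t_grid[:, None] - a_grid[None, :], 9)
    for c in np.unique(cs):
        idx = np.argwhere(cs == c)
        ages_needed = np.sort(a_grid[idx[:, 1]])
        a_hi = ages_needed[-1]
        # entry point of this characteristic into the domain
        a_start = a_min_dom
        if np.isfinite(t_min_dom) and c + a_min_dom < t_min_dom:
            a_start = t_min_dom - c
        if a_start > a_hi + 1e-12:
            continue  # no in-domain segment reaches these nodes
        p0 = float(np.clip(boundary_p_at_age0(c + a_start), 0.0, 1.0))
        traj = solve_prevalence_cohort(
            rates, t0=c + a_start, a0=a_start, p0=p0, a_end=a_hi, step=step
        )
        for it, ia in idx:
            a_node = a_grid[ia]
            if a_node < a_start - 1e-9 or a_node > traj.ages[-1] + 1e-9:
                continue
            p[it, ia] = np.interp(a_node, traj.ages, traj.p_values)
    return PrevalenceSurface(t_grid=t_grid, a_grid=a_grid, p=p)


def solve_SC_system(
    rates: RateSet,
    t_grid,
    a_grid,
    newborns,
    step: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two-compartment system for the numbers S (state A) and C (state B).

    Along each cohort line the balance equations are

        dS/da = -(i + m_A) S + r C
        dC/da =  i S - (m_B + r) C

    with ``S(t_birth, 0) = newborns(t_birth) > 0`` and ``C(t_birth, 0) = 0``.
    Returns arrays ``S, C`` of shape ``(len(t_grid), len(a_grid))``;
    ``C/(S+C)`` reproduces :func:`solve_prevalence_surface` to integrator
    tolerance (prevalence is scale-free in the newborn count).

    Requires the state-specific mortality parameterization.
    """
    if rates.tag != "state_specific":
        raise ValueError("solve_SC_system needs the (m_A, m_B) parameterization")
    t_grid = np.asarray(t_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)

    S = np.full((t_grid.size, a_grid.size), np.nan)
    C = np.full((t_grid.size, a_grid.size), np.nan)
    a_min_dom = max(rates.i.a_bounds[0], 0.0)

    cs = np.round(t_grid[:, None] - a_grid[None, :], 9)
    for c in np.unique(cs):
        idx = np.argwhere(cs == c)
        a_hi = float(np.max(a_grid[idx[:, 1]]))
        n0 = float(newborns(c + a_min_dom))
        if n0 <= 0:
            raise ValueError("newborns(t) must be positive")
        n_steps = max(1, int(np.ceil((a_hi - a_min_dom) / step - 1e-12))) if a_hi > a_min_dom else 0
        ages = a_min_dom + np.arange(n_steps + 1) * step
        if n_steps:
            ages[-1] = a_hi
        ys = np.empty((n_steps + 1, 2))
        ys[0] = (n0, 0.0)

        def f(a, y):
            t = c + a
            i = rates.i(t, a)
            r = rates.r(t, a)
            mA = rates.m_A(t, a)
            mB = rates.m_B(t, a)
            s_, c_ = y
            return np.array([-(i + mA) * s_ + r * c_, i * s_ - (mB + r) * c_])

        y = ys[0]
        for k in range(n_steps):
            a = ages[k]
            h = ages[k + 1] - a
            k1 = f(a, y)
            k2 = f(a + h / 2, y + h / 2 * k1)
            k3 = f(a + h / 2, y + h / 2 * k2)
            k4 = f(a + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            y = np.clip(y, 0.0, None)
            ys[k + 1] = y

        for it, ia in idx:
            a_node = a_grid[ia]
            S[it, ia] = np.interp(a_node, ages, ys[:, 0])
            C[it, ia] = np.interp(a_node, ages, ys[:, 1])
    return S, C


def keiding_prevalence(
    i: RateSurface,
    mA: RateSurface,
    mB: RateSurface,
    t: float,
    a: float,
    quad_step: float = 0.05,
) -> float:
    """Prevalence of an irreversible state (r = 0) by Keiding's integral.

    Evaluates ``N/(1+N)`` with

        N = int_0^a i(t-d, a-d) * exp(-int_0^d Psi(t-d+s, a-d+s) ds) dd,
        Psi = m_B - m_A - i,

    by composite Simpson quadrature with step ``quad_step`` on both nested
    integrals.  The inner integral runs along the same characteristic for
    every d, so its cumulative form ``G(u) = int_0^u Psi(t-a+u', u') du'`` is
    precomputed once and the inner integral is ``G(a) - G(a-d)``.
    """
    if a < 0:
        raise DomainError("age must be nonnegative")
    if a == 0:
        return 0.0
    n = max(2, int(np.ceil(a / quad_step)))
    if n % 2:
        n += 1  # Simpson needs an even panel count
    u = np.linspace(0.0, a, n + 1)  # age along the characteristic
    tt = t - a + u
    psi = mB(tt, u) - mA(tt, u) - i(tt, u)
    G = cumulative_simpson(psi, x=u, initial=0.0)
    # outer variable d = a - u: integrand i(t-d, a-d) * exp(-(G(a) - G(a-d)))
    integrand = i(tt, u) * np.exp(-(G[-1] - G))
    N = simpson(integrand, x=u)
    if N < 0:
        N = 0.0
    return float(N / (1.0 + N))


def invert_incidence(dp, p, r, mA, mB):
    """Solve the PDE for the incidence rate: ``i = (dp + r p)/(1-p) + p (m_B - m_A)``.

    Singular at p = 1; cells with ``p > 1 - 1e-9`` raise
    :class:`SingularInversionError` naming the offending values.  Sampling
    noise can produce negative results; they are returned as-is (flagging and
    clamping are application-level policy).
    """
    p = np.asarray(p, dtype=float)
    dp, r, mA, mB = (np.asarray(x, dtype=float) for x in (dp, r, mA, mB))
    bad = p > 1.0 - SINGULAR_EPS
    if np.any(bad):
        raise SingularInversionError(
            f"incidence inversion singular at p={np.atleast_1d(p)[np.atleast_1d(bad)]}"
        )
    out = (dp + r * p) / (1.0 - p) + p * (mB - mA)
    return float(out) if out.ndim == 0 else out


def invert_remission(dp, p, i, mA, mB):
    """Solve the PDE for the remission rate: ``r = ((1-p)(i - p (m_B - m_A)) - dp)/p``.

    Singular at p = 0; cells with ``p < 1e-9`` raise
    :class:`SingularInversionError`.
    """
    p = np.asarray(p, dtype=float)
    dp, i, mA, mB = (np.asarray(x, dtype=float) for x in (dp, i, mA, mB))
    bad = p < SINGULAR_EPS
    if np.any(bad):
        raise SingularInversionError(
            f"remission inversion singular at p={np.atleast_1d(p)[np.atleast_1d(bad)]}"
        )
    out = ((1.0 - p) * (i - p * (mB - mA)) - dp) / p
    return float(out) if out.ndim == 0 else out
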