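"""Rate and prevalence surfaces on the Lexis plane.

A *rate surface* is a nonnegative transition hazard (per person-year) as a
function of calendar time ``t`` and age ``a``, both in years, defined on a
rectangular domain.  A *prevalence surface* is a gridded field ``p(t, a)`` of
the fraction of living persons in state B, optionally backed by the counts
it was estimated from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "RateSurface",
    "RateSet",
    "PrevalenceSurface",
    "CohortTrajectory",
    "DomainError",
]


class DomainError(ValueError):
    """Evaluation outside a surface's (t, a) domain, or an invalid state value."""


@dataclass(frozen=True)
class RateSurface:
    """Nonnegative hazard h(t, a) on a rectangular (t, a) domain.

    Parameters
    ----------
    func : callable
        Vectorized evaluator ``func(t, a) -> hazard`` (per person-year).
    t_bounds, a_bounds : (float, float)
        Closed domain rectangle.  Evaluation outside raises
        :class:`DomainError`; the model never extrapolates a hazard.
    name : str
        Label used in error messages and manifests.
    """

    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    t_bounds: tuple[float, float] = (-np.inf, np.inf)
    a_bounds: tuple[float, float] = (0.0, np.inf)
    name: str = "rate"

    # tolerance for boundary round-off when solvers step exactly to an edge
    _edge_tol = 1e-9

    def __call__(self, t, a):
        t = np.asarray(t, dtype=float)
        a = np.asarray(a, dtype=float)
        self._check_domain(t, a)
        out = np.asarray(self.func(t, a), dtype=float)
        shape = np.broadcast_shapes(t.shape, a.shape)
        if shape == () and out.size == 1:
            out = out.reshape(())
        else:
            out = np.broadcast_to(out, shape).copy()
        if np.any(out < 0):
            raise ValueError(f"rate surface {self.name!r} returned a negative hazard")
        if t.ndim == 0 and a.ndim == 0:
            return float(out)
        return out

    def _check_domain(self, t, a) -> None:
        tol = self._edge_tol
        t0, t1 = self.t_bounds
        a0, a1 = self.a_bounds
        if np.any(t < t0 - tol) or np.any(t > t1 + tol) or np.any(a < a0 - tol) or np.any(a > a1 + tol):
            raise DomainError(
                f"rate surface {self.name!r} evaluated outside its domain "
                f"t in {self.t_bounds}, a in {self.a_bounds}"
            )

    def contains(self, t: float, a: float) -> bool:
        tol = self._edge_tol
        return (
            self.t_bounds[0] - tol <= t <= self.t_bounds[1] + tol
            and self.a_bounds[0] - tol <= a <= self.a_bounds[1] + tol
        )

    # ---- constructors -------------------------------------------------
    @classmethod
    def constant(cls, value: float, name: str = "const", **bounds) -> "RateSurface":
        if value < 0:
            raise ValueError("hazard must be nonnegative")
        return cls(lambda t, a: np.full(np.broadcast_shapes(np.shape(t), np.shape(a)), float(value)),
                   name=name, **bounds)

    @classmethod
    def from_age_function(cls, f: Callable, name: str = "age_rate", **bounds) -> "RateSurface":
        """Rate depending on age only (no calendar-time trend)."""
        return cls(lambda t, a: np.asarray(f(np.asarray(a, dtype=float)), dtype=float) + 0.0 * np.asarray(t, float),
                   name=name, **bounds)

    @classmethod
    def from_grid(
        cls,
        t_grid: Sequence[float],
        a_grid: Sequence[float],
        values: np.ndarray,
        method: str = "bilinear",
        name: str = "gridded",
    ) -> "RateSurface":
        """Interpolating surface from a (t, a) grid of hazards.

        ``method`` is ``"bilinear"`` or ``"step"`` (piecewise-constant on the
        cell whose lower-left node is nearest below).
        """
        t_grid = np.asarray(t_grid, dtype=float)
        a_grid = np.asarray(a_grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape != (t_grid.size, a_grid.size):
            raise ValueError("values must have shape (len(t_grid), len(a_grid))")
        if np.any(values < 0):
            raise ValueError("gridded hazards must be nonnegative")
        interp_method = {"bilinear": "linear", "step": "nearest"}.get(method)
        if interp_method is None:
            raise ValueError(f"unknown interpolation method {method!r}")
        interp = RegularGridInterpolator(
            (t_grid, a_grid), values, method=interp_method, bounds_error=False, fill_value=None
        )

        def f(t, a):
            pts = np.stack(np.broadcast_arrays(np.asarray(t, float), np.asarray(a, float)), axis=-1)
            return np.clip(interp(pts), 0.0, None)

        return cls(f, t_bounds=(t_grid[0], t_grid[-1]), a_bounds=(a_grid[0], a_grid[-1]), name=name)


@dataclass(frozen=True)
class RateSet:
    """The four transition rates of the three-state model.

    Mortality is held either state-specific ``(m_A, m_B)`` or as general
    mortality plus relative mortality ``(m, R)`` with ``R = m_B / m_A``;
    exactly one parameterization is present (``tag`` says which).
    """

    i: RateSurface
    r: RateSurface
    m_A: RateSurface | None = None
    m_B: RateSurface | None = None
    m: RateSurface | None = None
    R: RateSurface | None = None

    def __post_init__(self):
        has_ab = self.m_A is not None and self.m_B is not None
        has_mr = self.m is not None and self.R is not None
        if has_ab == has_mr:
            raise ValueError("provide exactly one mortality parameterization: (m_A, m_B) or (m, R)")

    @property
    def tag(self) -> str:
        return "state_specific" if self.m_A is not None else "relative"

    def contains(self, t: float, a: float) -> bool:
        surfs = [self.i, self.r] + [s for s in (self.m_A, self.m_B, self.m, self.R) if s is not None]
        return all(s.contains(t, a) for s in surfs)


@dataclass
class PrevalenceSurface:
    """Gridded prevalence p(t, a) with optional per-node counts.

    ``p`` has shape ``(len(t_grid), len(a_grid))``; NaN marks undefined nodes
    (no living persons).  Where counts are present, ``p = n_state_B/n_alive``.
    """

    t_grid: np.ndarray
    a_grid: np.ndarray
    p: np.ndarray
    n_alive: np.ndarray | None = None
    n_state_B: np.ndarray | None = None

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.a_grid = np.asarray(self.a_grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.t_grid.size, self.a_grid.size):
            raise ValueError("p must have shape (len(t_grid), len(a_grid))")
        if np.any(np.diff(self.t_grid) <= 0) or np.any(np.diff(self.a_grid) <= 0):
            raise ValueError("grids must be strictly ascending")
        finite = np.isfinite(self.p)
        if np.any((self.p[finite] < -1e-12) | (self.p[finite] > 1 + 1e-12)):
            raise ValueError("prevalence values must lie in [0, 1]")

    def at(self, t: float, a: float) -> float:
        """Exact-node lookup; raises KeyError naming a missing node."""
        it = np.flatnonzero(np.isclose(self.t_grid, t, atol=1e-9))
        ia = np.flatnonzero(np.isclose(self.a_grid, a, atol=1e-9))
        if it.size == 0 or ia.size == 0:
            raise KeyError(f"prevalence surface has no node at (t={t}, a={a})")
        return float(self.p[it[0], ia[0]])

    def slice_at(self, t: float) -> "PrevalenceSlice":
        it = np.flatnonzero(np.isclose(self.t_grid, t, atol=1e-9))
        if it.size == 0:
            raise KeyError(f"prevalence surface has no survey at t={t}")
        k = it[0]
        return PrevalenceSlice(
            t=float(self.t_grid[k]),
            ages=self.a_grid.copy(),
            p=self.p[k].copy(),
            n_alive=None if self.n_alive is None else self.n_alive[k].copy(),
            n_state_B=None if self.n_state_B is None else self.n_state_B[k].copy(),
        )


@dataclass
class PrevalenceSlice:
    """One cross-section: prevalence by age at a fixed survey time."""

    t: float
    ages: np.ndarray
    p: np.ndarray
    n_alive: np.ndarray | None = None
    n_state_B: np.ndarray | None = None

    def at_age(self, a: float) -> float:
        ia = np.flatnonzero(np.isclose(self.ages, a, atol=1e-9))
        if ia.size == 0:
            raise KeyError(f"survey at t={self.t} has no age bin {a}")
        return float(self.p[ia[0]])


@dataclass
class CohortTrajectory:
    """Prevalence along one birth cohort's characteristic (t0 + a, a)."""

    t0: float  # calendar time at ages[0]
    ages: np.ndarray
    p_values: np.ndarray
    truncated: bool = False  # characteristic clipped at the rate domain edge

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + (self.ages - self.ages[0])

    def final_p(self) -> float:
        return float(self.p_values[-1])
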