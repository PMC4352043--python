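"""File formats: gridded rate/prevalence CSV and flat key-value configs.

Gridded surfaces travel as UTF-8 CSV with header ``t,a,value``, one row per
node, dot decimal.  Configuration files are flat ``key = value`` text;
unknown keys are errors (silent misconfiguration of a simulation is worse
than a loud one).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .surfaces import PrevalenceSurface, RateSurface

__all__ = [
    "write_rate_grid",
    "read_rate_surface",
    "write_prevalence_surface",
    "read_prevalence_surface",
    "parse_config",
    "read_parametric_rate",
    "ConfigError",
]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def write_rate_grid(surface: RateSurface, t_grid, a_grid, path) -> None:
    """Sample a rate surface on a grid and write ``t,a,value`` rows."""
    t_grid = np.asarray(t_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)
    tt, aa = np.meshgrid(t_grid, a_grid, indexing="ij")
    vals = surface(tt, aa)
    pd.DataFrame({"t": tt.ravel(), "a": aa.ravel(), "value": np.asarray(vals).ravel()}).to_csv(
        path, index=False, float_format="%.10g"
    )


def _read_grid_csv(path, value_col: str):
    df = pd.read_csv(path)
    for col in ("t", "a", value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns t,a,{value_col}")
    t_grid = np.unique(df["t"].to_numpy(dtype=float))
    a_grid = np.unique(df["a"].to_numpy(dtype=float))
    values = np.full((t_grid.size, a_grid.size), np.nan)
    ti = np.searchsorted(t_grid, df["t"].to_numpy(dtype=float))
    ai = np.searchsorted(a_grid, df["a"].to_numpy(dtype=float))
    values[ti, ai] = df[value_col].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: grid is not complete over t x a")
    return t_grid, a_grid, values


def read_rate_surface(path, method: str = "bilinear", name: str | None = None) -> RateSurface:
    """Rate surface from a ``t,a,value`` CSV; ``method`` is bilinear or step."""
    t_grid, a_grid, values = _read_grid_csv(path, "value")
    return RateSurface.from_grid(t_grid, a_grid, values, method=method,
                                 name=name or Path(path).stem)


def write_prevalence_surface(surface: PrevalenceSurface, path) -> None:
    tt, aa = np.meshgrid(surface.t_grid, surface.a_grid, indexing="ij")
    pd.DataFrame({"t": tt.ravel(), "a": aa.ravel(), "value": surface.p.ravel()}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_prevalence_surface(path) -> PrevalenceSurface:
    t_grid, a_grid, values = _read_grid_csv(path, "value")
    return PrevalenceSurface(t_grid=t_grid, a_grid=a_grid, p=values)


def read_parametric_rate(path) -> RateSurface:
    """Rate surface from a key-value file naming a registered functional form.

    The file holds ``kind = <fixture name>`` plus that form's numeric
    parameters, e.g.::

        kind = gompertz_mortality
        alpha = 4.5e-5
        beta = 0.085

    Unknown parameters for the named form are errors.
    """
    from .simulate import FIXTURE_DEFAULTS, make_fixture_rates

    raw = parse_config(path, {"kind": str, **{k: float for p in FIXTURE_DEFAULTS.values() for k in p}})
    kind = raw.pop("kind", None)
    if kind is None:
        raise ConfigError(f"{path}: missing 'kind'")
    try:
        return make_fixture_rates(kind, **raw)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def parse_config(path, schema: dict[str, type]) -> dict:
    """Parse a flat ``key = value`` file against a schema.

    ``schema`` maps allowed keys to target types (int, float, str, bool).
    Lines starting with ``#`` and blank lines are skipped.  Unknown keys,
    repeated keys and unparseable values raise :class:`ConfigError`.
    """
    out: dict = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key not in schema:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in out:
            raise ConfigError(f"{path}:{lineno}: repeated key {key!r}")
        typ = schema[key]
        try:
            if typ is bool:
                if value.lower() not in ("true", "false", "0", "1"):
                    raise ValueError(value)
                out[key] = value.lower() in ("true", "1")
            else:
                out[key] = typ(value)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: cannot parse {value!r} as {typ.__name__}") from exc
    return out
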