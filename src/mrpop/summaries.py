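"""Demographic summary measures over posterior draws.

TFR, abridged-life-table life expectancy at birth, and empirical quantile
summaries (median with 50/80/95% predictive intervals) of draw-indexed
quantities.  The life-table convention matches the projection engine's
linear person-years approximation: ``q_x = 5 d / (1 + 2.5 d)`` for closed
five-year groups, ``L_x = 5 (l_x + l_{x+5}) / 2`` and ``L_z = l_z / d_z``
for the open-ended group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DimensionRegistry

LEVELS = (0.50, 0.80, 0.95)


def tfr(f: np.ndarray, registry: DimensionRegistry) -> np.ndarray:
    """Total fertility rate per region: 5 x sum of annual age-specific rates.

    ``f`` is (n, z) over all age groups (zero outside the reproductive
    window) or (n, n_reproductive) over the window only.
    """
    f = np.atleast_2d(np.asarray(f, dtype=float))
    a0, b0 = registry.reproductive_window
    if f.shape[1] == registry.n_ages:
        outside = np.ones(registry.n_ages, dtype=bool)
        outside[a0 : b0 + 1] = False
        if np.any(f[:, outside] != 0):
            raise ValueError("non-zero fertility outside the reproductive window")
        f = f[:, a0 : b0 + 1]
    elif f.shape[1] != b0 - a0 + 1:
        raise ValueError("fertility array does not match the reproductive window")
    return 5.0 * f.sum(axis=1)


def life_expectancy_at_birth(d: np.ndarray, registry: DimensionRegistry) -> float:
    """Period life expectancy at birth from an abridged life table.

    ``d`` holds age-specific mortality rates for the registry's z five-year
    groups, the last open-ended.  Death probabilities use the mid-interval
    person-years assumption ``q_x = 5 d / (1 + 2.5 d)``; the open-ended
    group is closed with ``L_z = l_z / d_z``.
    """
    d = np.asarray(d, dtype=float)
    z = registry.n_ages
    if d.shape != (z,):
        raise ValueError(f"expected {z} age-specific rates")
    if np.any(d < 0):
        raise ValueError("negative mortality rates")
    l = np.empty(z + 1)
    l[0] = 1.0
    q = 5.0 * d[:-1] / (1.0 + 2.5 * d[:-1])
    for a in range(z - 1):
        l[a + 1] = l[a] * (1.0 - q[a])
    l[z] = 0.0  # not used; open group handled via L_z
    L = 5.0 * (l[:-2] + l[1:-1]) / 2.0
    lz = l[z - 1]
    if lz > 0 and d[-1] <= 0:
        raise ValueError("open-ended closure undefined: d_z = 0 with survivors")
    Lz = lz / d[-1] if d[-1] > 0 else 0.0
    return float(L.sum() + Lz)


@dataclass
class QuantileSummary:
    """Median and nested 50/80/95% predictive intervals of a draw set."""

    median: np.ndarray
    lower: dict  # level -> array
    upper: dict

    def interval(self, level: float) -> tuple[np.ndarray, np.ndarray]:
        return self.lower[level], self.upper[level]

    def to_frame(self, keys: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"median": np.atleast_1d(self.median)})
        for lv in LEVELS:
            out[f"lo{int(lv * 100)}"] = np.atleast_1d(self.lower[lv])
            out[f"hi{int(lv * 100)}"] = np.atleast_1d(self.upper[lv])
        if keys is not None:
            out = pd.concat([keys.reset_index(drop=True), out], axis=1)
        return out


def summarize_draws(values: np.ndarray, levels=LEVELS) -> QuantileSummary:
    """Empirical quantile summary along the first (draw) axis.

    Quantiles use linear interpolation; intervals are nested by
    construction since the same draw set feeds every level.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two draws")
    med = np.quantile(values, 0.5, axis=0)
    lower, upper = {}, {}
    for lv in levels:
        lower[lv] = np.quantile(values, (1 - lv) / 2, axis=0)
        upper[lv] = np.quantile(values, 1 - (1 - lv) / 2, axis=0)
    return QuantileSummary(med, lower, upper)


def percentile_of(values: np.ndarray, x: float) -> float:
    """Percentile of an external value within a draw set (midrank)."""
    values = np.sort(np.asarray(values, dtype=float).ravel())
    below = np.searchsorted(values, x, side="left")
    above = np.searchsorted(values, x, side="right")
    return float(100.0 * (below + above) / (2 * values.size))
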