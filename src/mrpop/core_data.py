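"""Data model and I/O for cross-classified demographic count tables.

All five components of change (internal migration, mortality, fertility,
immigration, emigration) are carried as long-format tables of non-negative
event counts with positive exposures, fully cross-classified over the
dimensions declared in a :class:`DimensionRegistry`.  A single CSV layout
(``component,origin,destination,age,sex,year,count,exposure``) is the
interchange format for every component; unused dimension columns are left
empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class Component(str, Enum):
    """The five demographic components of change."""

    INTERNAL_MIGRATION = "internal_migration"
    MORTALITY = "mortality"
    FERTILITY = "fertility"
    IMMIGRATION = "immigration"
    EMIGRATION = "emigration"


SEXES = ("M", "F")


@dataclass(frozen=True)
class DimensionRegistry:
    """Registry of the cross-classifying dimensions of a population system.

    Parameters
    ----------
    regions
        Ordered region codes (n >= 2).
    age_groups
        Ordered lower bounds of 5-year age groups (0, 5, ..., 85); the last
        group is open-ended.
    years
        Ordered observation times with a constant step of 1 (annual) or 5
        (quinquennial).
    reproductive_window
        Pair of age-group *indices* (alpha, beta) bounding the reproductive
        ages, inclusive.
    """

    regions: tuple[str, ...]
    age_groups: tuple[int, ...]
    years: tuple[int, ...]
    reproductive_window: tuple[int, int]
    sexes: tuple[str, str] = SEXES

    def __post_init__(self):
        if len(self.regions) < 2:
            raise ValueError("at least two regions required")
        if len(self.regions) != len(set(self.regions)):
            raise ValueError("duplicate region codes")
        ages = np.asarray(self.age_groups)
        if ages.size < 2 or np.any(np.diff(ages) != 5):
            raise ValueError("age group bounds must increase in steps of 5")
        yrs = np.asarray(self.years)
        steps = np.diff(yrs)
        if yrs.size < 1 or (yrs.size > 1 and (np.any(steps != steps[0]) or steps[0] not in (1, 5))):
            raise ValueError("years must increase with a constant step of 1 or 5")
        a, b = self.reproductive_window
        if not (0 <= a <= b <= len(self.age_groups) - 1):
            raise ValueError("reproductive window indices out of range")

    # -- convenience ------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_ages(self) -> int:
        return len(self.age_groups)

    @property
    def year_step(self) -> int:
        yrs = self.years
        return int(yrs[1] - yrs[0]) if len(yrs) > 1 else 1

    @property
    def reproductive_ages(self) -> tuple[int, ...]:
        a, b = self.reproductive_window
        return tuple(self.age_groups[a : b + 1])

    def replace_years(self, years: Sequence[int]) -> "DimensionRegistry":
        return DimensionRegistry(
            self.regions, self.age_groups, tuple(int(y) for y in years),
            self.reproductive_window, self.sexes,
        )

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "age_groups": [int(a) for a in self.age_groups],
            "years": [int(y) for y in self.years],
            "reproductive_window": [int(i) for i in self.reproductive_window],
            "sexes": list(self.sexes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DimensionRegistry":
        return cls(
            tuple(d["regions"]),
            tuple(int(a) for a in d["age_groups"]),
            tuple(int(y) for y in d["years"]),
            tuple(d["reproductive_window"]),
            tuple(d.get("sexes", SEXES)),
        )


def component_dims(component: Component) -> list[str]:
    """Dimension columns that cross-classify a component's table."""
    component = Component(component)
    if component is Component.INTERNAL_MIGRATION:
        return ["origin", "destination", "age", "sex", "year"]
    if component is Component.FERTILITY:
        return ["region", "age", "year"]
    return ["region", "age", "sex", "year"]


def cell_grid(component: Component, registry: DimensionRegistry) -> pd.DataFrame:
    """Full cross-classified cell grid for a component (no counts)."""
    component = Component(component)
    dims = component_dims(component)
    levels = {}
    for d in dims:
        if d in ("origin", "destination", "region"):
            levels[d] = list(registry.regions)
        elif d == "age":
            if component is Component.FERTILITY:
                levels[d] = list(registry.reproductive_ages)
            else:
                levels[d] = [int(a) for a in registry.age_groups]
        elif d == "sex":
            levels[d] = list(registry.sexes)
        elif d == "year":
            levels[d] = [int(y) for y in registry.years]
    idx = pd.MultiIndex.from_product([levels[d] for d in dims], names=dims)
    grid = idx.to_frame(index=False)
    if component is Component.INTERNAL_MIGRATION:
        grid = grid[grid["origin"] != grid["destination"]].reset_index(drop=True)
    return grid


@dataclass
class ComponentTable:
    """A validated long-format table of counts and exposures for one component."""

    component: Component
    data: pd.DataFrame
    registry: DimensionRegistry

    def __post_init__(self):
        self.component = Component(self.component)
        self.data = _validate(self.component, self.data, self.registry)

    @property
    def dims(self) -> list[str]:
        return component_dims(self.component)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "component", self.component.value)
        if "origin" in out.columns:
            out = out.rename(columns={"origin": "origin"})
        else:
            out = out.rename(columns={"region": "origin"})
            out.insert(2, "destination", "")
        if "sex" not in out.columns:
            out.insert(out.columns.get_loc("year"), "sex", "")
        cols = ["component", "origin", "destination", "age", "sex", "year", "count", "exposure"]
        out[cols].to_csv(path, index=False)


def _validate(component: Component, df: pd.DataFrame, registry: DimensionRegistry) -> pd.DataFrame:
    dims = component_dims(component)
    missing = [c for c in dims + ["count", "exposure"] if c not in df.columns]
    if missing:
        raise ValueError(f"schema mismatch: missing columns {missing}")
    if component is Component.FERTILITY and "sex" in df.columns:
        raise ValueError("fertility restricted to females: sex column not allowed")
    df = df[dims + ["count", "exposure"]].copy()
    df["age"] = df["age"].astype(int)
    df["year"] = df["year"].astype(int)
    counts = df["count"].to_numpy()
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if np.any(counts != np.floor(counts)):
        raise ValueError("counts must be integers")
    if np.any(df["exposure"].to_numpy() <= 0):
        raise ValueError("non-positive exposures")
    if component is Component.IMMIGRATION and not np.allclose(df["exposure"], 1.0):
        raise ValueError("immigration exposure must be identically 1")

    # level checks
    for d in dims:
        if d in ("origin", "destination", "region"):
            extra = set(df[d]) - set(registry.regions)
        elif d == "age":
            ok = registry.reproductive_ages if component is Component.FERTILITY else registry.age_groups
            extra = set(df[d]) - set(int(a) for a in ok)
            if component is not Component.FERTILITY and (set(int(a) for a in ok) - set(df[d])):
                pass  # completeness handled below
        elif d == "sex":
            extra = set(df[d]) - set(registry.sexes)
        else:
            extra = set(df[d]) - set(int(y) for y in registry.years)
        if extra:
            if d == "age" and component is Component.FERTILITY and extra <= set(registry.age_groups):
                raise ValueError("fertility cells outside the reproductive window")
            raise ValueError(f"levels not in registry for {d}: {sorted(extra)}")

    if component is Component.INTERNAL_MIGRATION and np.any(df["origin"] == df["destination"]):
        raise ValueError("migration table must exclude diagonal (origin == destination) cells")

    if df.duplicated(subset=dims).any():
        raise ValueError("duplicate cells")
    grid = cell_grid(component, registry)
    merged = grid.merge(df, on=dims, how="left")
    if merged["count"].isna().any():
        raise ValueError(
            f"incomplete cross-classification: {int(merged['count'].isna().sum())} "
            f"missing cells for {component.value}"
        )
    if len(df) != len(grid):
        raise ValueError("incomplete cross-classification: extra cells present")
    return merged.reset_index(drop=True)


def read_component_table(
    path: str | Path, registry: DimensionRegistry, component: Component
) -> ComponentTable:
    """Read a long-format CSV (unified column layout) into a ComponentTable."""
    component = Component(component)
    raw = pd.read_csv(path, dtype={"origin": str, "destination": str, "sex": str})
    dims = component_dims(component)
    df = pd.DataFrame()
    if "origin" in dims:
        df["origin"] = raw["origin"]
        df["destination"] = raw["destination"]
    else:
        df["region"] = raw["origin"]
    df["age"] = raw["age"].astype(int)
    if "sex" in dims:
        df["sex"] = raw["sex"]
    df["year"] = raw["year"].astype(int)
    df["count"] = raw["count"]
    df["exposure"] = raw["exposure"]
    return ComponentTable(component, df, registry)


@dataclass
class BaselinePopulation:
    """Region x age x sex population at the baseline year, assumed error-free."""

    values: np.ndarray  # (n_regions, n_ages, 2)
    registry: DimensionRegistry
    year: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.registry.n_regions, self.registry.n_ages, 2)
        if self.values.shape != expect:
            raise ValueError(f"baseline population shape {self.values.shape} != {expect}")
        if np.any(self.values < 0):
            raise ValueError("negative baseline population")

    def to_frame(self) -> pd.DataFrame:
        reg = self.registry
        rows = []
        for i, r in enumerate(reg.regions):
            for a, x in enumerate(reg.age_groups):
                for s, sex in enumerate(reg.sexes):
                    rows.append((r, int(x), sex, int(self.year), self.values[i, a, s]))
        return pd.DataFrame(rows, columns=["region", "age", "sex", "year", "population"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, registry: DimensionRegistry) -> "BaselinePopulation":
        df = pd.read_csv(path, dtype={"region": str, "sex": str})
        year = int(df["year"].iloc[0])
        values = np.zeros((registry.n_regions, registry.n_ages, 2))
        ridx = {r: i for i, r in enumerate(registry.regions)}
        aidx = {int(a): i for i, a in enumerate(registry.age_groups)}
        sidx = {s: i for i, s in enumerate(registry.sexes)}
        for _, row in df.iterrows():
            values[ridx[row["region"]], aidx[int(row["age"])], sidx[row["sex"]]] = row["population"]
        return cls(values, registry, year)


def lag_exposure_for_migration(
    populations: pd.DataFrame, registry: DimensionRegistry
) -> pd.DataFrame:
    """Cohort-aligned exposures for quinquennial migration transition counts.

    A migrant recorded at terminal age group ``x`` for the interval
    ``(t-5, t]`` was at risk in the origin region five years earlier, at age
    ``x-5``.  Migrants recorded in the first age group were born during the
    interval; their exposure is the origin population of the first age group
    at the period start.

    Parameters
    ----------
    populations
        Long frame with columns ``region, age, sex, year, population``
        covering year ``t - 5`` for every migration observation year ``t``
        in ``registry.years``.

    Returns
    -------
    Frame with columns ``origin, age, sex, year, exposure``.
    """
    pop = populations.set_index(["region", "age", "sex", "year"])["population"]
    rows = []
    for t in registry.years:
        for r in registry.regions:
            for a_i, x in enumerate(registry.age_groups):
                lag_age = registry.age_groups[max(a_i - 1, 0)]
                for s in registry.sexes:
                    try:
                        k = float(pop.loc[(r, int(lag_age), s, int(t) - 5)])
                    except KeyError:
                        raise ValueError(
                            f"missing lagged population for year {int(t) - 5}"
                        ) from None
                    if k <= 0:
                        raise ValueError(
                            f"non-positive exposure for {r}, age {x}, {s}, year {t}"
                        )
                    rows.append((r, int(x), s, int(t), k))
    return pd.DataFrame(rows, columns=["origin", "age", "sex", "year", "exposure"])
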