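"""Deterministic multiregional cohort-component projection arithmetic.

The engine advances a region x age x sex population over five-year steps.
Per sex, age-specific matrices are built from the component rates:

* ``Sbar_x`` -- conditional survivorship proportions (rows: origin, columns:
  destination; row-stochastic), from interregional out-migration
  probabilities;
* ``Pbar_x = (Sbar_x + Sbar_{x-5}) / 2`` -- conditional transition
  probabilities (youngest group via ``(Sbar_0^2 + Sbar_0)/2``; oldest group
  equals ``Sbar_z``);
* ``P_x = Pbar_x P^DE_x`` -- un-conditioned on death and emigration through
  the diagonal adjustment
  ``P^DE_rr = (1 - 5/2 (d_r + e_r)) / (1 + 5/2 sum_k Pbar_rk (d_k + e_k))``;
* ``S_x = (I + P_{x+5}) P_x (I + P_x)^{-1}`` -- the survivorship matrix that
  moves age group x to x+5;
* ``S_{-5} = [I + (I + P_0)^{-1} (I - P_0)]^{-1}`` -- infant survivorship.

Populations are stacked as region vectors; births are split into sexes at a
fixed sex ratio at birth before sex-specific infant survivorship is applied.
Survivors of the open-ended terminal group advance with that group's own
transition-probability matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import BaselinePopulation, Component, DimensionRegistry

logger = logging.getLogger(__name__)

SRB_DEFAULT = 105.0  # males per 100 females


# ---------------------------------------------------------------------------
# matrix construction


def conditional_transitions(sbar: np.ndarray) -> np.ndarray:
    """Conditional transition probability matrices Pbar from Sbar.

    ``sbar`` has shape (z, n, n), indexed by the age group at the *start*
    of the interval; rows must be stochastic.
    """
    sbar = np.asarray(sbar, dtype=float)
    z = sbar.shape[0]
    if np.any(sbar < 0) or not np.allclose(sbar.sum(axis=2), 1.0):
        raise ValueError("Sbar rows must be non-negative and sum to 1")
    pbar = np.empty_like(sbar)
    pbar[0] = 0.5 * (sbar[0] @ sbar[0] + sbar[0])
    for a in range(1, z - 1):
        pbar[a] = 0.5 * (sbar[a] + sbar[a - 1])
    pbar[z - 1] = sbar[z - 1]
    return pbar


def uncondition(pbar_x: np.ndarray, d: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Un-condition one age's transition matrix on death and emigration."""
    pbar_x = np.asarray(pbar_x, dtype=float)
    d = np.asarray(d, dtype=float)
    e = np.asarray(e, dtype=float)
    de = d + e
    if np.any(2.5 * de >= 1.0):
        bad = np.where(2.5 * de >= 1.0)[0]
        raise ValueError(
            f"5/2 (d + e) >= 1 for region index {bad.tolist()}; "
            "rates too high for the linear person-years approximation"
        )
    num = 1.0 - 2.5 * de
    den = 1.0 + 2.5 * (pbar_x @ de)
    pde = num / den
    return pbar_x * pde[None, :]  # right-multiplication by diag(pde)


def survivorship(P_x: np.ndarray, P_x5: np.ndarray) -> np.ndarray:
    """S_x = (I + P_{x+5}) P_x (I + P_x)^{-1}."""
    n = P_x.shape[0]
    I = np.eye(n)
    return (I + P_x5) @ P_x @ np.linalg.inv(I + P_x)


def infant_survivorship(P_0: np.ndarray, M_0: np.ndarray | None = None) -> np.ndarray:
    """Survivorship of children born during the interval.

    Evaluates ``[I + (I + P_0)^{-1} (I - P_0)]^{-1}``; when an explicit
    matrix of first-age mortality rates ``M_0`` is supplied, the equivalent
    form ``(I + 5/2 M_0)^{-1}`` is used instead.
    """
    n = P_0.shape[0]
    I = np.eye(n)
    if M_0 is not None:
        return np.linalg.inv(I + 2.5 * np.asarray(M_0, dtype=float))
    return np.linalg.inv(I + np.linalg.inv(I + P_0) @ (I - P_0))


@dataclass
class MatrixSet:
    """Per-sex transition and survivorship matrices for every age group."""

    pbar: np.ndarray  # (z, n, n)
    P: np.ndarray  # (z, n, n)
    S: np.ndarray  # (z, n, n); S[a] moves a -> a+1, S[z-1] = P[z-1]
    S_minus5: np.ndarray  # (n, n)


def build_matrix_set(sbar: np.ndarray, d: np.ndarray, e: np.ndarray) -> MatrixSet:
    """Assemble the full matrix set for one sex.

    ``sbar``: (z, n, n) conditional survivorship proportions by start age;
    ``d``, ``e``: (n, z) annualised mortality and emigration rates.
    """
    sbar = np.asarray(sbar, dtype=float)
    z, n, _ = sbar.shape
    pbar = conditional_transitions(sbar)
    P = np.empty_like(pbar)
    for a in range(z):
        P[a] = uncondition(pbar[a], d[:, a], e[:, a])
    # Pbar/P are row-origin (the orientation the un-conditioning denominator
    # is written in); the survivorship sandwich acts on population column
    # vectors, so it is applied to the transposed (column-origin) matrices.
    At = P.transpose(0, 2, 1)
    S = np.empty_like(P)
    for a in range(z - 1):
        S[a] = survivorship(At[a], At[a + 1])
    S[z - 1] = At[z - 1]
    return MatrixSet(pbar, P, S, infant_survivorship(At[0]))


@dataclass
class ProjectionInputs:
    """Validated rate/count inputs for one five-year projection step."""

    sbar: dict  # sex -> (z, n, n)
    d: dict  # sex -> (n, z) annual mortality rates
    e: dict  # sex -> (n, z) annual emigration rates
    f: np.ndarray  # (n, z) annual fertility rates, zero outside [alpha, beta]
    G: np.ndarray  # (n, z, 2) immigrant counts per five-year interval
    srb: float = SRB_DEFAULT

    def validate(self, registry: DimensionRegistry) -> None:
        n, z = registry.n_regions, registry.n_ages
        a0, b0 = registry.reproductive_window
        for s in registry.sexes:
            sb = self.sbar[s]
            if sb.shape != (z, n, n) or np.any(sb < 0) or not np.allclose(sb.sum(axis=2), 1.0):
                raise ValueError("Sbar must be row-stochastic and non-negative")
            if np.any(self.d[s] < 0) or np.any(self.e[s] < 0):
                raise ValueError("mortality and emigration rates must be non-negative")
            if np.any(2.5 * (self.d[s] + self.e[s]) >= 1.0):
                raise ValueError("5/2 (d + e) must be below 1")
        if np.any(self.f < 0) or np.any(self.G < 0):
            raise ValueError("fertility rates and immigration counts must be non-negative")
        outside = np.ones(z, dtype=bool)
        outside[a0 : b0 + 1] = False
        if np.any(self.f[:, outside] != 0):
            raise ValueError("fertility rates outside the reproductive window must be zero")


def project_step(
    K_t: np.ndarray,
    mats: dict,
    f: np.ndarray,
    G: np.ndarray,
    registry: DimensionRegistry,
    srb: float = SRB_DEFAULT,
) -> np.ndarray:
    """One five-year step of the multiregional cohort-component model.

    Parameters
    ----------
    K_t
        (n, z, 2) population at the start of the interval.
    mats
        ``{sex: MatrixSet}`` built from the interval's rates.
    f
        (n, z) annual fertility rates (zero outside the reproductive window).
    G
        (n, z, 2) immigrant counts arriving during the interval.
    srb
        Sex ratio at birth, males per 100 females.
    """
    n, z = registry.n_regions, registry.n_ages
    K_t = np.asarray(K_t, dtype=float)
    out = np.zeros_like(K_t)
    sexes = list(registry.sexes)
    f_idx = sexes.index("F")

    for si, s in enumerate(sexes):
        S = mats[s].S
        for a in range(z - 1):
            out[:, a + 1, si] += S[a] @ (K_t[:, a, si] + 0.5 * G[:, a, si])
        out[:, z - 1, si] += S[z - 1] @ (K_t[:, z - 1, si] + 0.5 * G[:, z - 1, si])
        out[:, 1:, si] += 0.5 * G[:, 1:, si]

    # births: mothers aged x at t bear at rate f_x now and, after surviving
    # one step, at rate f_{x+5}
    SF = mats[sexes[f_idx]].S
    a0, b0 = registry.reproductive_window
    births = np.zeros(n)
    for a in range(a0, b0 + 1):
        B_a = np.diag(f[:, a])
        B_a5 = np.diag(f[:, a + 1]) if a + 1 < z else np.zeros((n, n))
        mothers = K_t[:, a, f_idx] + 0.5 * G[:, a, f_idx]
        births += (B_a + SF[a] @ B_a5) @ mothers
    births *= 2.5  # the 5/2 factor on annual rates

    male_share = srb / (srb + 100.0)
    for si, s in enumerate(sexes):
        share = male_share if s == "M" else 1.0 - male_share
        out[:, 0, si] = mats[s].S_minus5 @ (share * births) + 0.5 * G[:, 0, si]

    if np.any(out < 0):
        raise ValueError("negative projected population; invalid rate inputs")
    return out


# ---------------------------------------------------------------------------
# per-draw assembly from component forecasts


def _migration_sbar(cells: pd.DataFrame, values: np.ndarray, year: int, registry: DimensionRegistry):
    """Per-sex Sbar (z, n, n) from terminal-age out-migration probabilities.

    The probability recorded at terminal age group x applies to the cohort
    aged x-5 at the interval start; the open-ended group keeps its own
    terminal-age probabilities.
    """
    n, z = registry.n_regions, registry.n_ages
    ages = list(registry.age_groups)
    ridx = {r: i for i, r in enumerate(registry.regions)}
    sub = cells["year"].to_numpy() == year
    o = cells["origin"].map(ridx).to_numpy()[sub]
    dd = cells["destination"].map(ridx).to_numpy()[sub]
    a_term = cells["age"].map({a: i for i, a in enumerate(ages)}).to_numpy()[sub]
    sx = cells["sex"].map({s: i for i, s in enumerate(registry.sexes)}).to_numpy()[sub]
    vals = values[sub]
    out = {}
    for si, s in enumerate(registry.sexes):
        sbar = np.zeros((z, n, n))
        m = sx == si
        # start age = terminal age - 5 (cohort alignment); the open-ended
        # terminal group's probabilities also apply to its stayers
        start = a_term[m] - 1
        keep = start >= 0
        np.add.at(sbar, (start[keep], o[m][keep], dd[m][keep]), vals[m][keep])
        last = a_term[m] == z - 1
        np.add.at(
            sbar, (np.full(last.sum(), z - 1), o[m][last], dd[m][last]), vals[m][last]
        )
        rowsum = sbar.sum(axis=2)
        if np.any(rowsum >= 1.0):
            raise ValueError("aggregated out-migration probabilities reach 1")
        for a in range(z):
            sbar[a][np.arange(n), np.arange(n)] = 1.0 - rowsum[a]
        out[s] = sbar
    return out


def _rate_array(cells, values, years, registry, sex=None):
    """(n, z) array averaging annual forecasted rates over the interval years."""
    n, z = registry.n_regions, registry.n_ages
    ridx = {r: i for i, r in enumerate(registry.regions)}
    aidx = {a: i for i, a in enumerate(registry.age_groups)}
    sub = cells["year"].isin(years).to_numpy()
    if sex is not None:
        sub &= (cells["sex"] == sex).to_numpy()
    r = cells.loc[sub, cells.columns[0]].map(ridx).to_numpy()
    a = cells.loc[sub, "age"].map(aidx).to_numpy()
    out = np.zeros((n, z))
    np.add.at(out, (r, a), values[sub])
    return out / len(years)


@dataclass
class PopulationForecast:
    """Draw-indexed projected populations by region x age x sex x period."""

    values: np.ndarray  # (ndraw, n_periods, n, z, 2)
    years: list[int]
    registry: DimensionRegistry
    excluded_draws: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        reg = self.registry
        nd = self.values.shape[0]
        idx = pd.MultiIndex.from_product(
            [range(nd), self.years, reg.regions, reg.age_groups, reg.sexes],
            names=["draw", "year", "region", "age", "sex"],
        )
        return idx.to_frame(index=False).assign(population=self.values.ravel())

    def totals(self, by_region: bool = False) -> np.ndarray:
        """(ndraw, n_periods[, n]) summed populations."""
        if by_region:
            return self.values.sum(axis=(3, 4))
        return self.values.sum(axis=(2, 3, 4))


def project_horizon(
    K_t0: BaselinePopulation,
    rate_forecasts: dict,
    steps: int,
    registry: DimensionRegistry,
    srb: float = SRB_DEFAULT,
) -> PopulationForecast:
    """Run the projection for every posterior draw over `steps` intervals.

    ``rate_forecasts`` maps each :class:`Component` to its
    :class:`~mrpop.inference.RateForecast`; annual vital components are
    aggregated to quinquennial inputs (rates averaged, immigration counts
    summed) and migration forecasts are consumed on their native
    quinquennial grid.  Draws violating the un-conditioning precondition
    are excluded with a logged count.
    """
    comps = {Component(c): rf for c, rf in rate_forecasts.items()}
    nd = {c: rf.values.shape[0] for c, rf in comps.items()}
    if len(set(nd.values())) != 1:
        raise ValueError(f"forecast draw counts differ across components: {nd}")
    ndraw = next(iter(nd.values()))
    t0 = K_t0.year
    mig = comps[Component.INTERNAL_MIGRATION]
    periods = [t0 + 5 * (s + 1) for s in range(steps)]
    for p in periods:
        if p not in mig.years:
            raise ValueError(f"migration forecast missing period {p}")

    results = np.zeros((ndraw, steps + 1, registry.n_regions, registry.n_ages, 2))
    excluded = []
    for b in range(ndraw):
        K = K_t0.values.copy()
        results[b, 0] = K
        try:
            for s_i, p_end in enumerate(periods):
                interval_years = list(range(p_end - 4, p_end + 1))
                sbar = _migration_sbar(mig.cells, mig.values[b], p_end, registry)
                d = {
                    s: _rate_array(
                        comps[Component.MORTALITY].cells,
                        comps[Component.MORTALITY].values[b],
                        interval_years, registry, sex=s,
                    )
                    for s in registry.sexes
                }
                e = {
                    s: _rate_array(
                        comps[Component.EMIGRATION].cells,
                        comps[Component.EMIGRATION].values[b],
                        interval_years, registry, sex=s,
                    )
                    for s in registry.sexes
                }
                f = _rate_array(
                    comps[Component.FERTILITY].cells,
                    comps[Component.FERTILITY].values[b],
                    interval_years, registry,
                )
                G = np.stack(
                    [
                        _rate_array(
                            comps[Component.IMMIGRATION].cells,
                            comps[Component.IMMIGRATION].values[b],
                            interval_years, registry, sex=s,
                        )
                        * len(interval_years)  # counts are summed, not averaged
                        for s in registry.sexes
                    ],
                    axis=2,
                )
                mats = {s: build_matrix_set(sbar[s], d[s], e[s]) for s in registry.sexes}
                K = project_step(K, mats, f, G, registry, srb)
                results[b, s_i + 1] = K
        except ValueError:
            excluded.append(b)
    if excluded:
        logger.warning("excluded %d draws violating projection preconditions", len(excluded))
        keep = [b for b in range(ndraw) if b not in set(excluded)]
        results = results[keep]
    return PopulationForecast(results, [t0] + periods, registry, excluded)
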