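"""Synthetic multiregional demographic systems with known generative truths.

The generator emulates the structure of an eight-region national system
observed through quinquennial censuses and annual vital registration:
8 regions, 18 five-year age groups (0-4 ... 85+), two sexes, annual vital
series over 1981-2011, quinquennial migration transitions 1986-2011 (six
observations) and a 2004 definitional break in international migration.
Counts are drawn from the same Poisson-lognormal log-bilinear process the
models assume, so parameter-recovery tests are well-specified: baseline age
profiles are demographically shaped (Gompertz-like mortality, a bell-shaped
fertility schedule, labour-mobility humps for migration), per-component
intercepts sit at plausible levels, and the remaining effects and the kappa
paths are drawn from the model's own priors or dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _sampler
from .core_data import (
    BaselinePopulation,
    Component,
    ComponentTable,
    DimensionRegistry,
    cell_grid,
    lag_exposure_for_migration,
)
from .loglin import ModelSpec, constrain_bilinear_loadings, default_model_specs


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic system."""

    n_regions: int = 8
    n_ages: int = 18
    vital_years: tuple = tuple(range(1981, 2012))
    migration_years: tuple = tuple(range(1986, 2012, 5))
    break_year: int = 2004
    reproductive_window: tuple = (3, 9)  # age groups 15-19 ... 45-49
    exposure_scale: float = 1.0
    srb: float = 105.0
    overdispersion_sd: float = 0.05
    truth_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        a, b = self.reproductive_window
        if not (0 <= a <= b < self.n_ages):
            raise ValueError("reproductive window outside the age range")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1}" for i in range(self.n_regions))

    @property
    def age_groups(self) -> tuple[int, ...]:
        return tuple(5 * i for i in range(self.n_ages))

    def registry(self, component: Component) -> DimensionRegistry:
        years = (
            self.migration_years
            if Component(component) is Component.INTERNAL_MIGRATION
            else self.vital_years
        )
        return DimensionRegistry(
            self.regions, self.age_groups, tuple(int(y) for y in years),
            self.reproductive_window,
        )


# ---------------------------------------------------------------------------
# demographic baseline shapes (relative log profiles over age midpoints)


def _age_mid(cfg: GeneratorConfig) -> np.ndarray:
    return np.asarray(cfg.age_groups, dtype=float) + 2.5


def _mortality_log_profile(cfg: GeneratorConfig) -> np.ndarray:
    x = _age_mid(cfg)
    d = 3e-4 + 2.2e-5 * np.exp(0.098 * x)  # infant floor + Gompertz senescence
    d[0] = 1.2e-3
    return np.log(d)


def _fertility_log_profile(cfg: GeneratorConfig) -> np.ndarray:
    a0, b0 = cfg.reproductive_window
    x = _age_mid(cfg)[a0 : b0 + 1]
    f = 0.115 * np.exp(-(((x - 28.0) / 8.0) ** 2))
    return np.log(f)


def _mobility_log_profile(cfg: GeneratorConfig, base: float) -> np.ndarray:
    x = _age_mid(cfg)
    m = base * (0.45 + 1.8 * np.exp(-(((x - 24.0) / 13.0) ** 2)))
    return np.log(m)


def _profile_for(cfg: GeneratorConfig, component: Component) -> np.ndarray:
    """Absolute log-scale age schedule; its mean becomes the intercept truth."""
    component = Component(component)
    if component is Component.MORTALITY:
        return _mortality_log_profile(cfg)
    if component is Component.FERTILITY:
        return _fertility_log_profile(cfg)
    base = {
        Component.INTERNAL_MIGRATION: 0.008,  # 5-year out-migration probability
        Component.EMIGRATION: 0.003,  # annual emigration rate
        Component.IMMIGRATION: 250.0,  # annual immigrant count per cell
    }[component]
    return _mobility_log_profile(cfg, base)


def _truncnorm(rng, mean, sd, lo, hi):
    from scipy import stats

    return float(
        stats.truncnorm.rvs((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd,
                            random_state=rng)
    )


def _true_dynamics(dynamics: str, rng: np.random.Generator) -> dict:
    """Truth values for a kappa process, drawn from the model's own priors
    truncated to demographically plausible ranges.

    Coverage of posterior credible bands is only calibrated when truths are
    prior-consistent, so the autoregression and correlation truths follow
    their actual priors; drifts and innovation sds use the plausible core
    of theirs (full-width draws would produce exploding rate paths).
    """
    phi2 = _truncnorm(rng, 0.5, 0.2, 0.0, 0.95)
    sigma = _truncnorm(rng, 0.0, 1.0, 0.03, 0.15)  # half-normal core
    if dynamics == "ar1_drift":
        return {"phi1": rng.normal(0.0, 0.05), "phi2": phi2, "sigma": sigma}
    if dynamics == "ar1_nodrift":
        return {"phi1": 0.0, "phi2": phi2, "sigma": sigma}
    if dynamics == "rw_drift":
        return {"phi1": rng.normal(-0.1, 0.05), "phi2": 1.0, "sigma": sigma}
    rho = 2.0 * rng.beta(2.0, 2.0) - 1.0  # LKJ(2) marginal in the 2x2 case
    sigmas = np.array(
        [_truncnorm(rng, 0.0, 1.0, 0.03, 0.12), _truncnorm(rng, 0.0, 1.0, 0.03, 0.12)]
    )
    if dynamics == "mrw_drift":  # mortality: improvement drift for both sexes
        return {
            "phi1": np.array([rng.normal(-0.2, 0.04), rng.normal(-0.18, 0.04)]),
            "phi2": np.ones(2),
            "sigmas": sigmas,
            "rho": rho,
        }
    return {  # var1_drift
        "phi1": rng.normal(0.0, 0.05, 2),
        "phi2": np.array(
            [_truncnorm(rng, 0.5, 0.2, 0.0, 0.95), _truncnorm(rng, 0.5, 0.2, 0.0, 0.95)]
        ),
        "sigmas": sigmas,
        "rho": rho,
    }


def _dummy_table(component: Component, cfg: GeneratorConfig) -> ComponentTable:
    registry = cfg.registry(component)
    grid = cell_grid(component, registry)
    grid["count"] = 0
    grid["exposure"] = 1.0
    return ComponentTable(component, grid, registry)


def draw_true_parameters(
    cfg: GeneratorConfig, component: Component, rng: np.random.Generator
) -> dict:
    """A complete in-support truth set for the component's default model.

    Returns a state-shaped dict (``terms``, ``kappa``, ``dyn``, ``sigma``)
    with kappa paths simulated from the declared dynamics (anchored at
    zero), sum-to-one bilinear loadings, and symmetric origin-destination
    means.
    """
    component = Component(component)
    spec = default_model_specs(component, cfg.break_year)
    bm = _sampler.BoundModel(spec, _dummy_table(component, cfg), cfg.registry(component))
    profile = _profile_for(cfg, component)
    intercept = float(profile.mean())
    profile = profile - profile.mean()

    truths: dict = {"terms": {}, "kappa": {}, "dyn": {}, "sigma": cfg.overdispersion_sd}
    for name, bt in bm.terms.items():
        t = bt.spec
        if t.kind == "intercept":
            truths["terms"][name] = np.array([intercept])
        elif t.kind == "bilinear_loading":
            L = bt.size
            cov = np.linalg.inv(np.eye(L - 1) + np.ones((L - 1, L - 1))) / L**2
            if bt.paired:
                rows = [
                    constrain_bilinear_loadings(
                        rng.multivariate_normal(np.full(L - 1, 1.0 / L), cov)
                    )
                    for _ in range(2)
                ]
                truths["terms"][name] = np.stack(rows)
            else:
                u = rng.multivariate_normal(np.full(L - 1, 1.0 / L), cov)
                truths["terms"][name] = constrain_bilinear_loadings(u)
        elif name == "A1":
            truths["terms"][name] = profile - profile.mean() + rng.normal(0, 0.08, bt.size)
        elif name == "AS1":
            base = profile - profile.mean()
            vals = np.empty(bt.size)
            for li, key in enumerate(bt.level_keys):
                age, sex = key
                ai = bm.ages.index(age)
                shift = 0.15 if (sex == "M" and component is Component.MORTALITY) else 0.0
                vals[li] = base[ai] + shift + rng.normal(0, 0.08)
            truths["terms"][name] = vals
        elif t.prior.family == "symmetric_od_normal":
            n = cfg.n_regions
            alpha = rng.normal(0, 0.4, n * (n - 1) // 2)
            truths["terms"][name] = alpha[bt.pair_index] + rng.normal(0, 0.15, bt.size)
            truths["od_alpha"] = alpha
        elif t.kind == "break_indicator":
            truths["terms"][name] = rng.normal(0.0, 0.2, bt.size)
        elif t.kind == "main":
            truths["terms"][name] = rng.normal(0, 0.3, bt.size)
        else:  # interactions
            truths["terms"][name] = rng.normal(0, 0.1, bt.size)

    for k in spec.kappas:
        dyn = _true_dynamics(k.dynamics, rng)
        T = bm.T
        kap = np.zeros((k.n_series, T))
        if k.n_series == 1:
            for t in range(1, T):
                kap[0, t] = dyn["phi1"] + dyn["phi2"] * kap[0, t - 1] + dyn[
                    "sigma"
                ] * rng.standard_normal()
        else:
            sM, sF = dyn["sigmas"]
            rho = dyn["rho"]
            Lc = np.array([[sM, 0.0], [rho * sF, sF * np.sqrt(1 - rho**2)]])
            for t in range(1, T):
                kap[:, t] = (
                    dyn["phi1"] + dyn["phi2"] * kap[:, t - 1] + Lc @ rng.standard_normal(2)
                )
        truths["kappa"][k.name] = kap
        truths["dyn"][k.name] = dyn

    overrides = cfg.truth_overrides.get(component.value, {})
    for key, val in overrides.items():
        truths[key] = val
    return truths


def simulate_component_table(
    truths: dict,
    cfg: GeneratorConfig,
    exposures: pd.DataFrame,
    rng: np.random.Generator,
    component: Component,
) -> ComponentTable:
    """Draw a table from the generative model: log mu ~ N(M, sigma^2), Y ~ Poisson(mu K)."""
    component = Component(component)
    registry = cfg.registry(component)
    spec = default_model_specs(component, cfg.break_year)
    grid = cell_grid(component, registry)
    dims = [c for c in exposures.columns if c != "exposure"]
    grid = grid.merge(exposures, on=dims, how="left")
    if grid["exposure"].isna().any():
        raise ValueError("exposures do not cover the full cell grid")
    grid["count"] = 0
    table0 = ComponentTable(component, grid, registry)
    bm = _sampler.BoundModel(spec, table0, registry)
    M = bm.compute_M(truths)
    sigma = float(truths["sigma"])
    log_mu = M + sigma * rng.standard_normal(bm.N)
    lam = np.exp(log_mu) * bm.K
    counts = rng.poisson(lam)
    out = table0.data.copy()
    out["count"] = counts
    return ComponentTable(component, out, registry)


# ---------------------------------------------------------------------------
# the coherent full system


def _population_surface(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Smooth region x age x sex x year mid-year populations (persons)."""
    x = _age_mid(cfg)
    # declining-exponential pyramid with a young-adult hump
    shape = np.exp(-0.018 * x) * (1.0 + 0.35 * np.exp(-(((x - 30.0) / 16.0) ** 2)))
    shape /= shape.sum()
    base = np.array([7.2, 5.6, 4.5, 1.7, 2.4, 0.51, 0.23, 0.37]) * 1e6
    if cfg.n_regions <= base.size:
        region_scale = base[: cfg.n_regions]
    else:
        region_scale = np.concatenate(
            [base, np.full(cfg.n_regions - base.size, 4e5)]
        )
    region_scale = region_scale * cfg.exposure_scale
    y0 = cfg.vital_years[0]
    rows = []
    for ri, r in enumerate(cfg.regions):
        for ai, a in enumerate(cfg.age_groups):
            for si, s in enumerate(("M", "F")):
                sexf = 0.5 + (0.004 if s == "F" else -0.004)
                for y in cfg.vital_years:
                    pop = region_scale[ri] * shape[ai] * sexf * 1.013 ** (y - y0)
                    rows.append((r, int(a), s, int(y), pop))
    return pd.DataFrame(rows, columns=["region", "age", "sex", "year", "population"])


def make_full_fixture(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    """All five component tables, a baseline population and the truth bundle.

    Exposures for every component derive from one shared population surface,
    so the system is internally consistent; immigration exposures are
    identically 1 (counts are modelled directly).
    """
    pops = _population_surface(cfg, rng)
    truths = {}
    tables = {}

    for component in Component:
        truths[component.value] = draw_true_parameters(cfg, component, rng)

    pop_idx = pops.set_index(["region", "age", "sex", "year"])["population"]

    for component in Component:
        registry = cfg.registry(component)
        grid = cell_grid(component, registry)
        if component is Component.INTERNAL_MIGRATION:
            mig_reg = registry
            exp_df = lag_exposure_for_migration(pops, mig_reg)
        elif component is Component.IMMIGRATION:
            exp_df = grid.copy()
            exp_df["exposure"] = 1.0
        elif component is Component.FERTILITY:
            exp_df = grid.copy()
            exp_df["exposure"] = [
                pop_idx.loc[(r, a, "F", y)]
                for r, a, y in zip(exp_df["region"], exp_df["age"], exp_df["year"])
            ]
        else:
            exp_df = grid.copy()
            exp_df["exposure"] = [
                pop_idx.loc[(r, a, s, y)]
                for r, a, s, y in zip(
                    exp_df["region"], exp_df["age"], exp_df["sex"], exp_df["year"]
                )
            ]
        exp_df = exp_df[[c for c in exp_df.columns if c not in ("count",)]]
        tables[component.value] = simulate_component_table(
            truths[component.value], cfg, exp_df, rng, component
        )

    base_year = int(cfg.vital_years[-1])
    n, z = cfg.n_regions, cfg.n_ages
    baseline = np.zeros((n, z, 2))
    for ri, r in enumerate(cfg.regions):
        for ai, a in enumerate(cfg.age_groups):
            for si, s in enumerate(("M", "F")):
                baseline[ri, ai, si] = pop_idx.loc[(r, int(a), s, base_year)]
    baseline_pop = BaselinePopulation(baseline, cfg.registry(Component.MORTALITY), base_year)

    return {
        "tables": tables,
        "baseline": baseline_pop,
        "truths": truths,
        "populations": pops,
        "config": cfg,
    }


def save_truths(truths: dict, path: str | Path) -> None:
    def conv(obj):
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return float(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(conv(truths)))


def write_fixture(fixture: dict, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, table in fixture["tables"].items():
        table.write_csv(directory / f"{name}.csv")
    fixture["baseline"].write_csv(directory / "baseline_population.csv")
    save_truths(fixture["truths"], directory / "truths.yaml")
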