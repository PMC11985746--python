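"""Fitting, posterior-predictive forecasting and log-linear model screening.

``fit_component`` runs the in-package blocked Gibbs/Metropolis sampler (see
``_sampler``) over a component's Poisson-lognormal log-bilinear model and
returns :class:`PosteriorDraws` with split-R-hat / effective-sample-size
diagnostics.  ``forecast_component`` propagates each posterior draw through
the fitted time-series processes and rebuilds the predictor for future
periods; forecasted rates include the lognormal overdispersion draw but no
Poisson sampling (count-level variability is deliberately excluded from the
forecasts).  ``select_model`` is the maximum-likelihood screening harness
for simplified (bilinear-free) log-linear candidates, scored by RMSE of
log-rate residuals and BIC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _sampler
from .core_data import Component, ComponentTable, DimensionRegistry, cell_grid
from .loglin import ModelSpec

RHAT_THRESHOLD = 1.01


@dataclass
class MCMCConfig:
    """Sampler settings; the seed makes runs exactly reproducible."""

    chains: int = 2
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    target_accept: float = 0.44  # reference acceptance for the latent-lm RW step

    def __post_init__(self):
        if min(self.chains, self.warmup, self.samples) <= 0:
            raise ValueError("chains, warmup and samples must be positive")


@dataclass
class PosteriorDraws:
    """Posterior draws of every model block, stacked over chains."""

    component: Component
    spec: ModelSpec
    registry: DimensionRegistry
    years: list[int]
    n_chains: int
    terms: dict[str, np.ndarray]  # name -> (ndraw, L) or (ndraw, 2, L)
    hier_sd: dict[str, np.ndarray]
    od: dict[str, np.ndarray]
    kappa: dict[str, np.ndarray]  # name -> (ndraw, n_series, T)
    dyn: dict[str, dict[str, np.ndarray]]
    sigma: np.ndarray
    level_keys: dict[str, list]
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.sigma.size

    def to_frame(self) -> pd.DataFrame:
        """Flat named-parameter table: one row per draw, one column per scalar.

        Columns are e.g. ``A1[15]``, ``AS2[M|85]``, ``kappa_age[1995]``,
        ``kappa_as.phi1[M]``, ``sigma`` -- convenient for inspection and
        external tooling.
        """
        cols: dict[str, np.ndarray] = {"chain": np.repeat(
            np.arange(self.n_chains), self.n_draws // self.n_chains
        ), "draw": np.tile(
            np.arange(self.n_draws // self.n_chains), self.n_chains
        )}
        for name, vals in self.terms.items():
            keys = self.level_keys[name]
            if vals.ndim == 3:  # sex-paired loading (ndraw, 2, L)
                for si, sex in enumerate(self.registry.sexes):
                    for li, key in enumerate(keys):
                        label = "|".join(str(k) for k in key)
                        cols[f"{name}[{sex}|{label}]"] = vals[:, si, li]
            else:
                for li, key in enumerate(keys):
                    label = "|".join(str(k) for k in key)
                    cols[f"{name}[{label}]" if key else name] = vals[:, li]
        for name, sd in self.hier_sd.items():
            cols[f"sd({name})"] = sd
        if self.od:
            for pi in range(self.od["alpha"].shape[1]):
                cols[f"od_alpha[{pi}]"] = self.od["alpha"][:, pi]
            cols["sigma_od"] = self.od["sigma_od"]
        for name, kap in self.kappa.items():
            ns = kap.shape[1]
            for q in range(ns):
                tag = self.registry.sexes[q] if ns == 2 else None
                for ti, year in enumerate(self.years):
                    label = f"{tag}|{year}" if tag else str(year)
                    cols[f"{name}[{label}]"] = kap[:, q, ti]
        for name, dyn in self.dyn.items():
            for p, vals in dyn.items():
                if vals.ndim == 1:
                    cols[f"{name}.{p}"] = vals
                else:
                    for q in range(vals.shape[1]):
                        cols[f"{name}.{p}[{self.registry.sexes[q]}]"] = vals[:, q]
        cols["sigma"] = self.sigma
        return pd.DataFrame(cols)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path, name: str | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        name = name or self.component.value
        payload = {
            "component": self.component.value,
            "spec": self.spec.to_dict(),
            "registry": self.registry.to_dict(),
            "years": [int(y) for y in self.years],
            "n_chains": self.n_chains,
            "terms": {k: v.tolist() for k, v in self.terms.items()},
            "hier_sd": {k: v.tolist() for k, v in self.hier_sd.items()},
            "od": {k: v.tolist() for k, v in self.od.items()},
            "kappa": {k: v.tolist() for k, v in self.kappa.items()},
            "dyn": {
                k: {p: v.tolist() for p, v in d.items()} for k, d in self.dyn.items()
            },
            "sigma": self.sigma.tolist(),
            "level_keys": {k: [list(t) for t in v] for k, v in self.level_keys.items()},
            "diagnostics": _jsonify(self.diagnostics),
        }
        path = directory / f"{name}_draws.json"
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        d = json.loads(Path(path).read_text())
        return cls(
            component=Component(d["component"]),
            spec=ModelSpec.from_dict(d["spec"]),
            registry=DimensionRegistry.from_dict(d["registry"]),
            years=[int(y) for y in d["years"]],
            n_chains=d["n_chains"],
            terms={k: np.asarray(v) for k, v in d["terms"].items()},
            hier_sd={k: np.asarray(v) for k, v in d["hier_sd"].items()},
            od={k: np.asarray(v) for k, v in d["od"].items()},
            kappa={k: np.asarray(v) for k, v in d["kappa"].items()},
            dyn={
                k: {p: np.asarray(v) for p, v in dd.items()} for k, dd in d["dyn"].items()
            },
            sigma=np.asarray(d["sigma"]),
            level_keys={k: [tuple(t) for t in v] for k, v in d["level_keys"].items()},
            diagnostics=d.get("diagnostics", {}),
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj


@dataclass
class RateForecast:
    """Per-draw forecasted rates/probabilities/counts on the native scale."""

    component: Component
    cells: pd.DataFrame  # future cell grid (dims only)
    values: np.ndarray  # (ndraw, n_cells), strictly positive
    registry: DimensionRegistry

    def __post_init__(self):
        if np.any(self.values <= 0):
            raise ValueError("forecasted rates must be strictly positive")

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.cells["year"].unique())

    def to_frame(self) -> pd.DataFrame:
        nd = self.values.shape[0]
        out = pd.concat([self.cells] * nd, ignore_index=True)
        out.insert(0, "draw", np.repeat(np.arange(nd), len(self.cells)))
        out["value"] = self.values.ravel()
        return out

    def save(self, directory: str | Path, name: str | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        name = name or self.component.value
        path = directory / f"{name}_forecast.csv"
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def load(
        cls, path: str | Path, registry: DimensionRegistry, component: Component
    ) -> "RateForecast":
        df = pd.read_csv(path, dtype={"origin": str, "destination": str, "region": str, "sex": str})
        dims = [c for c in df.columns if c not in ("draw", "value")]
        nd = int(df["draw"].max()) + 1
        cells = df[df["draw"] == 0][dims].reset_index(drop=True)
        values = df["value"].to_numpy().reshape(nd, len(cells))
        return cls(Component(component), cells, values, registry)


# ---------------------------------------------------------------------------
# fitting


def fit_component(
    spec: ModelSpec, table: ComponentTable, cfg: MCMCConfig
) -> PosteriorDraws:
    """Fit one component model by MCMC and return stacked posterior draws."""
    bm = _sampler.BoundModel(spec, table, table.registry)
    state0 = bm.init_state()
    if not np.isfinite(bm.log_posterior(state0)):
        raise RuntimeError("non-finite likelihood at initialisation")

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    chains_store: list[dict] = []
    acc_rates = []
    for c in range(cfg.chains):
        rng = np.random.default_rng(seeds[c])
        state = bm.init_state(rng, init_style=c % 3)
        store = _empty_store(bm, cfg.samples)
        accs = []
        for it in range(cfg.warmup + cfg.samples):
            acc = _sampler.gibbs_sweep(bm, state, rng)
            if it >= cfg.warmup:
                accs.append(acc)
                _record(bm, state, store, it - cfg.warmup)
        chains_store.append(store)
        acc_rates.append(float(np.mean(accs)))

    draws = _stack_chains(bm, chains_store)
    diagnostics = _diagnose(bm, chains_store, acc_rates)
    level_keys = {name: bt.level_keys for name, bt in bm.terms.items()}
    return PosteriorDraws(
        component=table.component,
        spec=spec,
        registry=table.registry,
        years=bm.years,
        n_chains=cfg.chains,
        level_keys=level_keys,
        diagnostics=diagnostics,
        **draws,
    )


def _empty_store(bm, n):
    store = {"terms": {}, "hier_sd": {}, "od": {}, "kappa": {}, "dyn": {}, "sigma": np.empty(n)}
    st0 = bm.init_state()
    for k, v in st0["terms"].items():
        store["terms"][k] = np.empty((n,) + np.shape(v))
    for k in st0["hier_sd"]:
        store["hier_sd"][k] = np.empty(n)
    if st0["od"]:
        store["od"]["alpha"] = np.empty((n,) + st0["od"]["alpha"].shape)
        store["od"]["sigma_od"] = np.empty(n)
    for k, v in st0["kappa"].items():
        store["kappa"][k] = np.empty((n,) + v.shape)
    for k, d in st0["dyn"].items():
        store["dyn"][k] = {p: np.empty((n,) + np.shape(val)) for p, val in d.items()}
    return store


def _record(bm, state, store, i):
    for k, v in state["terms"].items():
        store["terms"][k][i] = v
    for k, v in state["hier_sd"].items():
        store["hier_sd"][k][i] = v
    if state["od"]:
        store["od"]["alpha"][i] = state["od"]["alpha"]
        store["od"]["sigma_od"][i] = state["od"]["sigma_od"]
    for k, v in state["kappa"].items():
        store["kappa"][k][i] = v
    for k, d in state["dyn"].items():
        for p, val in d.items():
            store["dyn"][k][p][i] = val
    store["sigma"][i] = state["sigma"]


def _stack_chains(bm, chains_store):
    out = {"terms": {}, "hier_sd": {}, "od": {}, "kappa": {}, "dyn": {}}
    first = chains_store[0]
    for k in first["terms"]:
        out["terms"][k] = np.concatenate([cs["terms"][k] for cs in chains_store])
    for k in first["hier_sd"]:
        out["hier_sd"][k] = np.concatenate([cs["hier_sd"][k] for cs in chains_store])
    for k in first["od"]:
        out["od"][k] = np.concatenate([cs["od"][k] for cs in chains_store])
    for k in first["kappa"]:
        out["kappa"][k] = np.concatenate([cs["kappa"][k] for cs in chains_store])
    for k in first["dyn"]:
        out["dyn"][k] = {
            p: np.concatenate([cs["dyn"][k][p] for cs in chains_store])
            for p in first["dyn"][k]
        }
    out["sigma"] = np.concatenate([cs["sigma"] for cs in chains_store])
    return out


def _diagnose(bm, chains_store, acc_rates):
    import arviz as az

    monitored = {"sigma": np.stack([cs["sigma"] for cs in chains_store])}
    for k in chains_store[0]["kappa"]:
        arr = np.stack([cs["kappa"][k] for cs in chains_store])  # (chain, draw, ns, T)
        ns, T = arr.shape[2], arr.shape[3]
        for q in range(ns):
            monitored[f"{k}[{q},mid]"] = arr[:, :, q, T // 2]
            monitored[f"{k}[{q},last]"] = arr[:, :, q, T - 1]
    rhat = {}
    ess = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in monitored.items():
            if arr.shape[0] < 2:
                rhat[name] = float("nan")
            else:
                rhat[name] = float(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"].values))
            ess[name] = float(np.asarray(az.ess(az.convert_to_dataset(arr))["x"].values))
    warn = [
        f"split-Rhat {v:.3f} > {RHAT_THRESHOLD} for {k}"
        for k, v in rhat.items()
        if np.isfinite(v) and v > RHAT_THRESHOLD
    ]
    return {
        "rhat": rhat,
        "ess": ess,
        "lm_acceptance": acc_rates,
        "warnings": warn,
    }


# ---------------------------------------------------------------------------
# forecasting


def forecast_component(
    draws: PosteriorDraws,
    spec: ModelSpec,
    horizon_periods: list[int],
    rng: np.random.Generator,
) -> RateForecast:
    """Per-draw forecasts of mu for every cell in the horizon periods.

    Non-time parameters are held at their posterior values; kappa paths are
    simulated forward from their fitted dynamics; lognormal noise N(0, sigma^2)
    is added on the log scale (no Poisson sampling).
    """
    years = draws.years
    if len(years) > 1:
        step = years[1] - years[0]
    else:
        step = 5 if draws.component is Component.INTERNAL_MIGRATION else 1
    horizon_periods = [int(y) for y in horizon_periods]
    expected = [years[-1] + step * (h + 1) for h in range(len(horizon_periods))]
    if horizon_periods != expected:
        raise ValueError(
            f"horizon {horizon_periods} does not extend the observed grid {years} "
            f"(expected {expected})"
        )
    H = len(horizon_periods)
    nd = draws.n_draws
    kfut = _forecast_kappas(draws, spec, H, rng)

    reg_f = draws.registry.replace_years(horizon_periods)
    cells = cell_grid(draws.component, reg_f)
    M = _predictor_matrix(draws, spec, cells, kfut, horizon_periods)
    noise = rng.standard_normal(M.shape) * draws.sigma[:, None]
    mu = np.exp(M + noise)
    return RateForecast(draws.component, cells, mu, draws.registry)


def _forecast_kappas(draws, spec, H, rng):
    out = {}
    nd = draws.n_draws
    for k in spec.kappas:
        kap = draws.kappa[k.name]  # (nd, ns, T)
        ns = kap.shape[1]
        dyn = draws.dyn[k.name]
        paths = np.empty((nd, ns, H))
        if ns == 1:
            if k.dynamics == "ar1_nodrift":
                phi1 = np.zeros(nd)
            else:
                phi1 = dyn["phi1"].reshape(nd)
            phi2 = np.ones(nd) if k.dynamics == "rw_drift" else dyn["phi2"].reshape(nd)
            sig = dyn["sigma"].reshape(nd)
            cur = kap[:, 0, -1].copy()
            for h in range(H):
                cur = phi1 + phi2 * cur + sig * rng.standard_normal(nd)
                paths[:, 0, h] = cur
        else:
            phi1 = dyn["phi1"].reshape(nd, 2)
            phi2 = (
                np.ones((nd, 2))
                if k.dynamics == "mrw_drift"
                else dyn["phi2"].reshape(nd, 2)
            )
            sM = dyn["sigmas"][:, 0]
            sF = dyn["sigmas"][:, 1]
            rho = dyn["rho"].reshape(nd)
            cur = kap[:, :, -1].copy()
            for h in range(H):
                z = rng.standard_normal((nd, 2))
                noise = np.empty((nd, 2))
                noise[:, 0] = sM * z[:, 0]
                noise[:, 1] = sF * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
                cur = phi1 + phi2 * cur + noise
                paths[:, :, h] = cur
        out[k.name] = paths
    return out


def _predictor_matrix(draws, spec, cells, kfut, horizon_periods):
    """(ndraw, n_future_cells) log-scale predictor from posterior draws."""
    nd = draws.n_draws
    Nf = len(cells)
    year_pos = {y: i for i, y in enumerate(horizon_periods)}
    t_idx = cells["year"].map(year_pos).to_numpy()
    sexes = list(draws.registry.sexes)
    s_idx = cells["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy() if "sex" in cells else np.zeros(Nf, dtype=int)
    M = np.zeros((nd, Nf))
    for term in spec.terms:
        vals = draws.terms[term.name]
        kspec = spec.kappa(term.kappa) if term.kappa else None
        paired = kspec is not None and kspec.dimension == "sex_paired"
        if paired:
            other = tuple(d for d in term.dims if d != "sex")
            keys = {k: i for i, k in enumerate(draws.level_keys[term.name])}
            idx = np.array(
                [keys[tuple(row)] for row in cells[list(other)].itertuples(index=False)]
            ) if other else np.zeros(Nf, dtype=int)
            contrib = vals[:, s_idx, idx] * kfut[term.kappa][:, s_idx, t_idx]
        else:
            if term.dims:
                keys = {k: i for i, k in enumerate(draws.level_keys[term.name])}
                idx = np.array(
                    [keys[tuple(row)] for row in cells[list(term.dims)].itertuples(index=False)]
                )
            else:
                idx = np.zeros(Nf, dtype=int)
            contrib = vals[:, idx]
            if term.kind == "bilinear_loading":
                contrib = contrib * kfut[term.kappa][:, 0, t_idx]
            elif term.kind == "break_indicator":
                mask = (cells["year"].to_numpy() >= term.break_year).astype(float)
                contrib = contrib * mask[None, :]
        M += contrib
    return M


# ---------------------------------------------------------------------------
# log-linear model screening (simplified, no bilinear terms)


def simplify_spec(spec: ModelSpec) -> ModelSpec:
    """Strip bilinear terms (and their kappas) from a model specification."""
    terms = [t for t in spec.terms if t.kind != "bilinear_loading"]
    return ModelSpec(spec.component, terms, [], spec.overdispersion_prior)


def candidate_ladder(component: Component) -> list[ModelSpec]:
    """A nested ladder of simplified log-linear candidates for screening."""
    from .loglin import default_model_specs

    base = simplify_spec(default_model_specs(component))
    specs = []
    for k in range(1, len(base.terms) + 1):
        specs.append(ModelSpec(base.component, base.terms[:k], []))
    return specs


def select_model(candidates: list[ModelSpec], table: ComponentTable) -> pd.DataFrame:
    """Poisson GLM screening of bilinear-free candidates.

    Each candidate is fit by maximum likelihood with a log-exposure offset.
    RMSE is computed on log-rate residuals ``log(Y/K) - M_hat`` over cells
    with positive counts; ``BIC = -2 loglik + p log(n_cells)`` with p the
    rank of the design.
    """
    import statsmodels.api as sm

    rows = []
    for ci, cand in enumerate(candidates):
        if any(t.kind == "bilinear_loading" for t in cand.terms):
            raise ValueError("candidates must be simplified (no bilinear terms)")
        bm = _sampler.BoundModel(cand, table, table.registry)
        X = _design_matrix(bm)
        p = int(np.linalg.matrix_rank(X))
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(bm.Y, X, family=sm.families.Poisson(), offset=bm.logK)
                res = model.fit(maxiter=200, tol=1e-10)
            converged = bool(getattr(res, "converged", True))
            eta = X @ res.params
            llf = float(res.llf)
        except Exception:
            converged = False
            eta = np.full(bm.N, np.nan)
            llf = np.nan
        pos = bm.Y > 0
        resid = np.log(bm.Y[pos] / bm.K[pos]) - eta[pos]
        rmse = float(np.sqrt(np.mean(resid**2)))
        bic = float(-2.0 * llf + p * np.log(bm.N))
        name = "+".join(t.name for t in cand.terms) or f"m{ci + 1}"
        rows.append({"name": name, "rmse": rmse, "bic": bic, "p": p, "converged": converged})
    return pd.DataFrame(rows)


def _design_matrix(bm: _sampler.BoundModel) -> np.ndarray:
    cols = []
    for name, bt in bm.terms.items():
        w = bm.term_weight(name, {"terms": {}, "kappa": {}})
        onehot = np.zeros((bm.N, bt.size))
        onehot[np.arange(bm.N), bt.index] = w
        cols.append(onehot)
    return np.hstack(cols)
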