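"""Blocked Metropolis-within-Gibbs sampler for Poisson-lognormal log-bilinear models.

The posterior factorises conveniently once the per-cell latent log-rates
``lm = log mu`` are treated as parameters (the augmented likelihood):

* given ``lm``, every linear block (intercept, interactions, main effects,
  break indicators, origin-destination means) has a Gaussian full
  conditional, as do the free elements of the sum-to-one bilinear loadings
  and the kappa paths -- these are drawn exactly (Gibbs);
* ``lm`` itself has a log-concave univariate conditional per cell
  (Poisson x normal) and is updated with a vectorised random-walk
  Metropolis step whose proposal scale tracks the local curvature
  (with the corresponding Hastings correction);
* scale and correlation parameters (overdispersion sd, hierarchical sds,
  innovation sds, the LKJ-distributed correlation) are updated by
  univariate slice sampling.

All hard constraints (kappa_1 = 0 per series, loading vectors summing to
one, symmetric origin-destination means) hold exactly in every draw by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import Component, ComponentTable, DimensionRegistry
from .dynamics import KappaSpec, PHI1_SD, PHI2_MEAN, PHI2_SD, LKJ_ETA
from .loglin import ModelSpec, TermSpec

_EXP_CAP = 60.0  # cap on exponents to keep lambda = K exp(lm) finite


def _safe_exp(x):
    return np.exp(np.minimum(x, _EXP_CAP))


# ---------------------------------------------------------------------------
# slice sampler


def slice_sample(
    x0: float,
    logp,
    rng: np.random.Generator,
    w: float = 0.5,
    lower: float = -np.inf,
    upper: float = np.inf,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampling with stepping out and shrinkage."""
    f0 = logp(x0)
    logy = f0 - rng.exponential()
    L = x0 - w * rng.uniform()
    R = L + w
    j = int(np.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and L > lower and logp(L) > logy:
        L -= w
        j -= 1
    while k > 0 and R < upper and logp(R) > logy:
        R += w
        k -= 1
    L = max(L, lower)
    R = min(R, upper)
    for _ in range(200):
        x1 = L + (R - L) * rng.uniform()
        if logp(x1) > logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0  # pathological shrinkage; keep current value


from functools import lru_cache
from math import lgamma


@lru_cache(maxsize=16)
def _half_t_const(df: float, scale: float) -> float:
    return (
        np.log(2.0)
        + lgamma((df + 1.0) / 2.0)
        - lgamma(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )


def _half_t_logpdf(s: float, df: float, scale: float) -> float:
    if s <= 0:
        return -np.inf
    return float(
        _half_t_const(df, scale) - (df + 1.0) / 2.0 * np.log1p((s / scale) ** 2 / df)
    )


# ---------------------------------------------------------------------------
# bound model


@dataclass
class BoundTerm:
    spec: TermSpec
    size: int  # number of parameter levels (free + constrained)
    index: np.ndarray  # (N,) level index per cell
    level_keys: list  # level tuples in index order
    weight: np.ndarray | None = None  # fixed multiplier per cell (break terms)
    pair_index: np.ndarray | None = None  # level -> unordered-pair index (OD terms)
    n_pairs: int = 0
    paired: bool = False  # loading paired with a sex-paired kappa
    sex_code: np.ndarray | None = None
    cells_by_level: list = field(default_factory=list)


class BoundModel:
    """A ModelSpec bound to one ComponentTable: index arrays and state logic."""

    def __init__(self, spec: ModelSpec, table: ComponentTable, registry: DimensionRegistry):
        if Component(spec.component) is not table.component:
            raise ValueError("spec component does not match table component")
        self.spec = spec
        self.registry = registry
        self.component = table.component
        df = table.data
        self.Y = df["count"].to_numpy(dtype=float)
        self.K = df["exposure"].to_numpy(dtype=float)
        self.logK = np.log(self.K)
        self.N = len(df)

        self.years = sorted(int(y) for y in df["year"].unique())
        self.T = len(self.years)
        year_pos = {y: i for i, y in enumerate(self.years)}
        self.t_idx = df["year"].map(year_pos).to_numpy()

        ages = sorted(int(a) for a in df["age"].unique())
        self.ages = ages
        age_pos = {a: i for i, a in enumerate(ages)}
        reg_pos = {r: i for i, r in enumerate(registry.regions)}
        sex_pos = {s: i for i, s in enumerate(registry.sexes)}
        self._codes = {}
        for d in df.columns:
            if d in ("origin", "destination", "region"):
                self._codes[d] = df[d].map(reg_pos).to_numpy()
            elif d == "age":
                self._codes[d] = df[d].map(age_pos).to_numpy()
            elif d == "sex":
                self._codes[d] = df[d].map(sex_pos).to_numpy()
        self._levels = {
            "origin": list(registry.regions),
            "destination": list(registry.regions),
            "region": list(registry.regions),
            "age": ages,
            "sex": list(registry.sexes),
        }
        self.sex_code = self._codes.get("sex")

        self.terms: dict[str, BoundTerm] = {}
        for t in spec.terms:
            self.terms[t.name] = self._bind_term(t, df)

        # kappa cell maps: for each kappa series, cells grouped by (series, time)
        self.kappa_specs = {k.name: k for k in spec.kappas}
        self.kappa_cells = {}
        self.kappa_loading = {}
        for k in spec.kappas:
            ns = k.n_series
            s_idx = self.sex_code if (ns == 2) else np.zeros(self.N, dtype=int)
            cells = [
                [np.where((s_idx == q) & (self.t_idx == t))[0] for t in range(self.T)]
                for q in range(ns)
            ]
            self.kappa_cells[k.name] = cells
            loading = [t.name for t in spec.terms if t.kappa == k.name]
            if len(loading) != 1:
                raise ValueError(f"kappa {k.name} must pair exactly one loading term")
            self.kappa_loading[k.name] = loading[0]

    # -- binding ----------------------------------------------------------
    def _bind_term(self, t: TermSpec, df) -> BoundTerm:
        if t.kind == "intercept":
            bt = BoundTerm(t, 1, np.zeros(self.N, dtype=int), [()])
        else:
            sizes = [len(self._levels[d]) for d in t.dims]
            code = np.zeros(self.N, dtype=int)
            for d, sz in zip(t.dims, sizes):
                code = code * sz + self._codes[d]
            used = np.unique(code)
            full = int(np.prod(sizes))
            if used.size == full:
                index = code
                keys = self._unravel_keys(np.arange(full), t.dims, sizes)
            else:  # e.g. off-diagonal OD pairs
                remap = -np.ones(full, dtype=int)
                remap[used] = np.arange(used.size)
                index = remap[code]
                keys = self._unravel_keys(used, t.dims, sizes)
            bt = BoundTerm(t, len(keys), index, keys)

        if t.kind == "break_indicator":
            bt.weight = (df["year"].to_numpy() >= t.break_year).astype(float)
        if t.prior.family == "symmetric_od_normal":
            n = self.registry.n_regions
            pair_of = {}
            pairs = []
            pidx = np.zeros(bt.size, dtype=int)
            for li, key in enumerate(bt.level_keys):
                i, j = self._levels["origin"].index(key[0]), self._levels["destination"].index(key[1])
                ij = (min(i, j), max(i, j))
                if ij not in pair_of:
                    pair_of[ij] = len(pairs)
                    pairs.append(ij)
                pidx[li] = pair_of[ij]
            bt.pair_index = pidx
            bt.n_pairs = len(pairs)
        if t.kind == "bilinear_loading":
            kspec = self.spec.kappa(t.kappa)
            bt.paired = kspec.dimension == "sex_paired"
            if bt.paired:
                if "sex" not in t.dims:
                    raise ValueError(f"paired loading {t.name} must include sex")
                # reorganise: index within sex = index over the non-sex dims
                other = tuple(d for d in t.dims if d != "sex")
                sizes = [len(self._levels[d]) for d in other]
                code = np.zeros(self.N, dtype=int)
                for d, sz in zip(other, sizes):
                    code = code * sz + self._codes[d]
                bt.index = code
                bt.size = int(np.prod(sizes))
                bt.level_keys = self._unravel_keys(np.arange(bt.size), other, sizes)
                bt.sex_code = self.sex_code
            bt.cells_by_level = [np.where(bt.index == i)[0] for i in range(bt.size)]
        return bt

    def _unravel_keys(self, flat: np.ndarray, dims, sizes) -> list:
        keys = []
        for f in flat:
            key = []
            rem = int(f)
            for sz in reversed(sizes):
                key.append(rem % sz)
                rem //= sz
            key = list(reversed(key))
            keys.append(tuple(self._levels[d][c] for d, c in zip(dims, key)))
        return keys

    # -- state ------------------------------------------------------------
    def _bilinear_init(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Rank-1 (Lee-Carter-style) initial values for a loading/kappa pair.

        The alternating conditional updates have a saddle at (uniform
        loading, zero kappa): with no loading deviation the kappa draw sees
        no level-specific signal and vice versa.  A crude SVD of the
        double-centred level x time log-rate margin starts each pair on the
        data's dominant time pattern instead.
        """
        bt = self.terms[name]
        kspec = self.kappa_specs[bt.spec.kappa]
        ns = kspec.n_series
        lr = np.log((self.Y + 0.5) / self.K)
        L = bt.size
        loadings = np.full((ns, L), 1.0 / L)
        kappas = np.zeros((ns, self.T))
        s_idx = self.sex_code if ns == 2 else np.zeros(self.N, dtype=int)
        for q in range(ns):
            m = np.zeros((L, self.T))
            cnt = np.zeros((L, self.T))
            sel = s_idx == q
            np.add.at(m, (bt.index[sel], self.t_idx[sel]), lr[sel])
            np.add.at(cnt, (bt.index[sel], self.t_idx[sel]), 1.0)
            if np.any(cnt == 0):
                continue
            m /= cnt
            m = m - m.mean(axis=1, keepdims=True)
            try:
                u, s, vt = np.linalg.svd(m, full_matrices=False)
            except np.linalg.LinAlgError:
                continue
            usum = u[:, 0].sum()
            if abs(usum) < 0.1:
                continue
            beta = u[:, 0] / usum
            kap = s[0] * vt[0] * usum
            kap = kap - kap[0]  # anchor at zero in the first period
            loadings[q] = beta
            kappas[q] = kap
        return loadings, kappas

    def init_state(
        self, rng: np.random.Generator | None = None, init_style: int | None = None
    ) -> dict:
        state = {"terms": {}, "hier_sd": {}, "od": {}, "kappa": {}, "dyn": {}}
        for name, bt in self.terms.items():
            t = bt.spec
            if t.kind == "bilinear_loading":
                loadings, kappas = self._bilinear_init(name)
                state["terms"][name] = loadings if bt.paired else loadings[0]
                state["kappa"][t.kappa] = kappas
            else:
                state["terms"][name] = np.zeros(bt.size)
            if t.prior.family == "normal_hier_sd_half_t":
                state["hier_sd"][name] = 0.3
            if t.prior.family == "symmetric_od_normal":
                state["od"] = {"alpha": np.zeros(bt.n_pairs), "sigma_od": 0.5}
        for k in self.spec.kappas:
            state["kappa"].setdefault(k.name, np.zeros((k.n_series, self.T)))
            dyn = {}
            if k.dynamics in ("ar1_drift", "rw_drift"):
                dyn = {"phi1": 0.0, "phi2": 0.5 if k.dynamics == "ar1_drift" else 1.0,
                       "sigma": 0.1}
            elif k.dynamics == "ar1_nodrift":
                dyn = {"phi1": 0.0, "phi2": 0.5, "sigma": 0.1}
            elif k.dynamics == "mrw_drift":
                dyn = {"phi1": np.zeros(2), "phi2": np.ones(2),
                       "sigmas": np.array([0.1, 0.1]), "rho": 0.0}
            elif k.dynamics == "var1_drift":
                dyn = {"phi1": np.zeros(2), "phi2": np.full(2, 0.5),
                       "sigmas": np.array([0.1, 0.1]), "rho": 0.0}
            state["dyn"][k.name] = dyn
        state["sigma"] = 0.3
        state["lm"] = np.log((self.Y + 0.5) / self.K)
        if rng is not None:
            # overdisperse starting points: the bilinear decompositions can
            # hold multiple posterior basins, so chains start from deliberately
            # diverse points -- the data-driven SVD start, a rescaled version
            # of it, or the neutral (uniform loading, flat path) start
            style = init_style if init_style is not None else 0
            state["lm"] = state["lm"] + 0.01 * rng.standard_normal(self.N)
            for k in self.spec.kappas:
                kap = state["kappa"][k.name]
                if style == 2:
                    kap[:, 1:] = 0.0
                elif style == 1:
                    kap[:, 1:] *= rng.uniform(0.3, 1.7)
                kap[:, 1:] += 0.02 * rng.standard_normal(kap[:, 1:].shape)
            if style == 2:
                for name, bt in self.terms.items():
                    if bt.spec.kind == "bilinear_loading":
                        if bt.paired:
                            state["terms"][name] = np.full((2, bt.size), 1.0 / bt.size)
                        else:
                            state["terms"][name] = np.full(bt.size, 1.0 / bt.size)
        return state

    def term_weight(self, name: str, state: dict) -> np.ndarray:
        """Per-cell multiplier of the term's parameter value."""
        bt = self.terms[name]
        t = bt.spec
        if t.kind == "break_indicator":
            return bt.weight
        if t.kind == "bilinear_loading":
            kap = state["kappa"][t.kappa]
            if bt.paired:
                return kap[self.sex_code, self.t_idx]
            return kap[0, self.t_idx]
        return np.ones(self.N)

    def term_contrib(self, name: str, state: dict) -> np.ndarray:
        bt = self.terms[name]
        vals = state["terms"][name]
        if bt.paired:
            v = vals[self.sex_code, bt.index]
        else:
            v = vals[bt.index]
        return v * self.term_weight(name, state)

    def compute_M(self, state: dict) -> np.ndarray:
        M = np.zeros(self.N)
        for name in self.terms:
            M += self.term_contrib(name, state)
        return M

    def log_posterior(self, state: dict) -> float:
        """Joint log posterior up to a constant (used in tests/debugging)."""
        lm = state["lm"]
        M = self.compute_M(state)
        lam = self.K * _safe_exp(lm)
        ll = float(np.sum(self.Y * lm + self.Y * self.logK - lam))
        ll += float(stats.norm.logpdf(lm, M, state["sigma"]).sum())
        return ll


# ---------------------------------------------------------------------------
# updates


def _update_lm(bm: BoundModel, state: dict, M: np.ndarray, rng) -> float:
    lm = state["lm"]
    sigma2 = state["sigma"] ** 2
    lam = bm.K * _safe_exp(lm)
    sd = 2.38 / np.sqrt(lam + 1.0 / sigma2)
    prop = lm + sd * rng.standard_normal(bm.N)
    lam_p = bm.K * _safe_exp(prop)
    sd_p = 2.38 / np.sqrt(lam_p + 1.0 / sigma2)

    def logpost(x, lamx):
        return bm.Y * x - lamx - (x - M) ** 2 / (2.0 * sigma2)

    log_acc = (
        logpost(prop, lam_p)
        - logpost(lm, lam)
        # Hastings correction for the state-dependent proposal scale
        - 0.5 * ((lm - prop) / sd_p) ** 2 - np.log(sd_p)
        + 0.5 * ((prop - lm) / sd) ** 2 + np.log(sd)
    )
    accept = np.log(rng.uniform(size=bm.N)) < log_acc
    lm[accept] = prop[accept]
    return float(accept.mean())


def _gibbs_linear_term(bm: BoundModel, name: str, state: dict, M: np.ndarray, rng):
    """Exact Gaussian draw for an unconstrained linear block."""
    bt = bm.terms[name]
    t = bt.spec
    vals = state["terms"][name]
    w = bm.term_weight(name, state)
    contrib = vals[bt.index] * w
    r = state["lm"] - (M - contrib)
    sigma2 = state["sigma"] ** 2
    prec_lik = np.bincount(bt.index, weights=w * w, minlength=bt.size) / sigma2
    b_lik = np.bincount(bt.index, weights=w * r, minlength=bt.size) / sigma2

    if t.prior.family == "normal_fixed_sd":
        prec0 = 1.0 / t.prior.sd**2
        m0 = np.zeros(bt.size)
    elif t.prior.family == "normal_hier_sd_half_t":
        prec0 = 1.0 / state["hier_sd"][name] ** 2
        m0 = np.zeros(bt.size)
    elif t.prior.family == "symmetric_od_normal":
        prec0 = 1.0 / state["od"]["sigma_od"] ** 2
        m0 = state["od"]["alpha"][bt.pair_index]
    else:
        raise ValueError(f"not a linear prior family: {t.prior.family}")

    prec = prec0 + prec_lik
    mean = (prec0 * m0 + b_lik) / prec
    new = mean + rng.standard_normal(bt.size) / np.sqrt(prec)
    M += (new[bt.index] - vals[bt.index]) * w
    state["terms"][name] = new


def _gibbs_constrained_loading(bm: BoundModel, name: str, state: dict, M: np.ndarray, rng):
    """Scalar Gibbs over the free elements of a sum-to-one loading vector."""
    bt = bm.terms[name]
    w_all = bm.term_weight(name, state)
    sigma2 = state["sigma"] ** 2
    L = bt.size
    prior_prec_diag = 2.0 * L * L  # Lambda_ii of Lambda = L^2 (I + J)

    rows = [None] if not bt.paired else [0, 1]
    for srow in rows:
        if bt.paired:
            vals = state["terms"][name][srow]
            in_row = bt.sex_code == srow
        else:
            vals = state["terms"][name]
            in_row = None
        last = L - 1
        cells_last = bt.cells_by_level[last]
        if bt.paired:
            cells_last = cells_last[in_row[cells_last]]
        for i in range(L - 1):
            cells_i = bt.cells_by_level[i]
            if bt.paired:
                cells_i = cells_i[in_row[cells_i]]
            w_i = w_all[cells_i]
            w_l = w_all[cells_last]
            # residuals with u_i's contribution removed (incl. via the last element)
            r_i = state["lm"][cells_i] - (M[cells_i] - vals[i] * w_i)
            r_l = state["lm"][cells_last] - (M[cells_last] - vals[last] * w_l)
            # on the last-level cells the loading is 1 - sum(u); holding the
            # other free elements fixed, contribution = const - u_i * w
            const_l = (vals[last] + vals[i]) * w_l
            prec_lik = (np.sum(w_i * w_i) + np.sum(w_l * w_l)) / sigma2
            b_lik = (np.sum(w_i * r_i) + np.sum(w_l * (const_l - r_l))) / sigma2
            # conditional prior of u_i given the other free elements
            m = 1.0 / L
            others = vals[:last].sum() - vals[i]
            mean0 = m - 0.5 * (others - (L - 2) * m)
            prec = prior_prec_diag + prec_lik
            mean = (prior_prec_diag * mean0 + b_lik) / prec
            new = mean + rng.standard_normal() / np.sqrt(prec)
            delta = new - vals[i]
            vals[i] = new
            vals[last] -= delta  # keep sum = 1
            M[cells_i] += delta * w_i
            M[cells_last] -= delta * w_l


def _update_od_hyper(bm: BoundModel, state: dict, rng):
    """alpha (symmetric OD means, N(0,1) prior) and sigma_OD (half-t)."""
    name = next(n for n, bt in bm.terms.items() if bt.spec.prior.family == "symmetric_od_normal")
    bt = bm.terms[name]
    od1 = state["terms"][name]
    sig2 = state["od"]["sigma_od"] ** 2
    cnt = np.bincount(bt.pair_index, minlength=bt.n_pairs)
    ssum = np.bincount(bt.pair_index, weights=od1, minlength=bt.n_pairs)
    prec = 1.0 + cnt / sig2
    mean = (ssum / sig2) / prec
    state["od"]["alpha"] = mean + rng.standard_normal(bt.n_pairs) / np.sqrt(prec)

    resid = od1 - state["od"]["alpha"][bt.pair_index]
    ss = float(np.sum(resid**2))
    L = od1.size

    def logp(logs):
        s = np.exp(logs)
        return -L * logs - ss / (2 * s * s) + _half_t_logpdf(s, 2.5, 0.5) + logs

    s0 = np.log(state["od"]["sigma_od"])
    state["od"]["sigma_od"] = float(np.exp(slice_sample(s0, logp, rng)))


def _update_hier_sds(bm: BoundModel, state: dict, rng):
    for name, s in list(state["hier_sd"].items()):
        theta = state["terms"][name]
        ss = float(np.sum(theta**2))
        L = theta.size
        prior = bm.terms[name].spec.prior

        def logp(logs):
            sd = np.exp(logs)
            return -L * logs - ss / (2 * sd * sd) + _half_t_logpdf(sd, prior.df, prior.scale) + logs

        state["hier_sd"][name] = float(np.exp(slice_sample(np.log(s), logp, rng)))


def _update_sigma(bm: BoundModel, state: dict, M: np.ndarray, rng, prior):
    resid = state["lm"] - M
    ss = float(np.sum(resid**2))
    N = bm.N

    def logp(logs):
        s = np.exp(logs)
        return -N * logs - ss / (2 * s * s) + _half_t_logpdf(s, prior.df, prior.scale) + logs

    state["sigma"] = float(np.exp(slice_sample(np.log(state["sigma"]), logp, rng)))


def _kappa_prior_blocks(kspec: KappaSpec, dyn: dict):
    """(phi1 vector, phi2 vector, Sigma inverse) on the series' native dimension."""
    ns = kspec.n_series
    if ns == 1:
        phi1 = np.array([0.0 if kspec.dynamics == "ar1_nodrift" else dyn["phi1"]])
        phi2 = np.array([1.0 if kspec.dynamics == "rw_drift" else dyn["phi2"]])
        Q = np.array([[1.0 / dyn["sigma"] ** 2]])
        return phi1, phi2, Q
    phi1 = np.asarray(dyn["phi1"], dtype=float)
    phi2 = np.ones(2) if kspec.dynamics == "mrw_drift" else np.asarray(dyn["phi2"], dtype=float)
    sM, sF = dyn["sigmas"]
    rho = dyn["rho"]
    Sigma = np.array([[sM * sM, rho * sM * sF], [rho * sM * sF, sF * sF]])
    return phi1, phi2, np.linalg.inv(Sigma)


def _gibbs_all_kappas(bm: BoundModel, state: dict, M: np.ndarray, rng):
    """Exact joint draw of every kappa path in the model.

    Given the loadings, the latent log-rates and the dynamics parameters,
    the free path values (t = 2..T of every series of every kappa) are
    jointly Gaussian: each time-series prior contributes a block-tridiagonal
    precision and the likelihood couples series that load on the same cells
    (the near-collinear regime where loadings sit close to their uniform
    prior mean makes this joint draw essential for mixing).
    """
    T = bm.T
    if T < 2 or not bm.kappa_specs:
        return
    sigma2 = state["sigma"] ** 2
    knames = list(bm.kappa_specs)
    offsets = {}
    nf = 0
    for kn in knames:
        offsets[kn] = nf
        nf += bm.kappa_specs[kn].n_series * (T - 1)
    # break-indicator coefficients ride along in the joint draw: a region
    # step at the break year is nearly collinear with a step in the kappa
    # paths, so updating them separately mixes poorly
    break_terms = [n for n, bt in bm.terms.items() if bt.spec.kind == "break_indicator"]
    brk_offsets = {}
    for n in break_terms:
        brk_offsets[n] = nf
        nf += bm.terms[n].size

    def pos(kn, q, j):  # j = 1..T-1 free time index
        ns = bm.kappa_specs[kn].n_series
        return offsets[kn] + (j - 1) * ns + q

    P = np.zeros((nf, nf))
    b = np.zeros(nf)
    for n in break_terms:
        sl = slice(brk_offsets[n], brk_offsets[n] + bm.terms[n].size)
        prior = bm.terms[n].spec.prior
        p0 = (
            1.0 / state["hier_sd"][n] ** 2
            if prior.family == "normal_hier_sd_half_t"
            else 1.0 / prior.sd**2
        )
        P[sl, sl] += np.eye(bm.terms[n].size) * p0

    # time-series priors (block tridiagonal per kappa)
    for kn in knames:
        kspec = bm.kappa_specs[kn]
        ns = kspec.n_series
        phi1, phi2, Q = _kappa_prior_blocks(kspec, state["dyn"][kn])
        A = np.diag(phi2)
        for j in range(1, T):
            sl = slice(pos(kn, 0, j), pos(kn, 0, j) + ns)
            P[sl, sl] += Q
            b[sl] += Q @ phi1  # kappa at j-1 = 0 anchors the j = 1 term
            if j >= 2:
                sl0 = slice(pos(kn, 0, j - 1), pos(kn, 0, j - 1) + ns)
                P[sl0, sl0] += A @ Q @ A
                P[sl0, sl] += -(A @ Q)
                P[sl, sl0] += -(Q @ A)
                b[sl0] += -(A @ Q @ phi1)

    # likelihood: partition cells by (sex group, time); every kappa loads on
    # each cell through exactly one of its series
    groups = (0, 1) if bm.sex_code is not None else (0,)
    sgrp = bm.sex_code if bm.sex_code is not None else np.zeros(bm.N, dtype=int)
    kap_cur = {kn: state["kappa"][kn] for kn in knames}
    for j in range(0, T):
        for g in groups:
            idx = np.where((bm.t_idx == j) & (sgrp == g))[0]
            if idx.size == 0:
                continue
            resid = state["lm"][idx] - M[idx]
            ws, poss = [], []
            if j >= 1:
                for kn in knames:
                    kspec = bm.kappa_specs[kn]
                    q = g if kspec.n_series == 2 else 0
                    bt = bm.terms[bm.kappa_loading[kn]]
                    w = (
                        state["terms"][bm.kappa_loading[kn]][q, bt.index[idx]]
                        if bt.paired
                        else state["terms"][bm.kappa_loading[kn]][bt.index[idx]]
                    )
                    resid = resid + w * kap_cur[kn][q, j]
                    ws.append(w)
                    poss.append(pos(kn, q, j))
            bvecs = []  # (positions per cell, weights per cell) for break terms
            for n in break_terms:
                bt = bm.terms[n]
                wb = bt.weight[idx]
                bp = brk_offsets[n] + bt.index[idx]
                resid = resid + state["terms"][n][bt.index[idx]] * wb
                bvecs.append((bp, wb))
            for a in range(len(ws)):
                b[poss[a]] += np.sum(ws[a] * resid) / sigma2
                for c in range(a, len(ws)):
                    val = np.sum(ws[a] * ws[c]) / sigma2
                    P[poss[a], poss[c]] += val
                    if c != a:
                        P[poss[c], poss[a]] += val
                for bp, wb in bvecs:
                    cross = np.bincount(bp, weights=ws[a] * wb, minlength=nf) / sigma2
                    nz = np.nonzero(cross)[0]
                    P[poss[a], nz] += cross[nz]
                    P[nz, poss[a]] += cross[nz]
            for bp, wb in bvecs:
                np.add.at(b, bp, wb * resid / sigma2)
                np.add.at(P, (bp, bp), wb * wb / sigma2)
                # cross terms between distinct break terms are not needed:
                # the reference models carry at most one break indicator

    C = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b)
    new = mean + np.linalg.solve(C.T, rng.standard_normal(nf))

    # write back and refresh M
    for kn in knames:
        kspec = bm.kappa_specs[kn]
        ns = kspec.n_series
        kap = state["kappa"][kn]
        bt = bm.terms[bm.kappa_loading[kn]]
        vals = state["terms"][bm.kappa_loading[kn]]
        for j in range(1, T):
            for q in range(ns):
                idx = bm.kappa_cells[kn][q][j]
                npos = new[pos(kn, q, j)]
                if idx.size:
                    w = vals[q, bt.index[idx]] if bt.paired else vals[bt.index[idx]]
                    M[idx] += w * (npos - kap[q, j])
        kap[:, 1:] = new[offsets[kn] : offsets[kn] + ns * (T - 1)].reshape(T - 1, ns).T

    for n in break_terms:
        bt = bm.terms[n]
        newvals = new[brk_offsets[n] : brk_offsets[n] + bt.size]
        M += (newvals[bt.index] - state["terms"][n][bt.index]) * bt.weight
        state["terms"][n] = newvals


def _kappa_lik_terms(bm: BoundModel, kname: str, state: dict, M: np.ndarray):
    """Diagonal likelihood precision and linear term for one kappa's free path."""
    kspec = bm.kappa_specs[kname]
    ns, T = kspec.n_series, bm.T
    nf = ns * (T - 1)
    lik_prec = np.zeros(nf)
    lik_b = np.zeros(nf)
    kap = state["kappa"][kname]
    bt = bm.terms[bm.kappa_loading[kname]]
    vals = state["terms"][bm.kappa_loading[kname]]
    sigma2 = state["sigma"] ** 2
    for j in range(1, T):
        for q in range(ns):
            idx = bm.kappa_cells[kname][q][j]
            if idx.size == 0:
                continue
            w = vals[q, bt.index[idx]] if bt.paired else vals[bt.index[idx]]
            r = state["lm"][idx] - (M[idx] - w * kap[q, j])
            pos = (j - 1) * ns + q
            lik_prec[pos] = np.sum(w * w) / sigma2
            lik_b[pos] = np.sum(w * r) / sigma2
    return lik_prec, lik_b


def _kappa_prior_Pb(kspec: KappaSpec, dyn: dict, T: int):
    """Block-tridiagonal prior precision/linear term for a free kappa path."""
    ns = kspec.n_series
    phi1, phi2, Q = _kappa_prior_blocks(kspec, dyn)
    A = np.diag(phi2)
    Tm1 = T - 1
    I = np.eye(Tm1)
    D1 = np.eye(Tm1)
    D1[-1, -1] = 0.0  # the last free time has no onward transition
    U = np.zeros((Tm1, Tm1))
    if Tm1 > 1:
        ix = np.arange(Tm1 - 1)
        U[ix, ix + 1] = 1.0
    AQ = A @ Q
    P = np.kron(I, Q) + np.kron(D1, AQ @ A) - np.kron(U, AQ) - np.kron(U.T, Q @ A)
    b = np.tile(Q @ phi1, Tm1)
    if Tm1 > 1:
        b[: ns * (Tm1 - 1)] -= np.tile(AQ @ phi1, Tm1 - 1)
    return P, b, phi1, Q


def _dyn_hyper_logprior(kspec: KappaSpec, dyn: dict) -> float:
    lp = 0.0
    if kspec.dynamics != "ar1_nodrift":
        phi1 = np.atleast_1d(np.asarray(dyn["phi1"], dtype=float))
        lp += float(-0.5 * np.sum(phi1**2) / PHI1_SD**2)
    if kspec.dynamics in ("ar1_drift", "ar1_nodrift", "var1_drift"):
        phi2 = np.atleast_1d(np.asarray(dyn["phi2"], dtype=float))
        if np.any((phi2 < 0) | (phi2 > 1)):
            return -np.inf
        lp += float(-0.5 * np.sum((phi2 - PHI2_MEAN) ** 2) / PHI2_SD**2)
    if kspec.n_series == 1:
        s = float(dyn["sigma"])
        if s <= 0:
            return -np.inf
        lp += -0.5 * s * s  # half-normal(0, 1)
    else:
        sM, sF = dyn["sigmas"]
        rho = float(dyn["rho"])
        if sM <= 0 or sF <= 0 or not (-1 < rho < 1):
            return -np.inf
        lp += -0.5 * (sM * sM + sF * sF)
        lp += (LKJ_ETA - 1.0) * np.log(1 - rho * rho)
    return float(lp)


def _collapsed_dyn_logmarg(bm, kspec, dyn, lik_prec, lik_b, T) -> float:
    """Log marginal of the dynamics parameters with the kappa path integrated out."""
    lp = _dyn_hyper_logprior(kspec, dyn)
    if not np.isfinite(lp):
        return -np.inf
    P_pr, b_pr, phi1, Q = _kappa_prior_Pb(kspec, dyn, T)
    # prior normalisation constants that depend on the dynamics parameters
    sign, logdetQ = np.linalg.slogdet(Q)
    lp += 0.5 * (T - 1) * logdetQ  # -(T-1)/2 log det Sigma
    lp += -0.5 * (T - 1) * float(phi1 @ Q @ phi1)
    P = P_pr + np.diag(lik_prec)
    b = b_pr + lik_b
    try:
        C = np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        return -np.inf
    half = np.linalg.solve(C, b)
    lp += -float(np.sum(np.log(np.diag(C)))) + 0.5 * float(half @ half)
    return lp


def _update_dynamics_collapsed(bm: BoundModel, kname: str, state: dict, M: np.ndarray, rng):
    """Slice-sample dynamics parameters under the path-marginalised posterior.

    Conditioning the innovation scale on the current path creates a funnel
    (the path cannot widen until the scale does and vice versa); integrating
    the Gaussian path out of the scale update removes it.  The path is
    redrawn from its full conditional immediately afterwards so the pair
    (dynamics, path) is updated as one block.
    """
    kspec = bm.kappa_specs[kname]
    T = bm.T
    if T < 2:
        return
    dyn = state["dyn"][kname]
    lik_prec, lik_b = _kappa_lik_terms(bm, kname, state, M)

    def logp_for(**kw):
        trial = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in dyn.items()}
        trial.update(kw)
        return _collapsed_dyn_logmarg(bm, kspec, trial, lik_prec, lik_b, T)

    if kspec.n_series == 1:
        if kspec.dynamics in ("ar1_drift", "rw_drift"):
            dyn["phi1"] = slice_sample(
                float(dyn["phi1"]), lambda v: logp_for(phi1=v), rng, w=0.5
            )
        if kspec.dynamics in ("ar1_drift", "ar1_nodrift"):
            dyn["phi2"] = slice_sample(
                float(dyn["phi2"]), lambda v: logp_for(phi2=v), rng, w=0.2,
                lower=0.0, upper=1.0,
            )
        dyn["sigma"] = float(
            np.exp(
                slice_sample(
                    np.log(float(dyn["sigma"])),
                    lambda ls: logp_for(sigma=np.exp(ls)) + ls,
                    rng, w=0.7,
                )
            )
        )
    else:
        phi1 = np.asarray(dyn["phi1"], dtype=float).copy()
        for q in range(2):
            def f(v, q=q):
                p = phi1.copy()
                p[q] = v
                return logp_for(phi1=p)

            phi1[q] = slice_sample(float(phi1[q]), f, rng, w=0.5)
        dyn["phi1"] = phi1
        if kspec.dynamics == "var1_drift":
            phi2 = np.asarray(dyn["phi2"], dtype=float).copy()
            for q in range(2):
                def f2(v, q=q):
                    p = phi2.copy()
                    p[q] = v
                    return logp_for(phi2=p)

                phi2[q] = slice_sample(float(phi2[q]), f2, rng, w=0.2, lower=0.0, upper=1.0)
            dyn["phi2"] = phi2
        sig = np.asarray(dyn["sigmas"], dtype=float).copy()
        for q in range(2):
            def fs(ls, q=q):
                s = sig.copy()
                s[q] = np.exp(ls)
                return logp_for(sigmas=s) + ls

            sig[q] = float(np.exp(slice_sample(np.log(sig[q]), fs, rng, w=0.7)))
        dyn["sigmas"] = sig
        dyn["rho"] = slice_sample(
            float(dyn["rho"]), lambda v: logp_for(rho=v), rng, w=0.3,
            lower=-0.999, upper=0.999,
        )

    # immediate joint redraw of this kappa's path under the new dynamics
    P_pr, b_pr, _, _ = _kappa_prior_Pb(kspec, dyn, T)
    P = P_pr + np.diag(lik_prec)
    b = b_pr + lik_b
    C = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b)
    new = (mean + np.linalg.solve(C.T, rng.standard_normal(b.size))).reshape(T - 1, kspec.n_series).T
    kap = state["kappa"][kname]
    bt = bm.terms[bm.kappa_loading[kname]]
    vals = state["terms"][bm.kappa_loading[kname]]
    for j in range(1, T):
        for q in range(kspec.n_series):
            idx = bm.kappa_cells[kname][q][j]
            if idx.size:
                w = vals[q, bt.index[idx]] if bt.paired else vals[bt.index[idx]]
                M[idx] += w * (new[q, j - 1] - kap[q, j])
    kap[:, 1:] = new


def _truncnorm_draw(mean, sd, lo, hi, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _update_dynamics(bm: BoundModel, kname: str, state: dict, rng):
    kspec = bm.kappa_specs[kname]
    kap = state["kappa"][kname]
    dyn = state["dyn"][kname]
    T = kap.shape[1]
    if T < 2:
        return

    if kspec.n_series == 1:
        y = kap[0, 1:]
        x = kap[0, :-1]
        sig2 = dyn["sigma"] ** 2
        drift = kspec.dynamics in ("ar1_drift", "rw_drift")
        ar = kspec.dynamics in ("ar1_drift", "ar1_nodrift")
        if drift:
            prec = 1.0 / PHI1_SD**2 + (T - 1) / sig2
            mean = np.sum(y - dyn["phi2"] * x) / sig2 / prec
            dyn["phi1"] = mean + rng.standard_normal() / np.sqrt(prec)
        if ar:
            prec = 1.0 / PHI2_SD**2 + np.sum(x * x) / sig2
            mean = (PHI2_MEAN / PHI2_SD**2 + np.sum(x * (y - dyn["phi1"])) / sig2) / prec
            dyn["phi2"] = _truncnorm_draw(mean, 1.0 / np.sqrt(prec), 0.0, 1.0, rng)
        resid = y - dyn["phi1"] - dyn["phi2"] * x
        ss = float(np.sum(resid**2))

        def logp(logs):
            s = np.exp(logs)
            # half-normal(0, 1) prior on the innovation sd
            return -(T - 1) * logs - ss / (2 * s * s) - s * s / 2.0 + logs

        dyn["sigma"] = float(np.exp(slice_sample(np.log(dyn["sigma"]), logp, rng)))
        return

    # sex-paired series
    phi1 = np.asarray(dyn["phi1"], dtype=float)
    phi2 = np.ones(2) if kspec.dynamics == "mrw_drift" else np.asarray(dyn["phi2"], dtype=float)
    Y2 = kap[:, 1:]
    X2 = kap[:, :-1]
    Tm1 = T - 1

    def Qmat():
        sM, sF = dyn["sigmas"]
        rho = dyn["rho"]
        Sigma = np.array([[sM * sM, rho * sM * sF], [rho * sM * sF, sF * sF]])
        return np.linalg.inv(Sigma)

    # drift pair: joint bivariate Gaussian conditional
    Q = Qmat()
    prec = Tm1 * Q + np.eye(2) / PHI1_SD**2
    b = Q @ np.sum(Y2 - phi2[:, None] * X2, axis=1)
    cov = np.linalg.inv(prec)
    mean = cov @ b
    phi1 = mean + np.linalg.cholesky(cov) @ rng.standard_normal(2)
    dyn["phi1"] = phi1

    if kspec.dynamics == "var1_drift":
        for q in range(2):
            qq = Q[q, q]
            qo = Q[q, 1 - q]
            a = Y2[q] - phi1[q]
            eps_o = Y2[1 - q] - phi1[1 - q] - phi2[1 - q] * X2[1 - q]
            x = X2[q]
            prec_s = 1.0 / PHI2_SD**2 + qq * np.sum(x * x)
            b_s = PHI2_MEAN / PHI2_SD**2 + qq * np.sum(x * a) + qo * np.sum(x * eps_o)
            phi2[q] = _truncnorm_draw(b_s / prec_s, 1.0 / np.sqrt(prec_s), 0.0, 1.0, rng)
        dyn["phi2"] = phi2

    eps = Y2 - phi1[:, None] - phi2[:, None] * X2

    def nll(sM, sF, rho):
        if sM <= 0 or sF <= 0 or not (-1 < rho < 1):
            return -np.inf
        det = (sM * sF) ** 2 * (1 - rho * rho)
        Qi = np.array(
            [[1.0 / (sM * sM), -rho / (sM * sF)], [-rho / (sM * sF), 1.0 / (sF * sF)]]
        ) / (1 - rho * rho)
        quad = float(np.sum(eps * (Qi @ eps)))
        return -0.5 * Tm1 * np.log(det) - 0.5 * quad

    sM, sF, rho = float(dyn["sigmas"][0]), float(dyn["sigmas"][1]), float(dyn["rho"])
    sM = float(
        np.exp(
            slice_sample(
                np.log(sM),
                lambda ls: nll(np.exp(ls), sF, rho) - np.exp(ls) ** 2 / 2 + ls,
                rng,
            )
        )
    )
    sF = float(
        np.exp(
            slice_sample(
                np.log(sF),
                lambda ls: nll(sM, np.exp(ls), rho) - np.exp(ls) ** 2 / 2 + ls,
                rng,
            )
        )
    )
    rho = float(
        slice_sample(
            rho,
            lambda r: nll(sM, sF, r) + (LKJ_ETA - 1.0) * np.log(max(1 - r * r, 1e-300)),
            rng,
            w=0.3,
            lower=-0.999,
            upper=0.999,
        )
    )
    dyn["sigmas"] = np.array([sM, sF])
    dyn["rho"] = rho


# ---------------------------------------------------------------------------
# the sweep


def gibbs_sweep(
    bm: BoundModel, state: dict, rng: np.random.Generator, collapse: bool = True
) -> float:
    """One full update of every block; returns the latent-lm acceptance rate.

    ``collapse`` switches on the path-marginalised dynamics update (the
    expensive anti-funnel move); callers may alternate it between sweeps.
    """
    M = bm.compute_M(state)
    acc = _update_lm(bm, state, M, rng)
    for name, bt in bm.terms.items():
        if bt.spec.kind == "bilinear_loading":
            _gibbs_constrained_loading(bm, name, state, M, rng)
        else:
            _gibbs_linear_term(bm, name, state, M, rng)
    if any(bt.spec.prior.family == "symmetric_od_normal" for bt in bm.terms.values()):
        _update_od_hyper(bm, state, rng)
    _update_hier_sds(bm, state, rng)
    if collapse:
        for kname in bm.kappa_specs:
            _update_dynamics_collapsed(bm, kname, state, M, rng)
    _gibbs_all_kappas(bm, state, M, rng)
    for kname in bm.kappa_specs:
        _update_dynamics(bm, kname, state, rng)
    _update_sigma(bm, state, M, rng, bm.spec.overdispersion_prior)
    return acc
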