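"""Log-linear predictors with bilinear terms, likelihood, priors, constraints.

Every component of change shares one observation model: counts are Poisson
given an exposure offset, ``Y ~ Poisson(mu * K)``, and the log rate is
normally distributed around a structured predictor, ``log mu ~ N(M, sigma^2)``
(a Poisson-lognormal over-dispersed count model).  The predictor ``M`` is a
sum of main effects, two-way interactions and Lee-Carter-style bilinear
terms: a profile loading (over ages, regions or origin-destination pairs)
multiplied by a latent time effect ``kappa_t``.

Identification is soft (hierarchical priors) apart from two hard
constraints: each kappa series starts at zero, and each bilinear loading
vector sums to one (its last element is one minus the sum of the free
elements).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .core_data import Component
from .dynamics import KappaSpec

BREAK_YEAR_DEFAULT = 2004


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one block of predictor parameters.

    families:
      - ``normal_fixed_sd``: iid Normal(0, sd^2) (interactions; intercept).
      - ``normal_hier_sd_half_t``: iid Normal(0, s^2) with s ~ half-t(df, scale)
        (main-effect profiles).
      - ``symmetric_od_normal``: Normal(alpha_ij, sigma_OD^2) with alpha
        symmetric in (i, j), alpha ~ N(0,1), sigma_OD ~ half-t(df, scale).
      - ``constrained_bilinear``: the sum-to-one loading prior; the L-1 free
        elements are MVN(iota/L, L^-2 Psi^-1) with Psi = I + J.
    """

    family: str
    sd: float = 1.0
    df: float = 2.5
    scale: float = 0.5

    def __post_init__(self):
        if self.family not in (
            "normal_fixed_sd",
            "normal_hier_sd_half_t",
            "symmetric_od_normal",
            "constrained_bilinear",
        ):
            raise ValueError(f"unknown prior family {self.family}")
        if self.sd <= 0 or self.scale <= 0:
            raise ValueError("scale hyperparameters must be positive")


@dataclass(frozen=True)
class TermSpec:
    """One additive term of the log-scale predictor."""

    name: str
    dims: tuple[str, ...]  # subset of origin/destination/region/age/sex
    kind: str  # intercept | main | interaction | bilinear_loading | break_indicator
    prior: PriorSpec
    kappa: Optional[str] = None  # paired kappa series (bilinear loadings only)
    break_year: Optional[int] = None  # threshold (break indicators only)

    def __post_init__(self):
        if self.kind == "bilinear_loading" and self.kappa is None:
            raise ValueError(f"bilinear term {self.name} must name a kappa series")
        if self.kind == "break_indicator" and self.break_year is None:
            raise ValueError(f"break term {self.name} must carry a threshold year")


@dataclass
class ModelSpec:
    """Declarative description of one component's log-bilinear model."""

    component: Component
    terms: list[TermSpec]
    kappas: list[KappaSpec]
    overdispersion_prior: PriorSpec = field(
        default_factory=lambda: PriorSpec("normal_hier_sd_half_t", df=2.5, scale=0.5)
    )

    def __post_init__(self):
        self.component = Component(self.component)
        names = {k.name for k in self.kappas}
        for t in self.terms:
            if t.kappa is not None and t.kappa not in names:
                raise ValueError(f"term {t.name} references unknown kappa {t.kappa}")

    def kappa(self, name: str) -> KappaSpec:
        return next(k for k in self.kappas if k.name == name)

    def to_dict(self) -> dict:
        return {
            "component": self.component.value,
            "terms": [
                {
                    "name": t.name,
                    "dims": list(t.dims),
                    "kind": t.kind,
                    "prior": {
                        "family": t.prior.family,
                        "sd": t.prior.sd,
                        "df": t.prior.df,
                        "scale": t.prior.scale,
                    },
                    "kappa": t.kappa,
                    "break_year": t.break_year,
                }
                for t in self.terms
            ],
            "kappas": [
                {"name": k.name, "dimension": k.dimension, "dynamics": k.dynamics}
                for k in self.kappas
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        terms = [
            TermSpec(
                t["name"],
                tuple(t["dims"]),
                t["kind"],
                PriorSpec(**t["prior"]),
                t.get("kappa"),
                t.get("break_year"),
            )
            for t in d["terms"]
        ]
        kappas = [KappaSpec(k["name"], k["dimension"], k["dynamics"]) for k in d["kappas"]]
        return cls(Component(d["component"]), terms, kappas)


# ---------------------------------------------------------------------------
# predictor evaluation


def _kappa_at(kappa_values: dict, name: str, cell: dict, spec: ModelSpec) -> float:
    kv = kappa_values[name]
    kspec = spec.kappa(name)
    if kspec.dimension == "sex_paired":
        return float(kv[(cell["sex"], cell["year"])])
    return float(kv[cell["year"]])


def linear_predictor(
    spec: ModelSpec,
    params: dict,
    kappa_values: dict,
    cell: dict,
) -> float:
    """Evaluate the additive log-scale predictor M for one cell.

    ``params`` maps term name to a dict keyed by the term's level tuple
    (single values keyed by the tuple of the cell's levels on the term's
    dims; the intercept by the empty tuple).  ``kappa_values`` maps kappa
    name to ``{year: value}`` (scalar series) or ``{(sex, year): value}``
    (sex-paired series).
    """
    total = 0.0
    for term in spec.terms:
        key = tuple(cell[d] for d in term.dims)
        try:
            value = params[term.name][key]
        except KeyError:
            raise KeyError(f"unknown cell level {key} for term {term.name}") from None
        if term.kind == "bilinear_loading":
            value = value * _kappa_at(kappa_values, term.kappa, cell, spec)
        elif term.kind == "break_indicator":
            value = value if cell["year"] >= term.break_year else 0.0
        total += value
    return float(total)


def constrain_bilinear_loadings(u: np.ndarray) -> np.ndarray:
    """Append the constrained last element so the loading vector sums to 1."""
    u = np.asarray(u, dtype=float)
    return np.concatenate([u, [1.0 - u.sum()]])


def bilinear_psi(z: int) -> np.ndarray:
    """The (z-1)x(z-1) precision pattern: 2 on the diagonal, 1 elsewhere."""
    return np.eye(z - 1) + np.ones((z - 1, z - 1))


def bilinear_prior_logdensity(u: np.ndarray) -> float:
    """Log density of the free loading elements: MVN(iota/z, z^-2 Psi^-1)."""
    u = np.asarray(u, dtype=float)
    z = u.size + 1
    mean = np.full(z - 1, 1.0 / z)
    cov = np.linalg.inv(bilinear_psi(z)) / z**2
    return float(stats.multivariate_normal(mean=mean, cov=cov).logpdf(u))


def expand_symmetric(alpha_free: np.ndarray, n: int) -> np.ndarray:
    """Expand n(n-1)/2 free values into a symmetric off-diagonal (n, n) array."""
    alpha_free = np.asarray(alpha_free, dtype=float)
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = alpha_free
    out[(iu[1], iu[0])] = alpha_free
    return out


def symmetric_od_prior(
    alpha_free: np.ndarray, od1: np.ndarray, sigma_od: float, n: int
) -> float:
    """Log density of OD1 given the symmetric alpha means.

    ``od1`` is an (n, n) array whose off-diagonal entries are the OD1
    parameters; the density sums Normal(OD1_ij; alpha_ij, sigma_OD^2) over
    ordered pairs i != j with alpha_ij == alpha_ji.
    """
    alpha = expand_symmetric(alpha_free, n)
    mask = ~np.eye(n, dtype=bool)
    return float(
        stats.norm.logpdf(np.asarray(od1)[mask], loc=alpha[mask], scale=sigma_od).sum()
    )


def poisson_lognormal_loglik(
    Y: int, K: float, log_mu: float, M: float, sigma: float
) -> float:
    """Joint log contribution of one cell in augmented (non-marginalised) form.

    ``log Poisson(Y; exp(log_mu) K) + log Normal(log_mu; M, sigma^2)``.
    The latent per-cell ``log_mu`` is a parameter, which preserves the
    over-dispersion of the Poisson-lognormal model exactly.
    """
    if K <= 0:
        raise ValueError("exposure must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if Y < 0 or Y != int(Y):
        raise ValueError("count must be a non-negative integer")
    lam = np.exp(log_mu) * K
    return float(
        stats.poisson.logpmf(int(Y), lam) + stats.norm.logpdf(log_mu, loc=M, scale=sigma)
    )


# ---------------------------------------------------------------------------
# default per-component specifications


def default_model_specs(component: Component, break_year: int = BREAK_YEAR_DEFAULT) -> ModelSpec:
    """The per-component model used in the reference application.

    internal migration:  M = c + AS + OA + DA + OD1 + OD2*k1(t) + A1 + A2*k2(t)
    mortality:           M = c + RA + RS + AS1 + AS2*k(s,t)   (bivariate RW drift)
    fertility:           M = c + RA + A1 + A2*k1(t) + R1 + R2*k2(t)  (driftless AR1)
    immigration/emigration:
        M = c + Rbrk*1(t>=break) + RA + AS1 + AS2*k1(s,t) + R1 + R2*k2(t)
        with sex-paired VAR(1) k1 and univariate AR(1)-with-drift k2.
    Immigration models counts (exposure identically 1); all others rates or
    probabilities.
    """
    component = Component(component)
    intercept = TermSpec("c", (), "intercept", PriorSpec("normal_fixed_sd", sd=np.sqrt(5.0)))
    inter = lambda name, dims: TermSpec(name, dims, "interaction", PriorSpec("normal_fixed_sd", sd=0.2))
    main = lambda name, dims: TermSpec(name, dims, "main", PriorSpec("normal_hier_sd_half_t"))
    bilin = lambda name, dims, kappa: TermSpec(
        name, dims, "bilinear_loading", PriorSpec("constrained_bilinear"), kappa=kappa
    )

    if component is Component.INTERNAL_MIGRATION:
        return ModelSpec(
            component,
            terms=[
                intercept,
                inter("AS", ("age", "sex")),
                inter("OA", ("origin", "age")),
                inter("DA", ("destination", "age")),
                TermSpec("OD1", ("origin", "destination"), "main", PriorSpec("symmetric_od_normal")),
                bilin("OD2", ("origin", "destination"), "kappa_od"),
                main("A1", ("age",)),
                bilin("A2", ("age",), "kappa_age"),
            ],
            kappas=[
                KappaSpec("kappa_od", "scalar", "ar1_drift"),
                KappaSpec("kappa_age", "scalar", "ar1_drift"),
            ],
        )
    if component is Component.MORTALITY:
        return ModelSpec(
            component,
            terms=[
                intercept,
                inter("RA", ("region", "age")),
                inter("RS", ("region", "sex")),
                main("AS1", ("age", "sex")),
                bilin("AS2", ("age", "sex"), "kappa_as"),
            ],
            kappas=[KappaSpec("kappa_as", "sex_paired", "mrw_drift")],
        )
    if component is Component.FERTILITY:
        return ModelSpec(
            component,
            terms=[
                intercept,
                inter("RA", ("region", "age")),
                main("A1", ("age",)),
                bilin("A2", ("age",), "kappa_age"),
                main("R1", ("region",)),
                bilin("R2", ("region",), "kappa_region"),
            ],
            kappas=[
                KappaSpec("kappa_age", "scalar", "ar1_nodrift"),
                KappaSpec("kappa_region", "scalar", "ar1_nodrift"),
            ],
        )
    if component in (Component.IMMIGRATION, Component.EMIGRATION):
        return ModelSpec(
            component,
            terms=[
                intercept,
                TermSpec(
                    "Rbrk", ("region",), "break_indicator",
                    PriorSpec("normal_hier_sd_half_t"), break_year=break_year,
                ),
                inter("RA", ("region", "age")),
                main("AS1", ("age", "sex")),
                bilin("AS2", ("age", "sex"), "kappa_as"),
                main("R1", ("region",)),
                bilin("R2", ("region",), "kappa_region"),
            ],
            kappas=[
                KappaSpec("kappa_as", "sex_paired", "var1_drift"),
                KappaSpec("kappa_region", "scalar", "ar1_drift"),
            ],
        )
    raise ValueError(f"unknown component {component}")
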