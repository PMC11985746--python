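"""Latent time-effect processes for the bilinear terms.

Each kappa series is anchored at zero in the first observed period (an
identification constraint) and evolves as one of:

- ``ar1_drift``:    kappa_t ~ N(phi1 + phi2 * kappa_{t-1}, sigma^2), phi2 in [0, 1]
- ``ar1_nodrift``:  as above with phi1 = 0 (used for fertility)
- ``rw_drift``:     phi2 = 1 (random walk with drift)
- ``mrw_drift``:    sex-paired bivariate random walk with drift and
                    covariance Sigma = D Omega D (used for mortality)
- ``var1_drift``:   sex-paired VAR(1) with drift, diagonal autoregression and
                    covariance Sigma = D Omega D (immigration/emigration)

Note on the covariance decomposition: the marginal standard deviations
sigma_M, sigma_F sit in the diagonal matrix D and Omega is the correlation
matrix, so Sigma = D Omega D (the form in which D is the matrix of marginal
standard deviations of Sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DYNAMICS = ("ar1_drift", "ar1_nodrift", "rw_drift", "mrw_drift", "var1_drift")


@dataclass(frozen=True)
class KappaSpec:
    """Declaration of one latent time-effect series."""

    name: str
    dimension: str  # "scalar" | "sex_paired"
    dynamics: str

    def __post_init__(self):
        if self.dimension not in ("scalar", "sex_paired"):
            raise ValueError(f"unknown kappa dimension {self.dimension}")
        if self.dynamics not in DYNAMICS:
            raise ValueError(f"unknown dynamics {self.dynamics}")
        if self.dynamics in ("mrw_drift", "var1_drift") and self.dimension != "sex_paired":
            raise ValueError(f"{self.dynamics} requires a sex-paired series")

    @property
    def n_series(self) -> int:
        return 2 if self.dimension == "sex_paired" else 1


def ar1_logdensity(kappa: np.ndarray, phi1: float, phi2: float, sigma: float) -> float:
    """Log density of a kappa path under the (possibly driftless) AR(1).

    The first value is the fixed anchor (kappa_1 = 0) and carries no density;
    with phi2 = 1 this is the random-walk-with-drift density.
    """
    kappa = np.asarray(kappa, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if kappa.size < 2:
        raise ValueError("need at least two time points")
    mean = phi1 + phi2 * kappa[:-1]
    return float(stats.norm.logpdf(kappa[1:], loc=mean, scale=sigma).sum())


def cov_from_corr(Omega: np.ndarray, sigmas: tuple[float, float] | np.ndarray) -> np.ndarray:
    """Covariance with marginal sds ``sigmas`` and correlation ``Omega``."""
    Omega = np.asarray(Omega, dtype=float)
    sig = np.asarray(sigmas, dtype=float)
    if Omega.shape[0] != Omega.shape[1] or not np.allclose(Omega, Omega.T):
        raise ValueError("Omega must be symmetric")
    if not np.allclose(np.diag(Omega), 1.0):
        raise ValueError("Omega must have a unit diagonal")
    if np.any(np.linalg.eigvalsh(Omega) <= 0):
        raise ValueError("Omega must be positive definite")
    if np.any(sig <= 0):
        raise ValueError("marginal standard deviations must be positive")
    D = np.diag(sig)
    return D @ Omega @ D


def lkj_logdensity(Omega: np.ndarray, eta: float) -> float:
    """Unnormalised LKJ log density: (eta - 1) * log det Omega.

    With eta = 1 this is constant (a uniform prior over valid correlation
    matrices); eta > 1 shrinks towards the identity.
    """
    Omega = np.asarray(Omega, dtype=float)
    if not np.allclose(Omega, Omega.T) or not np.allclose(np.diag(Omega), 1.0):
        raise ValueError("invalid correlation matrix")
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        raise ValueError("correlation matrix not positive definite")
    return float((eta - 1.0) * logdet)


# prior hyperparameters for the time-series parameters
PHI1_SD = 2.0
PHI2_MEAN, PHI2_SD = 0.5, 0.2
LKJ_ETA = 2.0


def dynamics_prior_logdensity(params: dict) -> float:
    """Sum of the stated priors over whichever dynamics parameters are present.

    ``phi1 ~ N(0, 2^2)``; ``phi2 ~ N(0.5, 0.2^2)`` truncated to [0, 1]
    (``-inf`` outside); ``sigma`` (univariate innovation sd) half-standard
    normal; ``sigmas`` (marginal sds of a paired series) half-N(0, 1); and
    ``Omega ~ LKJ(2)``.
    """
    total = 0.0
    if "phi1" in params:
        total += float(stats.norm.logpdf(np.asarray(params["phi1"]), 0.0, PHI1_SD).sum())
    if "phi2" in params:
        phi2 = np.atleast_1d(np.asarray(params["phi2"], dtype=float))
        if np.any((phi2 < 0.0) | (phi2 > 1.0)):
            return -np.inf
        a = (0.0 - PHI2_MEAN) / PHI2_SD
        b = (1.0 - PHI2_MEAN) / PHI2_SD
        total += float(stats.truncnorm.logpdf(phi2, a, b, loc=PHI2_MEAN, scale=PHI2_SD).sum())
    for key in ("sigma", "sigmas"):
        if key in params:
            sig = np.atleast_1d(np.asarray(params[key], dtype=float))
            if np.any(sig <= 0):
                return -np.inf
            # half-normal(0, 1): 2 * N(sig; 0, 1)
            total += float((np.log(2.0) + stats.norm.logpdf(sig, 0.0, 1.0)).sum())
    if "Omega" in params:
        total += lkj_logdensity(np.asarray(params["Omega"]), LKJ_ETA)
    return float(total)


def forecast_path(
    spec: KappaSpec,
    params: dict,
    last_kappa: float | np.ndarray,
    horizon: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Iterated simulation of future kappa values from the fitted process.

    Returns shape ``(horizon,)`` for a scalar series or ``(horizon, 2)`` for
    a sex-paired series.  With zero innovation variance this is the
    deterministic recursion.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if spec.dimension == "scalar":
        phi1 = float(params.get("phi1", 0.0))
        phi2 = 1.0 if spec.dynamics == "rw_drift" else float(params.get("phi2", 0.0))
        if spec.dynamics == "ar1_nodrift":
            phi1 = 0.0
        sigma = float(params["sigma"])
        out = np.empty(horizon)
        k = float(np.asarray(last_kappa).ravel()[0])
        for h in range(horizon):
            k = phi1 + phi2 * k + sigma * rng.standard_normal()
            out[h] = k
        return out

    # sex-paired
    phi1 = np.asarray(params.get("phi1", (0.0, 0.0)), dtype=float)
    if spec.dynamics == "mrw_drift":
        phi2 = np.ones(2)
    else:
        phi2 = np.asarray(params["phi2"], dtype=float)
    Sigma = np.asarray(params["Sigma"], dtype=float)
    if np.allclose(Sigma, 0.0):
        L = np.zeros((2, 2))
    else:
        L = np.linalg.cholesky(Sigma)
    out = np.empty((horizon, 2))
    k = np.asarray(last_kappa, dtype=float).copy()
    for h in range(horizon):
        k = phi1 + phi2 * k + L @ rng.standard_normal(2)
        out[h] = k
    return out
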