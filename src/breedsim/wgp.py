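"""Whole-genome prediction: marker-effect models, GEBVs and cross-validation.

Five model kinds are provided, matching the usual genomic-prediction
alphabet:

* ``rr``     — ridge regression / RR-BLUP; variance components by REML on the
               equivalent kinship (GBLUP) model, marker effects backsolved.
* ``bl``     — Bayesian Lasso (double-exponential prior), Gibbs.
* ``ebl``    — extended Bayesian Lasso (marker-specific shrinkage with
               hyperparameter theta), Gibbs.
* ``bayesc`` — spike-and-slab with common slab variance and inclusion
               probability pi, Gibbs; reports per-marker inclusion
               probabilities.
* ``rkhs``   — reproducing kernel Hilbert space regression with a Gaussian
               kernel on marker distances, fitted as a kernel mixed model.

For the linear kinds the fitted model is an intercept plus per-marker
additive effects, so GEBV(x) = mu + sum_j x_j beta_j exactly.  Model
accuracy is evaluated by leave-one-out cross-validation: the Pearson
correlation between observed phenotypes and held-out GEBVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from ._mixed import MixedModelFit, fit_mixed_model
from ._samplers import gibbs_bayesc, gibbs_bl, gibbs_ebl
from .data_model import GenotypeMatrix, compute_kinship

__all__ = [
    "MarkerEffectModel",
    "ShrinkageConfig",
    "CVReport",
    "fit_rr",
    "fit_shrinkage",
    "fit_rkhs",
    "fit_model",
    "predict_gebv",
    "loocv",
    "best_method_per_trait",
    "LINEAR_KINDS",
    "MODEL_KINDS",
]

LINEAR_KINDS = ("rr", "bl", "ebl", "bayesc")
MODEL_KINDS = LINEAR_KINDS + ("rkhs",)


@dataclass
class ShrinkageConfig:
    """Sampler settings and hyperpriors for the Gibbs-fitted models.

    theta is the rate of the Gamma hyperprior on the EBL marker-specific
    shrinkage multipliers; the default 1e-4 gives the diffuse setting used
    for association scanning.  pi0 is the prior inclusion probability for
    BayesC (estimated from the data unless ``estimate_pi`` is False).
    """

    niter: int = 1500
    burnin: int = 500
    seed: int = 0
    # BL
    r_lambda: float = 1.0
    delta_lambda: float = 1e-4
    # EBL
    phi: float = 1.0
    omega: float = 0.1
    psi: float = 1.0
    theta: float = 1e-4
    # BayesC
    pi0: float = 0.1
    estimate_pi: bool = True
    # residual variance prior
    nu_e: float = 4.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0, 1)")
        if self.niter <= self.burnin:
            raise ValueError("iterations must exceed burn-in")


@dataclass
class MarkerEffectModel:
    """A fitted WGP model that can score arbitrary genotypes.

    Linear kinds store an intercept and m additive effects (any centring used
    during fitting is folded into the intercept, so prediction is literally
    mu + X beta).  RKHS stores the training genotypes, dual weights and
    bandwidth instead.
    """

    model_kind: str
    mu: float
    marker_ids: list[str]
    beta: np.ndarray | None = None
    # RKHS representation
    train_X: np.ndarray | None = None
    alpha: np.ndarray | None = None
    bandwidth: float | None = None
    hyperparameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    inclusion_prob: np.ndarray | None = None

    def predict(self, g: GenotypeMatrix | np.ndarray) -> np.ndarray:
        return predict_gebv(self, g)


@dataclass
class CVReport:
    trait: str
    method: str
    accuracy: float
    predictions: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        if np.isfinite(self.accuracy) and not -1.0 <= self.accuracy <= 1.0 + 1e-12:
            raise ValueError("accuracy must lie in [-1, 1]")


def _as_dosage(g: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(g, GenotypeMatrix):
        return g.imputed(), list(g.marker_ids)
    x = np.asarray(g, dtype=float)
    return x, [f"m{j}" for j in range(x.shape[1])]


def _check_y(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size != n:
        raise ValueError("phenotype length does not match genotype rows")
    if np.isnan(y).any():
        raise ValueError("missing phenotypes are not allowed in training")
    return y


def fit_rr(
    g: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    delta: float | None = None,
) -> MarkerEffectModel:
    """RR-BLUP: ridge regression with REML-estimated shrinkage.

    The variance components are estimated on the equivalent GBLUP model
    (VanRaden kinship), then the marker effects are recovered in the dual
    form beta = Z' V^{-1} (y - mu) * sigma2_g / c with Z the centred dosages
    and c = 2 sum p(1-p).  ``delta`` fixes the variance ratio
    sigma2_e/sigma2_g instead of estimating it (used by equivalence tests).
    """
    X, marker_ids = _as_dosage(g)
    n, m = X.shape
    y = _check_y(y, n)
    if n < 2:
        raise ValueError("at least two individuals are required")
    if m == 0 or np.allclose(y, y[0]):
        return MarkerEffectModel(
            model_kind="rr", mu=float(y.mean()),
            marker_ids=marker_ids, beta=np.zeros(m),
            diagnostics={"degenerate": True},
        )
    p = X.mean(axis=0) / 2.0
    c = 2.0 * float(np.sum(p * (1.0 - p)))
    if c <= 0:
        raise ValueError("all markers are monomorphic")
    Z = X - 2.0 * p
    K = Z @ Z.T / c
    ones = np.ones((n, 1))
    if delta is None:
        fit = fit_mixed_model(y, ones, K)
    else:
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        w = 1.0 / (d + delta)
        yr, Xr = U.T @ y, U.T @ ones
        XtWX = (Xr * w[:, None]).T @ Xr
        beta0 = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
        r = yr - Xr @ beta0
        s2g = float(np.sum(r * r * w) / (n - 1))
        fit = MixedModelFit(
            beta=beta0, sigma2_g=s2g, sigma2_e=s2g * delta, delta=delta,
            eigenvalues=d, eigenvectors=U, X=ones, y=y,
            reml_loglik=np.nan, converged=True,
        )
    if not fit.converged:
        warnings.warn("REML variance estimation did not converge", stacklevel=2)
    mu_gls = float(fit.beta[0])
    if np.isinf(fit.delta):
        beta = np.zeros(m)
    else:
        beta = Z.T @ fit.vinv_residual() / c
    intercept = mu_gls - float(2.0 * p @ beta)  # fold centring into mu
    return MarkerEffectModel(
        model_kind="rr",
        mu=intercept,
        marker_ids=marker_ids,
        beta=beta,
        hyperparameters={"delta": fit.delta},
        diagnostics={
            "sigma2_g": fit.sigma2_g,
            "sigma2_e": fit.sigma2_e,
            "converged": fit.converged,
            "mu_gls": mu_gls,
        },
    )


def fit_shrinkage(
    g: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    method: str,
    config: ShrinkageConfig | None = None,
) -> MarkerEffectModel:
    """Fit BL, EBL or BayesC by Gibbs sampling; effects are posterior means."""
    method = method.lower()
    if method not in ("bl", "ebl", "bayesc"):
        raise ValueError(f"unknown shrinkage method {method!r}")
    cfg = config or ShrinkageConfig()
    X, marker_ids = _as_dosage(g)
    n, m = X.shape
    y = _check_y(y, n)
    if n < 2:
        raise ValueError("at least two individuals are required")
    if m == 0 or np.allclose(y, y[0]):
        return MarkerEffectModel(
            model_kind=method, mu=float(y.mean()),
            marker_ids=marker_ids, beta=np.zeros(m),
            diagnostics={"degenerate": True},
        )
    X = np.asfortranarray(X, dtype=np.float64)  # column access dominates
    yv = np.ascontiguousarray(y, dtype=np.float64)
    vy = float(np.var(yv))
    s_e = vy / 2.0 if vy > 0 else 1.0
    seed = int(cfg.seed) % (2**31 - 1)
    pip = None
    if method == "bl":
        mu, beta, s2e, lam2 = gibbs_bl(
            X, yv, cfg.niter, cfg.burnin, seed,
            cfg.r_lambda, cfg.delta_lambda, cfg.nu_e, s_e,
        )
        diag = {"sigma2_e": s2e, "lambda2": lam2}
    elif method == "ebl":
        mu, beta, s2e = gibbs_ebl(
            X, yv, cfg.niter, cfg.burnin, seed,
            cfg.phi, cfg.omega, cfg.psi, cfg.theta, cfg.nu_e, s_e,
        )
        diag = {"sigma2_e": s2e}
    else:
        p = X.mean(axis=0) / 2.0
        het = 2.0 * float(np.sum(p * (1.0 - p)))
        # prior slab scale from the expected-genetic-variance heuristic
        s_b = (vy / 2.0) / max(cfg.pi0 * het, 1e-8)
        mu, beta, pip, s2e, pi_mean = gibbs_bayesc(
            X, yv, cfg.niter, cfg.burnin, seed,
            cfg.pi0, cfg.estimate_pi, cfg.nu_e, s_e, 4.0, s_b,
        )
        diag = {"sigma2_e": s2e, "pi": pi_mean}
    if not np.all(np.isfinite(beta)):
        raise RuntimeError(
            f"{method} sampler diverged: non-finite effects; diagnostics {diag}"
        )
    diag.update({"niter": cfg.niter, "burnin": cfg.burnin, "seed": cfg.seed})
    return MarkerEffectModel(
        model_kind=method,
        mu=float(mu),
        marker_ids=marker_ids,
        beta=np.asarray(beta, dtype=float),
        hyperparameters={"theta": cfg.theta} if method == "ebl" else {},
        diagnostics=diag,
        inclusion_prob=None if pip is None else np.asarray(pip, dtype=float),
    )


def _gaussian_kernel(A: np.ndarray, B: np.ndarray, bandwidth: float, m: int) -> np.ndarray:
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    d2 = np.clip(d2, 0.0, None)
    return np.exp(-d2 / (bandwidth * m))


def fit_rkhs(
    g: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    bandwidth: float | None = None,
) -> MarkerEffectModel:
    """Kernel mixed model with Gaussian kernel K = exp(-d^2 / (h m)).

    ``bandwidth`` defaults to the median of the pairwise squared marker
    distances divided by m (the median heuristic).
    """
    X, marker_ids = _as_dosage(g)
    n, m = X.shape
    y = _check_y(y, n)
    if m == 0 or np.allclose(y, y[0]):
        return MarkerEffectModel(
            model_kind="rkhs", mu=float(y.mean()), marker_ids=marker_ids,
            train_X=X, alpha=np.zeros(n), bandwidth=bandwidth or 1.0,
            diagnostics={"degenerate": True},
        )
    if bandwidth is None:
        d2 = pdist(X, metric="sqeuclidean")
        med = float(np.median(d2))
        bandwidth = med / m if med > 0 else 1.0
    K = _gaussian_kernel(X, X, bandwidth, m)
    jitter = 1e-8 * np.eye(n)
    try:
        np.linalg.cholesky(K + jitter)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("kernel not PSD after jitter") from exc
    fit = fit_mixed_model(y, np.ones((n, 1)), K)
    alpha = np.zeros(n) if np.isinf(fit.delta) else fit.vinv_residual()
    return MarkerEffectModel(
        model_kind="rkhs",
        mu=float(fit.beta[0]),
        marker_ids=marker_ids,
        train_X=X,
        alpha=alpha,
        bandwidth=float(bandwidth),
        hyperparameters={"bandwidth": float(bandwidth)},
        diagnostics={
            "sigma2_g": fit.sigma2_g,
            "sigma2_e": fit.sigma2_e,
            "converged": fit.converged,
        },
    )


def fit_model(
    g,
    y,
    method: str,
    config: ShrinkageConfig | None = None,
    **kwargs,
) -> MarkerEffectModel:
    """Dispatch on the model kind; the registry accepts future additions."""
    method = method.lower()
    if method == "rr":
        return fit_rr(g, y, **kwargs)
    if method in ("bl", "ebl", "bayesc"):
        return fit_shrinkage(g, y, method, config=config)
    if method == "rkhs":
        return fit_rkhs(g, y, **kwargs)
    raise ValueError(f"unknown model kind {method!r}; known: {MODEL_KINDS}")


def predict_gebv(model: MarkerEffectModel, g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """GEBVs for new genotypes; marker set and order must match training."""
    X, marker_ids = _as_dosage(g)
    if isinstance(g, GenotypeMatrix):
        if marker_ids != model.marker_ids:
            for a, b in zip(marker_ids, model.marker_ids):
                if a != b:
                    raise ValueError(f"marker mismatch: {a!r} != model {b!r}")
            raise ValueError("marker count differs from the trained model")
    elif X.shape[1] != len(model.marker_ids):
        raise ValueError("marker count differs from the trained model")
    if model.model_kind == "rkhs":
        Kq = _gaussian_kernel(X, model.train_X, model.bandwidth, X.shape[1] or 1)
        return model.mu + Kq @ model.alpha
    return model.mu + X @ model.beta


def loocv(
    g: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    method: str,
    config: ShrinkageConfig | None = None,
    trait: str = "trait",
    **kwargs,
) -> CVReport:
    """Leave-one-out cross-validation accuracy for one trait and method."""
    X, marker_ids = _as_dosage(g)
    n = X.shape[0]
    y = _check_y(y, n)
    if n < 3:
        raise ValueError("LOOCV needs at least three individuals")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        cfg = config
        if cfg is not None:
            cfg = replace(cfg, seed=cfg.seed + 7919 * i)
        model = fit_model(X[mask], y[mask], method, config=cfg, **kwargs)
        preds[i] = predict_gebv(model, X[i : i + 1])[0]
    if np.std(preds) == 0 or np.std(y) == 0:
        acc = np.nan
    else:
        acc = float(pearsonr(y, preds)[0])
    return CVReport(trait=trait, method=method, accuracy=acc, predictions=preds, observed=y)


def best_method_per_trait(reports: list[CVReport]) -> pd.DataFrame:
    """Pick, per trait, the method with the highest LOOCV accuracy."""
    df = pd.DataFrame(
        [(r.trait, r.method, r.accuracy) for r in reports],
        columns=["trait", "method", "accuracy"],
    )
    idx = df.groupby("trait")["accuracy"].idxmax()
    return df.loc[idx].reset_index(drop=True)
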