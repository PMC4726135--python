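"""Single-kernel linear mixed model fitted by spectral REML.

Model: y = X b + u + e with u ~ N(0, sigma2_g K) and e ~ N(0, sigma2_e I).
The kernel K is eigendecomposed once and the restricted likelihood profiled
over the variance ratio delta = sigma2_e / sigma2_g with a bounded 1-D
optimiser (the EMMA formulation), which is exact and fast for the panel
sizes this package targets (n in the tens to hundreds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["MixedModelFit", "fit_mixed_model"]

_LOG_DELTA_BOUNDS = (-12.0, 12.0)


@dataclass
class MixedModelFit:
    beta: np.ndarray  # fixed-effect estimates (GLS)
    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    X: np.ndarray
    y: np.ndarray
    reml_loglik: float
    converged: bool

    @property
    def weights(self) -> np.ndarray:
        """Rotated-space inverse variances 1 / (d_i + delta) (up to sigma2_g)."""
        return 1.0 / (self.eigenvalues + self.delta)

    def vinv_residual(self) -> np.ndarray:
        """V^{-1}(y - Xb) * sigma2_g, i.e. U W U' (y - Xb)."""
        U = self.eigenvectors
        r = self.y - self.X @ self.beta
        return U @ (self.weights * (U.T @ r))

    def blup_u(self, K: np.ndarray) -> np.ndarray:
        """BLUP of the genetic values u = sigma2_g K V^{-1}(y - Xb)."""
        return K @ self.vinv_residual()


def _profile(log_delta: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    r = yr - Xr @ beta
    q = float(np.sum(r * r * w))
    return delta, w, beta, q, XtWX


def fit_mixed_model(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> MixedModelFit:
    """REML fit of the one-kernel mixed model via eigendecomposition of K."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y have incompatible shapes")
    if n - p < 1:
        raise ValueError("more fixed effects than residual degrees of freedom")
    d, U = np.linalg.eigh(np.asarray(K, dtype=float))
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    nf = n - p

    def neg_reml(log_delta: float) -> float:
        delta, w, beta, q, XtWX = _profile(log_delta, d, yr, Xr)
        if q <= 0:
            return np.inf
        s2 = q / nf
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            nf * (np.log(2.0 * np.pi * s2) + 1.0)
            - np.sum(np.log(w))
            + logdet_xwx
        )
        return -ll

    # degenerate response: no variance to decompose
    if np.allclose(y, y[0]):
        beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
        return MixedModelFit(
            beta=beta0, sigma2_g=0.0, sigma2_e=0.0, delta=np.inf,
            eigenvalues=d, eigenvectors=U, X=X, y=y,
            reml_loglik=np.nan, converged=True,
        )

    opt = minimize_scalar(
        neg_reml, bounds=_LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    delta, w, beta, q, _ = _profile(opt.x, d, yr, Xr)
    sigma2_g = q / nf
    sigma2_e = sigma2_g * delta
    return MixedModelFit(
        beta=beta,
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        delta=float(delta),
        eigenvalues=d,
        eigenvectors=U,
        X=X,
        y=y,
        reml_loglik=float(-opt.fun),
        converged=bool(opt.success),
    )
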