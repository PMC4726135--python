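"""Association scans and marker-based regression for marker-assisted selection.

Two scan flavours:

* ``mlm_scan`` — single-marker mixed linear model with a VanRaden kinship
  as the polygenic covariance and the leading principal components of the
  dosage matrix as fixed covariates (default 6).  Variance components are
  estimated once on the null model and reused for every marker (the
  P3D/EMMAX approximation); Wald t-tests give the p-values, thresholded by
  Benjamini–Hochberg FDR (default 5%).

* ``ebl_scan`` — multi-marker scan: the extended Bayesian Lasso fit of the
  trait on all markers simultaneously (theta default 1e-4), with
  associations called where |posterior-mean effect| exceeds k standard
  deviations of all effects.  The k·SD call rule is this package's policy —
  a numeric convention for turning a shrinkage profile into a hit list.

``sig_marker_regression`` then mirrors the marker-assisted-selection
assessment: an OLS fit of the trait on the significant markers with
bidirectional stepwise selection minimising AIC, reporting the selected
marker count and the model r².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._mixed import fit_mixed_model
from .data_model import GenotypeMatrix
from .wgp import MarkerEffectModel, ShrinkageConfig, fit_shrinkage

__all__ = [
    "GWASResult",
    "SigMarkerRegression",
    "mlm_scan",
    "fdr_significant",
    "ebl_scan",
    "sig_marker_regression",
    "genotype_pcs",
]


@dataclass
class GWASResult:
    table: pd.DataFrame  # marker_id, effect, stat, p, q, significant
    method: str
    n_pcs: int
    fdr_level: float
    extra: dict = field(default_factory=dict)

    @property
    def significant_markers(self) -> list[str]:
        t = self.table
        flags = t["significant"].map(lambda v: bool(v) if v is not None else False)
        return t.loc[flags, "marker_id"].tolist()


@dataclass
class SigMarkerRegression:
    candidates: list[str]
    selected: list[str]
    coefficients: pd.Series
    r2: float

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.candidates):
            raise ValueError("selected markers must be a subset of candidates")
        if not -1e-9 <= self.r2 <= 1.0 + 1e-9:
            raise ValueError("r2 must lie in [0, 1]")


def genotype_pcs(g: GenotypeMatrix | np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading principal-component scores of the centred dosage matrix."""
    x = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    if n_pcs == 0:
        return np.empty((x.shape[0], 0))
    if n_pcs >= x.shape[0]:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def mlm_scan(
    g: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    kinship: np.ndarray,
    n_pcs: int = 6,
    fdr_level: float = 0.05,
    exact: bool = False,
) -> GWASResult:
    """Single-marker MLM scan: y = PCs a + x_j b_j + u + e, u ~ N(0, s2g K).

    With ``exact=False`` (default) the null-model REML variance components
    are fixed and each marker is tested by GLS under that covariance;
    ``exact=True`` re-estimates the variance components per marker.
    Zero-variance markers get NaN statistics.
    """
    x = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    marker_ids = g.marker_ids if isinstance(g, GenotypeMatrix) else [
        f"m{j}" for j in range(x.shape[1])
    ]
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.shape
    pcs = genotype_pcs(g, n_pcs)
    X0 = np.column_stack([np.ones(n), pcs])
    p0 = X0.shape[1]
    null = fit_mixed_model(y, X0, kinship)
    U, d = null.eigenvectors, null.eigenvalues
    w = 1.0 / (d + null.delta)
    yr = U.T @ y
    X0r = U.T @ X0
    Mr = U.T @ x
    # weighted projection removing the covariates
    WX0 = X0r * w[:, None]
    G = np.linalg.solve(X0r.T @ WX0, WX0.T)
    resid = lambda A: A - X0r @ (G @ A)
    y_perp = resid(yr)
    effects = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    dof = n - p0 - 1
    if exact:
        for j in range(m):
            xj = x[:, j]
            if np.std(xj) == 0:
                continue
            fit_j = fit_mixed_model(y, np.column_stack([X0, xj]), kinship)
            wj = 1.0 / (fit_j.eigenvalues + fit_j.delta)
            Xr_j = fit_j.eigenvectors.T @ np.column_stack([X0, xj])
            XtWX = (Xr_j * wj[:, None]).T @ Xr_j
            cov = np.linalg.inv(XtWX) * fit_j.sigma2_g
            b = fit_j.beta[-1]
            se = np.sqrt(cov[-1, -1])
            effects[j], stat[j] = b, b / se
            pvals[j] = 2 * stats.t.sf(abs(stat[j]), dof)
    else:
        M_perp = resid(Mr)
        denom = np.einsum("ij,ij->j", M_perp, M_perp * w[:, None])
        numer = M_perp.T @ (w * y_perp)
        ok = (denom > 1e-12) & (x.std(axis=0) > 0)
        effects[ok] = numer[ok] / denom[ok]
        se = np.sqrt(null.sigma2_g / denom[ok])
        stat[ok] = effects[ok] / se
        pvals[ok] = 2 * stats.t.sf(np.abs(stat[ok]), dof)
    flags, qvals, cutoff = fdr_significant(pvals, level=fdr_level)
    table = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "effect": effects,
            "stat": stat,
            "p": pvals,
            "q": qvals,
            "significant": flags,
        }
    )
    return GWASResult(
        table=table,
        method="mlm",
        n_pcs=n_pcs,
        fdr_level=fdr_level,
        extra={
            "sigma2_g": null.sigma2_g,
            "sigma2_e": null.sigma2_e,
            "p_cutoff": cutoff,
            "exact": exact,
        },
    )


def fdr_significant(
    pvalues: np.ndarray, level: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Benjamini–Hochberg step-up at ``level``.

    Returns (significant flags, q-values, realised p-value cutoff); the
    cutoff is the largest p-value rejected (NaN when nothing is rejected).
    NaN p-values are excluded from the procedure and flagged missing.
    """
    p = np.asarray(pvalues, dtype=float)
    flags = np.zeros(p.shape, dtype=object)
    qvals = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        rej, q, *_ = multipletests(p[ok], alpha=level, method="fdr_bh")
        flags[ok] = rej
        qvals[ok] = q
    flags = np.where(ok, flags.astype(bool), None)
    rejected = p[ok][np.asarray(flags[ok], dtype=bool)] if ok.any() else np.array([])
    cutoff = float(rejected.max()) if rejected.size else float("nan")
    return flags, qvals, cutoff


def ebl_scan(
    g: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    theta: float = 1e-4,
    config: ShrinkageConfig | None = None,
    call_sd: float = 5.0,
) -> tuple[MarkerEffectModel, pd.DataFrame]:
    """EBL multi-marker scan; shares the WGP fitting code path exactly."""
    cfg = config or ShrinkageConfig()
    if config is None or config.theta != theta:
        from dataclasses import replace

        cfg = replace(cfg, theta=theta)
    model = fit_shrinkage(g, y, "ebl", config=cfg)
    beta = model.beta
    sd = float(np.std(beta))
    called = np.abs(beta) > call_sd * sd if sd > 0 else np.zeros(len(beta), bool)
    table = pd.DataFrame(
        {
            "marker_id": model.marker_ids,
            "effect": beta,
            "abs_effect_sd": np.abs(beta) / sd if sd > 0 else np.zeros(len(beta)),
            "called": called,
        }
    )
    return model, table


def _aic(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    if rss <= 0:
        rss = 1e-12
    k = X.shape[1]
    return n * np.log(rss / n) + 2 * k


def sig_marker_regression(
    y: np.ndarray,
    g: GenotypeMatrix | np.ndarray,
    candidate_ids: list[str] | None = None,
) -> SigMarkerRegression:
    """OLS on significant markers with bidirectional stepwise AIC selection.

    Starts from the full candidate model (collinear columns dropped first)
    and alternates drop/add steps until AIC no longer improves.  With a
    single candidate no selection is performed.
    """
    if isinstance(g, GenotypeMatrix):
        X_all = g.imputed()
        ids = list(g.marker_ids)
    else:
        X_all = np.asarray(g, dtype=float)
        ids = candidate_ids or [f"m{j}" for j in range(X_all.shape[1])]
    if candidate_ids is not None and isinstance(g, GenotypeMatrix):
        idx = [ids.index(c) for c in candidate_ids]
        X_all = X_all[:, idx]
        ids = list(candidate_ids)
    y = np.asarray(y, dtype=float).ravel()
    if X_all.shape[1] == 0:
        raise ValueError("at least one candidate marker is required")
    n = len(y)

    # drop exactly collinear candidates (keep first of each aliased group)
    keep: list[int] = []
    ones = np.ones((n, 1))
    for j in range(X_all.shape[1]):
        trial = np.column_stack([ones] + [X_all[:, k] for k in keep + [j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    current = set(keep)
    pool = set(keep)

    def design(sel: set[int]) -> np.ndarray:
        cols = [ones] + [X_all[:, j][:, None] for j in sorted(sel)]
        return np.hstack(cols)

    if len(pool) > 1:
        best = _aic(y, design(current))
        improved = True
        while improved:
            improved = False
            moves: list[tuple[float, str, int]] = []
            for j in sorted(current):
                if len(current) > 0:
                    moves.append((_aic(y, design(current - {j})), "drop", j))
            for j in sorted(pool - current):
                moves.append((_aic(y, design(current | {j})), "add", j))
            if moves:
                moves.sort(key=lambda t: (t[0], t[2]))
                aic_new, kind, j = moves[0]
                if aic_new < best - 1e-10:
                    best = aic_new
                    current = current - {j} if kind == "drop" else current | {j}
                    improved = True
    selected = sorted(current)
    sel_ids = [ids[j] for j in selected]
    Xd = sm.add_constant(X_all[:, selected]) if selected else ones
    fit = sm.OLS(y, Xd).fit()
    r2 = float(fit.rsquared) if selected else 0.0
    names = ["const"] + sel_ids
    coefs = pd.Series(np.atleast_1d(fit.params), index=names[: len(np.atleast_1d(fit.params))])
    return SigMarkerRegression(
        candidates=ids, selected=sel_ids, coefficients=coefs, r2=max(0.0, min(1.0, r2))
    )
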