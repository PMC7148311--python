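"""Relating module eigengenes to environmental covariates.

Redundancy analysis (RDA) is the constrained ordination at the heart of
this stage: a PCA of the part of the response matrix (eigengene dynamics)
explained by multivariate linear regression on explanatory variables
(abiotic factors, cell densities, taxon RAT). Per-pair Pearson/Spearman
correlations with Benjamini-Hochberg control complement the ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class RDAResult:
    """Constrained ordination output (correlation-biplot convention)."""

    sample_scores: pd.DataFrame  # sample x axis
    response_scores: pd.DataFrame  # response variable x axis
    biplot_scores: pd.DataFrame  # explanatory variable x axis (corr with axes)
    eigenvalues: pd.Series  # per constrained axis, non-increasing
    constrained_fraction: float  # ||Yhat||_F^2 / ||Y||_F^2, in [0, 1]
    dropped_predictors: list[str]


def standardize_env(env: pd.DataFrame, interpolate: bool = True) -> pd.DataFrame:
    """Z-score each explanatory column; linearly interpolate missing values.

    Mixed units (salinity, m^3/s, cells/L) make raw-scale fitting
    meaningless, so variables are standardized before entering the RDA.
    """
    filled = env.astype(float)
    if interpolate and filled.isna().any().any():
        n_missing = int(filled.isna().sum().sum())
        logger.warning("interpolating %d missing environmental values", n_missing)
        filled = filled.interpolate(axis=0, limit_direction="both")
    sd = filled.std(ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping constant columns: %s", list(sd.index[~keep]))
    filled = filled.loc[:, keep]
    return (filled - filled.mean()) / filled.std(ddof=0)


def rda(Y: pd.DataFrame, X: pd.DataFrame, standardize: bool = True) -> RDAResult:
    """Redundancy analysis of responses Y on explanatory variables X.

    Both matrices are sample x variable with aligned indexes. Y and X are
    column-centered (X optionally z-scored); the fitted values
    Yhat = X (X'X)^- X' Y are decomposed by SVD into orthogonal constrained
    axes. Eigenvalues are the squared singular values divided by (n - 1);
    the constrained fraction is ||Yhat||^2_F / ||Y||^2_F. Biplot scores are
    Pearson correlations of the explanatory columns with the sample axis
    scores (a 'scaling 2' correlation biplot).
    """
    if not Y.index.equals(X.index):
        raise ValueError("Y and X must share the same sample index")
    n = len(Y)
    if n < 3:
        raise ValueError("RDA needs at least 3 samples")

    dropped = [c for c in X.columns if X[c].astype(float).std(ddof=0) == 0]
    if dropped:
        logger.warning("constant explanatory columns dropped: %s", dropped)
    Xs = standardize_env(X.drop(columns=dropped)) if standardize else (
        X.drop(columns=dropped) - X.drop(columns=dropped).mean()
    )
    Yc = Y - Y.mean()

    Xa = Xs.to_numpy(dtype=float)
    Ya = Yc.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        logger.warning("rank-deficient explanatory matrix; pseudo-inverse used")
    beta, *_ = np.linalg.lstsq(Xa, Ya, rcond=None)
    Yhat = Xa @ beta

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = int((s > s.max() * 1e-10).sum()) if s.size and s.max() > 0 else 0
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    axes = [f"RDA{i + 1}" for i in range(n_axes)]

    sample_scores = pd.DataFrame(U * s, index=Y.index, columns=axes)
    response_scores = pd.DataFrame(Vt.T, index=Y.columns, columns=axes)
    eigenvalues = pd.Series(s**2 / (n - 1), index=axes, name="eigenvalue")

    total = float((Ya**2).sum())
    constrained = float((Yhat**2).sum())
    fraction = constrained / total if total > 0 else 0.0

    biplot = np.zeros((Xs.shape[1], n_axes))
    for j in range(Xs.shape[1]):
        for k in range(n_axes):
            col = sample_scores.iloc[:, k].to_numpy()
            if col.std(ddof=0) > 0:
                biplot[j, k] = np.corrcoef(Xa[:, j], col)[0, 1]
    biplot_scores = pd.DataFrame(biplot, index=Xs.columns, columns=axes)

    return RDAResult(
        sample_scores=sample_scores,
        response_scores=response_scores,
        biplot_scores=biplot_scores,
        eigenvalues=eigenvalues,
        constrained_fraction=min(1.0, fraction),
        dropped_predictors=dropped,
    )


def eigengene_env_correlations(
    eigengenes: pd.DataFrame,
    env: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise eigengene-environment correlations with BH-adjusted p-values.

    ``eigengenes`` is module x sample, ``env`` sample x variable. Returns
    long-form rows (module, variable, coefficient, p, q). Zero-variance
    series yield missing coefficients, flagged with q = NaN.
    """
    if eigengenes.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    func = stats.pearsonr if method == "pearson" else stats.spearmanr

    rows = []
    for m in eigengenes.index:
        x = eigengenes.loc[m].to_numpy(dtype=float)
        for v in env.columns:
            y = env[v].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((m, v, np.nan, np.nan))
                continue
            r, p = func(x, y)
            rows.append((m, v, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["module", "variable", "coefficient", "p"])
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out
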