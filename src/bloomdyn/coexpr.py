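"""Weighted co-expression module detection with eigengenes.

Reimplements the WGCNA-style core: variance-stabilizing normalization of
the count matrix, a soft-thresholded unsigned correlation network using
the biweight midcorrelation, the topological overlap matrix (TOM),
average-linkage clustering of 1-TOM with a static height cut and a
minimum module size, module eigengenes (first principal component of the
module expression submatrix), and merging of modules whose eigengenes are
highly correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quant import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ModuleParams:
    """Tunable parameters of the module detection.

    soft_power: exponent of the adjacency |corr|^beta (default 6).
    correlation: 'bicor' (robust, default) or 'pearson'.
    min_module_size: clusters smaller than this become unassigned
        (field default 1000 transcripts; synthetic communities use 50).
    merge_corr_threshold: modules whose eigengenes correlate (Pearson)
        strictly above this are merged (default 0.75).
    min_mean_count: transcripts averaging fewer reads across samples are
        discarded before normalization (default 10).
    max_block_size: hard cap on transcripts handled in one block (35000);
        larger inputs raise rather than silently approximate.
    tree_cut_height: static cut height on the 1-TOM dendrogram.
    """

    soft_power: int = 6
    correlation: str = "bicor"
    min_module_size: int = 1000
    merge_corr_threshold: float = 0.75
    min_mean_count: float = 10.0
    max_block_size: int = 35_000
    tree_cut_height: float = 0.95

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.correlation not in ("bicor", "pearson"):
            raise ValueError("correlation must be 'bicor' or 'pearson'")
        if not 0.0 < self.tree_cut_height < 1.0:
            raise ValueError("tree_cut_height must be in (0, 1)")
        if not 0.0 < self.merge_corr_threshold < 1.0:
            raise ValueError("merge_corr_threshold must be in (0, 1)")


@dataclass
class ExpressionMatrix:
    """Variance-stabilized expression, transcript x sample, with provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    trend_a0: float  # dispersion trend alpha(mu) = a0/mu + a1
    trend_a1: float
    fallback_log2: bool = False


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned), eigengenes and sizes."""

    labels: pd.Series  # transcript -> module id
    eigengenes: pd.DataFrame  # module x sample, unit-norm rows
    sizes: pd.Series  # module -> transcript count

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def filter_low_coverage(
    counts: pd.DataFrame, min_mean: float = 10.0
) -> pd.DataFrame:
    """Discard transcripts covered by fewer than ``min_mean`` reads on average."""
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    return counts.loc[counts.mean(axis=1) >= min_mean]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Uses transcripts with nonzero counts in every sample; when none exist,
    falls back to total-count scaling (factors proportional to column sums,
    geometric mean 1), with a log notice.
    """
    arr = counts.to_numpy(dtype=float)
    everywhere = (arr > 0).all(axis=1)
    if not everywhere.any():
        logger.warning("no transcript nonzero in all samples; total-count fallback")
        totals = arr.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns, name="size_factor")
    sub = arr[everywhere]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(counts: pd.DataFrame, factors: pd.Series) -> tuple[float, float]:
    """Fit alpha(mu) = a0/mu + a1 to method-of-moments per-transcript dispersions."""
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    keep = (mu > 0) & (var > mu)  # only overdispersed transcripts inform the trend
    if keep.sum() < 3:
        raise RuntimeError("too few overdispersed transcripts for a trend fit")
    mu_k, disp_k = mu[keep], (var[keep] - mu[keep]) / mu[keep] ** 2

    def model(m: np.ndarray, a0: float, a1: float) -> np.ndarray:
        return a0 / m + a1

    (a0, a1), _ = optimize.curve_fit(
        model, mu_k, disp_k, p0=[1.0, 0.1],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=5000,
    )
    return float(a0), float(a1)


def vst_closed_form(q: np.ndarray | float, a0: float, a1: float) -> np.ndarray:
    """Closed-form NB variance-stabilizing map for the trend a0/mu + a1.

    Monotone increasing in q, asymptotically log2 (differences of one
    doubling approach 1 as q grows).
    """
    q = np.asarray(q, dtype=float)
    return np.log2(
        (1.0 + a0 + 2.0 * a1 * q + 2.0 * np.sqrt(a1 * q * (1.0 + a0 + a1 * q)))
        / (4.0 * a1)
    )


def vst(counts: pd.DataFrame, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Variance-stabilizing transformation of a count matrix.

    Counts are scaled by size factors, a parametric dispersion trend
    alpha(mu) = a0/mu + a1 is fit by regression on method-of-moments
    dispersions, and the closed-form NB stabilizing map for that trend is
    applied. Degenerate fits (non-positive coefficients or no
    overdispersion) fall back to log2(q+1), logged.
    """
    factors = size_factors(counts) if factors is None else factors
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = counts / factors
    try:
        a0, a1 = _fit_dispersion_trend(counts, factors)
        if a0 <= 0 or a1 <= 0:
            raise RuntimeError("degenerate trend coefficients")
        values = pd.DataFrame(
            vst_closed_form(norm.to_numpy(), a0, a1),
            index=counts.index, columns=counts.columns,
        )
        return ExpressionMatrix(values=values, size_factors=factors,
                                trend_a0=a0, trend_a1=a1)
    except RuntimeError as exc:
        logger.warning("VST trend fit failed (%s); falling back to log2(q+1)", exc)
        values = np.log2(norm + 1.0)
        return ExpressionMatrix(values=values, size_factors=factors,
                                trend_a0=float("nan"), trend_a1=float("nan"),
                                fallback_log2=True)


# --------------------------------------------------------------------------
# Correlation and network
# --------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray, c: float = 9.0) -> np.ndarray | None:
    """Tukey-biweight deviations from the median; None when MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (c * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x: np.ndarray, y: np.ndarray, c: float = 9.0) -> float:
    """Biweight midcorrelation of two series, in [-1, 1].

    Median/MAD standardization with Tukey biweight down-weighting
    (tuning constant c = 9). A zero-MAD series falls back to Pearson.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xt, yt = _bicor_transform(x, c), _bicor_transform(y, c)
    if xt is None or yt is None:
        logger.debug("zero MAD; Pearson fallback")
        xs, ys = x - x.mean(), y - y.mean()
        denom = np.sqrt((xs**2).sum() * (ys**2).sum())
        return float(np.dot(xs, ys) / denom) if denom > 0 else float("nan")
    denom = np.sqrt((xt**2).sum() * (yt**2).sum())
    return float(np.clip(np.dot(xt, yt) / denom, -1.0, 1.0))


def correlation_matrix(expression: pd.DataFrame, method: str = "bicor") -> np.ndarray:
    """Pairwise transcript correlations (rows of ``expression``)."""
    X = expression.to_numpy(dtype=float)
    if method == "pearson":
        return np.corrcoef(X)
    if method != "bicor":
        raise ValueError(f"unknown correlation method {method!r}")
    # vectorized bicor: transform each row, then normalized cross-products;
    # rows with zero MAD fall back to their centered values (Pearson-like)
    transformed = np.empty_like(X)
    for i in range(X.shape[0]):
        t = _bicor_transform(X[i])
        transformed[i] = (X[i] - X[i].mean()) if t is None else t
    norms = np.sqrt((transformed**2).sum(axis=1))
    norms[norms == 0] = np.nan
    unit = transformed / norms[:, None]
    return np.clip(unit @ unit.T, -1.0, 1.0)


def adjacency_tom(
    expression: pd.DataFrame, params: ModuleParams | None = None
) -> pd.DataFrame:
    """Soft-thresholded unsigned adjacency and its topological overlap.

    a_uv = |corr(u,v)|^beta;
    TOM_uv = (sum_w a_uw a_wv + a_uv) / (min(k_u, k_v) + 1 - a_uv)
    with k the connectivity (row sum of a, excluding the diagonal).
    TOM is symmetric, in [0, 1], with unit diagonal.
    """
    params = params or ModuleParams()
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expression.shape[0] > params.max_block_size:
        raise ValueError(
            f"{expression.shape[0]} transcripts exceed max_block_size "
            f"{params.max_block_size}"
        )
    corr = correlation_matrix(expression, params.correlation)
    if not np.isfinite(corr).all():
        bad = expression.index[np.argwhere(~np.isfinite(corr))[:, 0]].unique()
        raise ValueError(f"non-finite correlations involving {list(bad[:5])}")
    a = np.abs(corr) ** params.soft_power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    numerator = a @ a + a
    k_min = np.minimum.outer(k, k)
    tom = numerator / (k_min + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=expression.index, columns=expression.index)


# --------------------------------------------------------------------------
# Clustering and eigengenes
# --------------------------------------------------------------------------

def detect_modules(tom: pd.DataFrame, params: ModuleParams | None = None) -> pd.Series:
    """Cluster 1-TOM by average linkage and cut at a fixed height.

    Clusters smaller than ``min_module_size`` are relabeled 0 (unassigned);
    remaining modules are renumbered 1..K by decreasing size.
    """
    params = params or ModuleParams()
    arr = tom.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("TOM must be symmetric")
    diss = 1.0 - arr
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=params.tree_cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index, name="module")
    sizes = labels.value_counts()
    keep = sizes[sizes >= params.min_module_size].sort_values(ascending=False)
    if keep.empty:
        logger.warning("no cluster reached min_module_size; all transcripts unassigned")
    mapping = {old: new for new, old in enumerate(keep.index, start=1)}
    return labels.map(lambda m: mapping.get(m, 0)).astype(int)


def eigengene(expression: pd.DataFrame, module_transcripts: pd.Index) -> pd.Series:
    """First principal component of a module's expression submatrix.

    Transcripts are standardized across samples; constant transcripts are
    dropped from the SVD. The sign is oriented so the eigengene correlates
    positively with the module's mean expression profile; the vector has
    unit norm.
    """
    sub = expression.loc[module_transcripts]
    if len(sub) < 2:
        raise ValueError("eigengene needs at least 2 transcripts")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        logger.debug("dropping %d constant transcripts from eigengene SVD", const.sum())
        X = X[~const]
        sd = sd[~const]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eg = vt[0]
    mean_profile = sub.to_numpy().mean(axis=0)
    centered = mean_profile - mean_profile.mean()
    if np.dot(eg, centered) < 0:
        eg = -eg
    return pd.Series(eg, index=expression.columns)


def eigengenes_for_labels(expression: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Eigengene matrix (module x sample) for all labels > 0."""
    modules = sorted(int(m) for m in labels.unique() if m > 0)
    rows = {m: eigengene(expression, labels.index[labels == m]) for m in modules}
    return pd.DataFrame(rows).T.rename_axis("module")


def merge_modules(
    expression: pd.DataFrame,
    labels: pd.Series,
    merge_corr_threshold: float = 0.75,
) -> pd.Series:
    """Merge modules whose eigengenes are Pearson-correlated above threshold.

    Iteratively merges the highest-correlated pair (strictly above the
    threshold; ties broken by the smaller label pair), recomputing
    eigengenes after each merge. After convergence, modules are renumbered
    by decreasing size.
    """
    labels = labels.copy()
    while True:
        modules = sorted(int(m) for m in labels.unique() if m > 0)
        if len(modules) < 2:
            break
        egs = eigengenes_for_labels(expression, labels)
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(modules):
            for b in modules[i + 1 :]:
                r = float(np.corrcoef(egs.loc[a], egs.loc[b])[0, 1])
                if r > merge_corr_threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
    sizes = labels[labels > 0].value_counts().sort_values(ascending=False)
    mapping = {old: new for new, old in enumerate(sizes.index, start=1)}
    return labels.map(lambda m: mapping.get(m, 0)).astype(int)


def detect_and_merge(
    expression: pd.DataFrame, params: ModuleParams | None = None
) -> ModuleSet:
    """Full module pipeline: TOM, clustering, merging, eigengenes."""
    params = params or ModuleParams()
    tom = adjacency_tom(expression, params)
    labels = detect_modules(tom, params)
    if (labels > 0).any():
        labels = merge_modules(expression, labels, params.merge_corr_threshold)
        egs = eigengenes_for_labels(expression, labels)
    else:
        egs = pd.DataFrame(columns=expression.columns).rename_axis("module")
    sizes = labels[labels > 0].value_counts().sort_index()
    return ModuleSet(labels=labels, eigengenes=egs, sizes=sizes)


def module_composition(
    labels: pd.Series,
    transcript_species: pd.Series,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-(species, module) transcript counts and within-species proportions.

    Transcripts without a species assignment are tallied under 'other'.
    When a taxonomy with a phylum column is given, phylum rows are appended.
    """
    sp = transcript_species.reindex(labels.index).fillna("other")
    df = pd.DataFrame({"module": labels, "species": sp})
    comp = df.groupby(["species", "module"]).size().rename("n_transcripts").reset_index()
    totals = comp.groupby("species")["n_transcripts"].transform("sum")
    comp["proportion"] = comp["n_transcripts"] / totals
    comp.insert(0, "level", "species")
    comp = comp.rename(columns={"species": "taxon"})
    if taxonomy is not None and "phylum" in taxonomy.columns:
        phyl = df.copy()
        phyl["taxon"] = taxonomy["phylum"].reindex(sp.to_numpy()).to_numpy()
        pcomp = (
            phyl.dropna(subset=["taxon"])
            .groupby(["taxon", "module"]).size().rename("n_transcripts").reset_index()
        )
        ptot = pcomp.groupby("taxon")["n_transcripts"].transform("sum")
        pcomp["proportion"] = pcomp["n_transcripts"] / ptot
        pcomp.insert(0, "level", "phylum")
        comp = pd.concat([comp, pcomp], ignore_index=True)
    return comp


def run_coexpression(
    counts: CountMatrix | pd.DataFrame, params: ModuleParams | None = None
) -> tuple[ExpressionMatrix, ModuleSet]:
    """Coverage filter, VST and module detection in one call."""
    params = params or ModuleParams()
    raw = counts.counts if isinstance(counts, CountMatrix) else counts
    filtered = filter_low_coverage(raw, params.min_mean_count)
    expr = vst(filtered)
    modules = detect_and_merge(expr.values, params)
    return expr, modules
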