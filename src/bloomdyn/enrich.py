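"""Species-by-module GO enrichment with redundancy-aware term clustering.

Within each co-expression module, each sufficiently represented species is
tested for over-representation of each sufficiently large GO biological
process by a two-sided Fisher exact test on the 2x2 table (in module /
outside module) x (carries GO / does not), with Benjamini-Hochberg control
per species. Because the GO hierarchy makes terms redundant, terms are
clustered on the overlap distance 1 - |GO_i n GO_j| / min(|GO_i|, |GO_j|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentFilters:
    """Gates of the enrichment analysis.

    A (species, module) cell is analyzed only when the species has strictly
    more than ``min_species_transcripts_in_module`` transcripts in that
    module; a GO term is tested only when it covers strictly more than
    ``min_go_size`` of the species' analyzed transcripts. A row is
    significant when odds ratio > ``odds_ratio_min`` and q < ``q_max``.
    """

    min_species_transcripts_in_module: int = 450
    min_go_size: int = 20
    odds_ratio_min: float = 3.0
    q_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_species_transcripts_in_module", "min_go_size",
                     "odds_ratio_min", "q_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class GOAnnotation:
    """Bidirectional transcript <-> GO term maps."""

    def __init__(self, table: pd.DataFrame):
        if not {"transcript", "go"}.issubset(table.columns):
            raise ValueError("annotation table needs 'transcript' and 'go' columns")
        self.table = table.drop_duplicates(["transcript", "go"])
        self.transcript_to_go: dict[str, set[str]] = {
            t: set(g) for t, g in self.table.groupby("transcript")["go"]
        }
        self.go_to_transcripts: dict[str, set[str]] = {
            g: set(t) for g, t in self.table.groupby("go")["transcript"]
        }

    def terms(self) -> list[str]:
        return sorted(self.go_to_transcripts)


_TIE_REL_TOL = 1e-7  # tables within this relative probability count as ties


def two_sided_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for one 2x2 table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (near-ties within a 1e-7 relative tolerance count as ties, the
    standard convention). Equivalent to scipy's two-sided test but
    exposed so the whole support of a margin set can be scored at once.
    """
    p = two_sided_fisher_p_for_margins(a + b, a + c, a + b + c + d)
    return float(p[a - max(0, (a + b) + (a + c) - (a + b + c + d))])


def two_sided_fisher_p_for_margins(r: int, k: int, n: int) -> np.ndarray:
    """Two-sided Fisher p for every table with row-1 total r, col-1 total k, grand total n.

    Returns the p-value for each admissible top-left cell a in
    [max(0, r+k-n), min(r, k)], in order.
    """
    support = np.arange(max(0, r + k - n), min(r, k) + 1)
    pmf = stats.hypergeom.pmf(support, n, r, k)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # p(a) = total probability of tables no more likely than table a
    idx = np.searchsorted(pmf[order], pmf * (1.0 + _TIE_REL_TOL), side="right")
    return np.minimum(1.0, csum[np.maximum(idx - 1, 0)])


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Unconditional sample odds ratio ad/bc; inf when bc = 0 and ad > 0."""
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_enrichment(
    labels: pd.Series,
    transcript_species: pd.Series,
    annotation: GOAnnotation,
    filters: EnrichmentFilters | None = None,
) -> pd.DataFrame:
    """Species-specific GO enrichment per module.

    The test universe for one species is that species' analyzed transcripts
    (all transcripts carrying a module label, including label 0). For each
    (species, module) passing the size gate and each GO passing the
    term-size gate within the species, the 2x2 table is
    a = species transcripts in the module annotated with the GO,
    b = in module without it, c = outside the module with it, d = outside
    without it. Two-sided Fisher exact p-values are BH-adjusted within each
    species across all its (module, GO) tests.
    """
    filters = filters or EnrichmentFilters()
    if labels.empty:
        raise ValueError("empty transcript universe")

    rows = []
    for sp, sp_transcripts in labels.groupby(transcript_species.reindex(labels.index)):
        universe = set(sp_transcripts.index)
        n_universe = len(universe)
        go_sizes = {
            g: len(annotation.go_to_transcripts.get(g, set()) & universe)
            for g in annotation.terms()
        }
        testable_terms = [g for g, sz in go_sizes.items() if sz > filters.min_go_size]
        for module in sorted(int(m) for m in sp_transcripts.unique() if m > 0):
            in_module = set(sp_transcripts.index[sp_transcripts == module])
            if len(in_module) <= filters.min_species_transcripts_in_module:
                continue
            for g in testable_terms:
                carriers = annotation.go_to_transcripts[g] & universe
                a = len(carriers & in_module)
                b = len(in_module) - a
                c = len(carriers) - a
                d = n_universe - len(in_module) - c
                if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
                    p, orat = 1.0, float("nan")
                else:
                    p = two_sided_fisher_p(a, b, c, d)
                    orat = _sample_odds_ratio(a, b, c, d)
                rows.append((sp, module, g, a, b, c, d, orat, float(p)))

    out = pd.DataFrame(
        rows,
        columns=["species", "module", "go", "a", "b", "c", "d", "odds_ratio", "p"],
    )
    out["q"] = np.nan
    for sp in out["species"].unique():
        mask = out["species"] == sp
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = (
        (out["odds_ratio"] > filters.odds_ratio_min) & (out["q"] < filters.q_max)
    ).fillna(False)
    return out


def go_distance(go_set_i: set[str], go_set_j: set[str]) -> float:
    """Overlap distance between two GO term memberships.

    1 - |GO_i n GO_j| / min(|GO_i|, |GO_j|): 0 when one set contains the
    other, 1 when disjoint; symmetric and bounded in [0, 1].
    """
    if not go_set_i or not go_set_j:
        raise ValueError("GO sets must be nonempty")
    overlap = len(go_set_i & go_set_j)
    return 1.0 - overlap / min(len(go_set_i), len(go_set_j))


def go_distance_matrix(annotation: GOAnnotation, terms: list[str] | None = None) -> pd.DataFrame:
    """Symmetric overlap-distance matrix over GO terms (zero diagonal)."""
    terms = sorted(terms) if terms is not None else annotation.terms()
    n = len(terms)
    mat = np.zeros((n, n))
    sets = [annotation.go_to_transcripts[t] for t in terms]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = go_distance(sets[i], sets[j])
    return pd.DataFrame(mat, index=terms, columns=terms)


def cluster_go_terms(
    distance: pd.DataFrame, height: float = 0.5, linkage: str = "average"
) -> tuple[list[str], pd.Series]:
    """Agglomeratively cluster GO terms on the overlap distance.

    Returns the dendrogram leaf order and flat cluster ids at the given
    height. The input must be symmetric with a zero diagonal; term order
    is made deterministic by sorting ids before linking.
    """
    arr = distance.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    order = sorted(distance.index)
    if len(order) == 1:
        return order, pd.Series([1], index=order, name="cluster")
    d = distance.loc[order, order].to_numpy()
    link = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    leaves = hierarchy.leaves_list(link)
    flat = hierarchy.fcluster(link, t=height, criterion="distance")
    return [order[i] for i in leaves], pd.Series(flat, index=order, name="cluster")


def enrichment_heat_table(
    enrichment: pd.DataFrame, leaf_order: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Exportable odds-ratio matrix GO x (species, module) with masks.

    Returns (odds_ratios, significance mask, analyzed mask); cells missing
    from the enrichment table (term failed the size gate for that species)
    are marked not-analyzed — the grey cells of a published heatmap.
    """
    if enrichment.empty:
        empty = pd.DataFrame()
        return empty, empty.astype(bool), empty.astype(bool)
    pivot = enrichment.pivot_table(
        index="go", columns=["species", "module"], values="odds_ratio", aggfunc="first"
    )
    sig = (
        enrichment.pivot_table(
            index="go", columns=["species", "module"], values="significant",
            aggfunc="first",
        )
        .infer_objects(copy=False)
        .fillna(False)
        .astype(bool)
    )
    analyzed = pivot.notna()
    if leaf_order is not None:
        present = [g for g in leaf_order if g in pivot.index]
        rest = [g for g in pivot.index if g not in set(present)]
        pivot = pivot.reindex(present + rest)
        sig = sig.reindex(pivot.index, fill_value=False)
        analyzed = analyzed.reindex(pivot.index, fill_value=False)
    return pivot, sig, analyzed
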