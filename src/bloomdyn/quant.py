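"""Alignment filtering and relative abundance of transcripts (RAT).

The RAT of species j in sample i is the length-normalized share of the
sample's aligned reads attributable to that species::

    RAT_ij = (n_ij / l_j) / sum_j (n_ij / l_j)

where n_ij is the number of reads from sample i mapping to transcripts of
species j and l_j the total reference length of species j in bases. Reads
are counted only after discarding low-quality alignments (mapping quality
below a floor) and reads hitting several transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metaref import ReferenceCatalogue

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ["sample", "read", "transcript", "mapq", "nhits"]


@dataclass
class CountMatrix:
    """Transcript x sample read counts with species ownership.

    ``counts`` rows are transcripts, columns samples; ``transcript_species``
    maps every transcript row to exactly one species.
    """

    counts: pd.DataFrame
    transcript_species: pd.Series
    unassigned: pd.Series | None = None  # per-sample reads hitting unknown transcripts

    def __post_init__(self) -> None:
        missing = self.counts.index.difference(self.transcript_species.index)
        if len(missing):
            raise ValueError(f"transcripts without species ownership: {list(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def species_counts(self) -> pd.DataFrame:
        """n_ij: species x sample read totals."""
        return self.counts.groupby(self.transcript_species.loc[self.counts.index]).sum()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class RATMatrix:
    """Species x sample relative abundance of transcripts."""

    rat: pd.DataFrame
    empty_samples: list[str] = field(default_factory=list)

    def max_per_species(self) -> pd.Series:
        return self.rat.max(axis=1)


def filter_alignments(
    alignments: pd.DataFrame,
    catalogue: ReferenceCatalogue,
    mapq_min: int = 10,
    drop_multimapped: bool = True,
    samples: list[str] | None = None,
) -> CountMatrix:
    """Turn an alignment table into a transcript x sample count matrix.

    ``alignments`` has one row per (sample, read, transcript) with integer
    ``mapq`` and ``nhits`` columns. Records with mapping quality strictly
    below ``mapq_min`` are removed; reads reported with more than one hit
    are removed entirely when ``drop_multimapped``. Alignments to
    transcripts absent from the catalogue are tallied per sample under
    ``unassigned`` and reported, not counted.
    """
    required = set(ALIGNMENT_COLUMNS)
    if not required.issubset(alignments.columns):
        raise ValueError(f"alignment table must have columns {sorted(required)}")
    tbl = alignments
    tbl = tbl[tbl["mapq"] >= mapq_min]
    if drop_multimapped:
        tbl = tbl[tbl["nhits"] <= 1]

    tmap = catalogue.transcript_species_map()
    known = tbl["transcript"].isin(tmap.index)
    unassigned = (
        tbl.loc[~known].groupby("sample").size() if (~known).any() else pd.Series(dtype=int)
    )
    if len(unassigned):
        logger.warning(
            "%d aligned reads hit transcripts absent from the catalogue", int(unassigned.sum())
        )
    tbl = tbl.loc[known]

    counts = (
        tbl.groupby(["transcript", "sample"]).size().unstack(fill_value=0)
    )
    all_samples = samples if samples is not None else sorted(alignments["sample"].unique())
    counts = counts.reindex(index=tmap.index, columns=all_samples, fill_value=0).astype(int)
    return CountMatrix(
        counts=counts,
        transcript_species=tmap,
        unassigned=unassigned if len(unassigned) else None,
    )


def compute_rat(
    counts: CountMatrix | pd.DataFrame,
    catalogue: ReferenceCatalogue,
) -> RATMatrix:
    """Compute RAT_ij = (n_ij/l_j) / sum_j (n_ij/l_j) per sample.

    Accepts either a CountMatrix (aggregated to species internally) or an
    already species-level n_ij DataFrame. Samples with no aligned reads
    yield all-zero columns and are flagged in ``empty_samples``.
    """
    n_ij = counts.species_counts() if isinstance(counts, CountMatrix) else counts
    lengths = catalogue.lengths().reindex(n_ij.index)
    if lengths.isna().any():
        raise KeyError(
            f"species missing from catalogue: {list(lengths.index[lengths.isna()])}"
        )
    zero_len = lengths[lengths <= 0]
    if len(zero_len):
        raise ValueError(f"zero-length reference for species: {list(zero_len.index)}")

    density = n_ij.div(lengths, axis=0)  # n_ij / l_j
    totals = density.sum(axis=0)
    empty = list(totals.index[totals == 0])
    if empty:
        logger.warning("samples with zero aligned reads: %s", empty)
    safe_totals = totals.replace(0, np.nan)
    rat = density.div(safe_totals, axis=1).fillna(0.0)
    return RATMatrix(rat=rat, empty_samples=empty)


def aggregate_rat_by_taxon(
    rat: RATMatrix, taxonomy: pd.DataFrame, level: str = "phylum"
) -> RATMatrix:
    """Aggregate species RAT to a higher taxon by summation.

    Because all species in a sample share the RAT denominator, summing
    member species' RAT equals recomputing the formula with taxon-pooled
    n/l terms.
    """
    if level not in taxonomy.columns:
        raise KeyError(f"taxonomy has no {level!r} column")
    labels = taxonomy[level].reindex(rat.rat.index)
    if labels.isna().any():
        raise KeyError(
            f"species missing {level} assignment: {list(labels.index[labels.isna()])}"
        )
    agg = rat.rat.groupby(labels).sum()
    return RATMatrix(rat=agg, empty_samples=list(rat.empty_samples))


def select_focal_species(rat: RATMatrix, threshold: float = 0.03) -> list[str]:
    """Species whose maximum RAT over samples strictly exceeds the threshold."""
    if rat.rat.empty:
        return []
    mx = rat.max_per_species()
    return sorted(mx.index[mx > threshold])


def rat_vs_external_correlation(
    rat_row: pd.Series | np.ndarray, external: pd.Series | np.ndarray
) -> float:
    """Spearman correlation of a species' RAT trajectory with an external series.

    Used e.g. to compare RAT with microscopy cell densities or metabarcoding
    relative abundances. Returns NaN when either series is constant.
    """
    x = np.asarray(rat_row, dtype=float)
    y = np.asarray(external, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must be equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance series; Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def aligned_read_proportion(
    counts: CountMatrix, total_reads_per_sample: pd.Series
) -> pd.Series:
    """Raw per-sample proportion of reads aligned, without length normalization."""
    aligned = counts.counts.sum(axis=0)
    return (aligned / total_reads_per_sample.reindex(aligned.index)).rename("aligned_prop")
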