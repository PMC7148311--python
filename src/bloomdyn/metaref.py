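"""Meta-reference construction with congeneric collapse.

A meta-reference is the concatenation of many species' reference
transcriptomes used for competitive read alignment. Two passes are used:
a first meta-reference containing every available species, and a second
one in which same-genus species whose RAT trajectories are rank-correlated
above a threshold are collapsed to the single most abundant representative
(to suppress cross-mapping artefacts between close congeners), followed by
a minimum-total-length filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Catalogue containers
# --------------------------------------------------------------------------

@dataclass
class Transcript:
    """One reference transcript: id, optional sequence, length in bases."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"transcript {self.id}: sequence length {len(self.sequence)}"
                f" != declared length {self.length}"
            )


@dataclass
class SpeciesReference:
    """Reference transcriptome of one species."""

    species: str
    genus: str
    phylum: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        """l_j: total reference length in bases, the RAT length normalizer."""
        return sum(t.length for t in self.transcripts)

    def transcript_ids(self) -> list[str]:
        return [t.id for t in self.transcripts]


@dataclass
class ReferenceCatalogue:
    """Collection of species references forming (part of) a meta-reference."""

    references: list[SpeciesReference] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids: set[str] = set()
        for ref in self.references:
            if not ref.genus:
                raise ValueError(f"species {ref.species} has an empty genus")
            for t in ref.transcripts:
                if t.id in ids:
                    raise ValueError(f"duplicate transcript id {t.id!r} in catalogue")
                ids.add(t.id)

    @property
    def species_ids(self) -> list[str]:
        return [r.species for r in self.references]

    def get(self, species: str) -> SpeciesReference:
        for r in self.references:
            if r.species == species:
                return r
        raise KeyError(f"species {species!r} not in catalogue")

    def lengths(self) -> pd.Series:
        """Per-species total reference length l_j (bases)."""
        return pd.Series(
            {r.species: r.total_length for r in self.references}, name="l_j"
        )

    def transcript_species_map(self) -> pd.Series:
        """transcript id -> owning species id."""
        out: dict[str, str] = {}
        for r in self.references:
            for t in r.transcripts:
                out[t.id] = r.species
        return pd.Series(out, name="species", dtype=object)

    def taxonomy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.references],
                "genus": [r.genus for r in self.references],
                "phylum": [r.phylum for r in self.references],
            }
        ).set_index("species")

    def __len__(self) -> int:
        return len(self.references)


# --------------------------------------------------------------------------
# Collapse parameters and report
# --------------------------------------------------------------------------

@dataclass
class CollapseParams:
    """Thresholds of the congeneric collapse.

    rho_threshold: genus members whose pairwise Spearman correlation of RAT
        trajectories is strictly above this are considered redundant.
    min_total_length: species whose reference is shorter (strictly) than
        this many bases are discarded after the collapse.
    """

    rho_threshold: float = 0.75
    min_total_length: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_threshold < 1.0:
            raise ValueError("rho_threshold must be in (0, 1)")
        if self.min_total_length <= 0:
            raise ValueError("min_total_length must be positive")


@dataclass
class CollapseReport:
    """Bookkeeping of the congeneric collapse decisions."""

    genus_decisions: pd.DataFrame  # genus, decision in {single,collapsed,mixed}
    species_log: pd.DataFrame  # species, genus, kept, reason
    n_singleton_kept: int = 0
    n_collapsed_representatives: int = 0
    n_mixed_retained: int = 0
    n_length_filtered: int = 0

    @property
    def n_kept(self) -> int:
        return int(self.species_log["kept"].sum())

    def category_identity_holds(self) -> bool:
        """kept == singletons + collapsed reps + mixed retained − length-filtered."""
        return self.n_kept == (
            self.n_singleton_kept
            + self.n_collapsed_representatives
            + self.n_mixed_retained
            - self.n_length_filtered
        )


# --------------------------------------------------------------------------
# Reference preparation
# --------------------------------------------------------------------------

_DEFAULT_ISOFORM_RE = re.compile(r"^(?P<gene>.+)\.[^.]+$")


def select_longest_isoforms(
    reference: SpeciesReference,
    isoform_regex: str | re.Pattern[str] | None = None,
) -> SpeciesReference:
    """Keep only the longest isoform per gene.

    The gene grouping key is extracted from the transcript id via a regex
    with a ``gene`` group (default: everything before the last dot). Ids
    that do not match the pattern fall back to identity grouping (each id
    its own gene), with a warning. Ties in length are broken by keeping the
    lexicographically smallest id.
    """
    pattern = (
        re.compile(isoform_regex)
        if isinstance(isoform_regex, str)
        else (isoform_regex or _DEFAULT_ISOFORM_RE)
    )
    groups: dict[str, Transcript] = {}
    unparsed = 0
    for t in sorted(reference.transcripts, key=lambda t: t.id):
        m = pattern.match(t.id)
        if m is None or "gene" not in m.groupdict() or m.group("gene") is None:
            key = t.id
            unparsed += 1
        else:
            key = m.group("gene")
        incumbent = groups.get(key)
        # strict > keeps the earlier (lexicographically smaller) id on ties
        if incumbent is None or t.length > incumbent.length:
            groups[key] = t
    if unparsed:
        logger.warning(
            "%s: %d transcript ids lacked a parsable isoform key; "
            "identity grouping used for those",
            reference.species,
            unparsed,
        )
    kept = sorted(groups.values(), key=lambda t: t.id)
    return SpeciesReference(
        species=reference.species,
        genus=reference.genus,
        phylum=reference.phylum,
        transcripts=kept,
    )


def _kmers(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def merge_strain_references(
    references: list[SpeciesReference],
    identity_threshold: float = 0.95,
    k: int = 21,
) -> SpeciesReference:
    """Merge several strain references of one species, removing redundancy.

    Concatenates the inputs, then applies a deterministic greedy pass: work
    through sequences by decreasing length (ties by id); a sequence is
    dropped when at least ``identity_threshold`` of its k-mers already occur
    in a kept sequence. Requires sequences to be present.
    """
    if not references:
        raise ValueError("merge_strain_references requires at least one reference")
    species = references[0].species
    all_transcripts = [t for r in references for t in r.transcripts]
    for t in all_transcripts:
        if t.sequence is None:
            raise ValueError(
                f"transcript {t.id} has no sequence; redundancy removal needs sequences"
            )
    order = sorted(all_transcripts, key=lambda t: (-t.length, t.id))
    kept: list[Transcript] = []
    seen_ids: set[str] = set()
    kept_kmers: set[str] = set()
    for t in order:
        if t.id in seen_ids:
            continue  # exact duplicate record across strain files
        km = _kmers(t.sequence, k)  # type: ignore[arg-type]
        shared = len(km & kept_kmers)
        if kept and shared / len(km) >= identity_threshold:
            continue
        kept.append(t)
        seen_ids.add(t.id)
        kept_kmers |= km
    kept.sort(key=lambda t: t.id)
    return SpeciesReference(
        species=species,
        genus=references[0].genus,
        phylum=references[0].phylum,
        transcripts=kept,
    )


def build_metaref(
    catalogue: ReferenceCatalogue,
    species_subset: list[str] | None = None,
    prefix_ids: bool = True,
) -> ReferenceCatalogue:
    """Restrict a catalogue to a species subset and guarantee unique ids.

    Transcript ids are prefixed with ``<species>|`` so that two species
    carrying the same local transcript id cannot collide once concatenated
    into one meta-reference.
    """
    subset = catalogue.species_ids if species_subset is None else list(species_subset)
    if not subset:
        raise ValueError("species subset must be nonempty")
    known = set(catalogue.species_ids)
    unknown = [s for s in subset if s not in known]
    if unknown:
        raise KeyError(f"unknown species in subset: {unknown}")
    refs = []
    for sp in subset:
        ref = catalogue.get(sp)
        transcripts = [
            Transcript(
                id=f"{sp}|{t.id}" if prefix_ids and not t.id.startswith(f"{sp}|") else t.id,
                length=t.length,
                sequence=t.sequence,
            )
            for t in ref.transcripts
        ]
        refs.append(
            SpeciesReference(
                species=sp, genus=ref.genus, phylum=ref.phylum, transcripts=transcripts
            )
        )
    return ReferenceCatalogue(references=refs)


# --------------------------------------------------------------------------
# Congeneric collapse
# --------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; NaN when either series is constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def _connected_components(nodes: list[str], edges: set[tuple[str, str]]) -> list[list[str]]:
    parent = {n: n for n in nodes}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    return [sorted(c) for c in comps.values()]


def genus_collapse(
    rat: pd.DataFrame,
    taxonomy: pd.DataFrame,
    params: CollapseParams | None = None,
    lengths: pd.Series | None = None,
) -> tuple[list[str], CollapseReport]:
    """Select the species set of the second-pass meta-reference.

    ``rat`` is species x sample. Per genus:

    a. a single species is kept unconditionally;
    b. when every pairwise Spearman correlation of RAT trajectories is
       strictly above the threshold, only the species with the highest
       maximum RAT is kept;
    c. otherwise, species are grouped into connected components of the
       graph whose edges join pairs with correlation above the threshold;
       each multi-species component contributes its highest-max-RAT
       representative, and every singleton component (a species correlated
       above threshold with no other) is kept.

    A zero-variance RAT trajectory has undefined correlation and is treated
    as uncorrelated with everything (the species is kept). After selection,
    species whose total reference length falls strictly below
    ``params.min_total_length`` are discarded (skipped if ``lengths`` is
    None). Returns the kept species (sorted) and a CollapseReport.
    """
    params = params or CollapseParams()
    if rat.shape[1] < 3:
        raise ValueError("genus collapse requires at least 3 samples")
    missing = [s for s in rat.index if s not in taxonomy.index]
    if missing:
        raise KeyError(f"species missing from taxonomy: {missing}")

    genus_rows: list[dict] = []
    species_rows: list[dict] = []
    selected: list[str] = []
    n_singleton = n_collapsed = n_mixed = 0

    for genus, members_df in taxonomy.loc[sorted(rat.index)].groupby("genus", sort=True):
        members = sorted(members_df.index)
        if len(members) == 1:
            sp = members[0]
            selected.append(sp)
            n_singleton += 1
            genus_rows.append({"genus": genus, "decision": "single"})
            species_rows.append(
                {"species": sp, "genus": genus, "kept": True, "reason": "singleton genus"}
            )
            continue

        max_rat = rat.loc[members].max(axis=1)
        edges: set[tuple[str, str]] = set()
        all_above = True
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                rho = _spearman(rat.loc[a].to_numpy(), rat.loc[b].to_numpy())
                if np.isnan(rho):
                    logger.info(
                        "genus %s: correlation %s vs %s undefined (constant RAT); "
                        "treated as uncorrelated",
                        genus, a, b,
                    )
                    all_above = False
                    continue
                if rho > params.rho_threshold:
                    edges.add((a, b))
                else:
                    all_above = False

        if all_above:
            # rule (b): fully correlated genus, keep single best representative
            rep = max_rat.sort_index().idxmax()  # ties -> first in sorted order
            selected.append(rep)
            n_collapsed += 1
            genus_rows.append({"genus": genus, "decision": "fully-correlated-collapsed"})
            for sp in members:
                species_rows.append(
                    {
                        "species": sp,
                        "genus": genus,
                        "kept": sp == rep,
                        "reason": "collapsed representative"
                        if sp == rep
                        else f"collapsed into {rep}",
                    }
                )
            continue

        # rule (c): mixed genus
        genus_rows.append({"genus": genus, "decision": "mixed"})
        for comp in _connected_components(members, edges):
            if len(comp) == 1:
                sp = comp[0]
                selected.append(sp)
                n_mixed += 1
                species_rows.append(
                    {
                        "species": sp,
                        "genus": genus,
                        "kept": True,
                        "reason": "uncorrelated within mixed genus",
                    }
                )
            else:
                rep = max_rat.loc[comp].sort_index().idxmax()
                selected.append(rep)
                n_mixed += 1
                for sp in comp:
                    species_rows.append(
                        {
                            "species": sp,
                            "genus": genus,
                            "kept": sp == rep,
                            "reason": "component representative"
                            if sp == rep
                            else f"collapsed into {rep}",
                        }
                    )

    # length filter, applied after the collapse
    n_length_filtered = 0
    if lengths is not None:
        surviving = []
        for sp in selected:
            if sp in lengths.index and lengths[sp] < params.min_total_length:
                n_length_filtered += 1
                for row in species_rows:
                    if row["species"] == sp:
                        row["kept"] = False
                        row["reason"] += "; dropped: reference shorter than length floor"
            else:
                surviving.append(sp)
        selected = surviving

    report = CollapseReport(
        genus_decisions=pd.DataFrame(genus_rows),
        species_log=pd.DataFrame(species_rows),
        n_singleton_kept=n_singleton,
        n_collapsed_representatives=n_collapsed,
        n_mixed_retained=n_mixed,
        n_length_filtered=n_length_filtered,
    )
    return sorted(selected), report


def length_filter(
    catalogue: ReferenceCatalogue, min_total_length: int = 2_000_000
) -> tuple[ReferenceCatalogue, list[str]]:
    """Drop species whose total reference length is strictly below the floor.

    Returns the filtered catalogue and the list of removed species ids.
    """
    kept, dropped = [], []
    for ref in catalogue.references:
        if ref.total_length < min_total_length:
            dropped.append(ref.species)
        else:
            kept.append(ref)
    if dropped:
        logger.info("length filter removed %d species: %s", len(dropped), dropped)
    return ReferenceCatalogue(references=kept), dropped
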