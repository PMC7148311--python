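"""Synthetic multi-species bloom communities with known ground truth.

The generator emulates the statistical structure of a coastal bloom
meta-transcriptome time series: species whose (log-)abundances respond
linearly to autocorrelated environmental drivers and succeed each other
over time, congeneric species pairs with a tunable rank correlation of
their abundance trajectories, negative-binomial transcript counts carrying
planted co-expression modules with smooth time profiles, and Gene Ontology
labels carrying planted per-module enrichments.

Every downstream stage (RAT quantification, congeneric collapse, module
detection, redundancy analysis, GO enrichment) can therefore be tested
against the generating truth without any external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metaref import ReferenceCatalogue, SpeciesReference, Transcript
from .quant import CountMatrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community.

    Defaults describe the study conditions the pipeline targets: a season
    of 40 samplings of a 12-species community driven by nine abiotic
    variables, with two congeneric pairs (one tightly co-varying, one
    nearly independent), three planted co-expression modules and planted
    per-module GO enrichment.
    """

    n_samples: int = 40
    n_species: int = 12
    congeneric_pairs: list[tuple[str, float]] = field(
        default_factory=lambda: [("Chaetoceros", 0.95), ("Thalassiosira", 0.3)]
    )
    transcripts_per_species: int = 80
    length_log_mean: float = 7.0  # log bases; median transcript ~1.1 kb
    length_log_sd: float = 0.6
    n_env_vars: int = 9
    driver_weights: list[list[float]] | None = None  # species x env; drawn if None
    driver_weight_sd: float = 0.2
    ar1_coeff: float = 0.6
    species_noise_sd: float = 0.5  # AR(1) innovation scale on log-abundance
    baseline_sd: float = 0.7  # spread of species' mean log-abundance
    total_reads_per_sample: int = 500_000
    nb_dispersion: float = 0.3
    n_modules: int = 3
    module_amplitude: float = 3.0
    module_fraction: float = 0.85  # share of transcripts carrying a module profile
    go_terms: int = 50
    go_base_rate: float = 0.05
    go_enrichment_factor: float = 5.0
    go_linked_per_module: int = 3
    generate_sequences: bool = True  # skip for speed when only lengths matter
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("invalid config: n_samples must be >= 2")
        for name in (
            "n_species",
            "transcripts_per_species",
            "n_env_vars",
            "total_reads_per_sample",
            "go_terms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid config: {name} must be positive")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("invalid config: ar1_coeff must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("invalid config: nb_dispersion must be > 0")
        if self.module_amplitude < 0 or self.n_modules < 0:
            raise ValueError("invalid config: module settings must be non-negative")
        if self.go_enrichment_factor < 1:
            raise ValueError("invalid config: go_enrichment_factor must be >= 1")
        if not 0.0 <= self.module_fraction <= 1.0:
            raise ValueError("invalid config: module_fraction must be in [0, 1]")
        for genus, rho in self.congeneric_pairs:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"invalid config: pair {genus} rho {rho} outside [-1, 1]")
        if 2 * len(self.congeneric_pairs) > self.n_species:
            raise ValueError(
                "invalid config: congeneric pairs need 2 species each; "
                f"{len(self.congeneric_pairs)} pairs exceed {self.n_species} species"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["congeneric_pairs"] = [[g, float(r)] for g, r in self.congeneric_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["congeneric_pairs"] = [(g, float(r)) for g, r in d.get("congeneric_pairs", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """The generating truth of one synthetic community."""

    species_proportions: pd.DataFrame  # species x sample, columns sum to 1
    transcript_module_labels: pd.Series  # transcript -> module (0 = background)
    module_go_map: dict[int, list[str]]  # module -> planted enriched GO ids
    env: pd.DataFrame  # env var x sample
    driver_weights: pd.DataFrame  # species x env var, effective weights
    module_profiles: pd.DataFrame  # module x sample time profile (mean 0)

    def species_go_enrichment_map(
        self, transcript_species: pd.Series
    ) -> dict[tuple[str, int], list[str]]:
        """Planted (species, module) -> enriched GO ids, for species present in the module."""
        out: dict[tuple[str, int], list[str]] = {}
        labels = self.transcript_module_labels
        for m, gos in self.module_go_map.items():
            in_module = labels.index[labels == m]
            for sp in sorted(transcript_species.loc[in_module].unique()):
                out[(sp, m)] = list(gos)
        return out


@dataclass
class SyntheticBundle:
    """Everything one simulation run produces."""

    config: SimulationConfig
    catalogue: ReferenceCatalogue
    counts: CountMatrix
    env: pd.DataFrame
    go: pd.DataFrame  # long form: transcript, go columns
    taxonomy: pd.DataFrame  # indexed by species: genus, phylum
    truth: GroundTruth


# --------------------------------------------------------------------------
# Environment
# --------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, phi: float, innovation_sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series of length n."""
    x = np.empty(n)
    stat_sd = innovation_sd / np.sqrt(1.0 - phi**2) if phi > 0 else innovation_sd
    x[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, innovation_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_environment(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Environment table: one standardized AR(1) Gaussian series per variable.

    Rows are environmental variables, columns samples. Each series is
    z-scored to mean 0 and sd 1, so the lag-1 autocorrelation equals the
    AR(1) coefficient in expectation. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _environment_from_rng(config, rng)


def _environment_from_rng(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _ in range(config.n_env_vars):
        x = _ar1(rng, config.n_samples, config.ar1_coeff)
        x = (x - x.mean()) / x.std(ddof=0)
        rows.append(x)
    env = pd.DataFrame(
        rows,
        index=[f"env_{k + 1:02d}" for k in range(config.n_env_vars)],
        columns=[f"S{t + 1:02d}" for t in range(config.n_samples)],
    )
    return env


# --------------------------------------------------------------------------
# Community
# --------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _solve_pair_mixing(
    rho: float,
    shared_std: np.ndarray,
    indep_a: np.ndarray,
    indep_b: np.ndarray,
    other_exp: np.ndarray,
    baseline_a: float,
    baseline_b: float,
    scale: float,
) -> float:
    """Signed mixing weight hitting a target Spearman rho between pair members.

    The target applies to the realized per-sample proportions, not the
    latent log-abundances: the shared softmax denominator (compositional
    closure) pulls pairwise correlations down, so the weight is solved
    numerically against the closed trajectories. For jointly Gaussian
    series, Spearman rho_s corresponds to Pearson r = 2 sin(pi rho_s / 6);
    the root of realized-Pearson(v) = r is found by bisection over the
    signed mixing parameter v in [-1, 1], clipping to the attainable range.
    """
    target_r = 2.0 * np.sin(np.pi * rho / 6.0)

    def realized_r(v: float) -> float:
        w, s = np.sqrt(abs(v)), np.sqrt(1.0 - abs(v))
        sign = 1.0 if v >= 0 else -1.0
        eta_a = baseline_a + scale * (w * shared_std + s * indep_a)
        eta_b = baseline_b + scale * (sign * w * shared_std + s * indep_b)
        z = np.log(other_exp + np.exp(eta_a) + np.exp(eta_b))
        da, db = eta_a - z, eta_b - z
        return float(np.corrcoef(da, db)[0, 1])

    lo, hi = -1.0, 1.0
    r_lo, r_hi = realized_r(lo), realized_r(hi)
    if target_r <= r_lo:
        return lo
    if target_r >= r_hi:
        return hi
    from scipy.optimize import brentq

    return float(brentq(lambda v: realized_r(v) - target_r, lo, hi, xtol=1e-6))


def simulate_community(
    config: SimulationConfig, count_seed: int | None = None
) -> SyntheticBundle:
    """Generate one synthetic community.

    Species log-abundance = baseline + driver_weights . env + AR(1) noise,
    mapped to per-sample proportions through a softmax (which guarantees
    the simplex constraint). Congeneric pair members mix a shared latent
    trajectory with independent ones so that the realized rank correlation
    of their proportions lands near the configured target. Per-transcript
    expected counts are total_reads x species proportion x within-species
    transcript weight x a module multiplier exp(amplitude x time profile);
    counts are negative-binomial. GO terms are assigned so that each
    module's linked terms occur ``go_enrichment_factor`` times more often
    inside the module than in the background.

    ``count_seed``, when given, reseeds only the negative-binomial draw:
    two runs with the same config but different count seeds share the same
    generative truth (proportions, module labels, GO map) and differ only
    in count noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    env = _environment_from_rng(config, rng)
    samples = list(env.columns)
    n, S, E = config.n_samples, config.n_species, config.n_env_vars

    # -- species naming and taxonomy: pairs first, then singleton genera
    species, genera = [], []
    for gi, (genus, _rho) in enumerate(config.congeneric_pairs):
        for member in ("a", "b"):
            species.append(f"{genus}_{member}")
            genera.append(genus)
    k = 0
    while len(species) < S:
        k += 1
        species.append(f"Species_{k:02d}")
        genera.append(f"Genus_{k:02d}")
    phyla = ["Phylum_A" if i % 2 == 0 else "Phylum_B" for i in range(S)]
    taxonomy = pd.DataFrame({"genus": genera, "phylum": phyla}, index=pd.Index(species, name="species"))

    # -- driver weights
    if config.driver_weights is not None:
        W = np.asarray(config.driver_weights, dtype=float)
        if W.shape != (S, E):
            raise ValueError(f"invalid config: driver_weights must be {S}x{E}")
    else:
        W = rng.normal(0.0, config.driver_weight_sd, size=(S, E))

    env_arr = env.to_numpy()  # E x n
    baselines = rng.normal(0.0, config.baseline_sd, size=S)

    # latent deviations (driver response + AR(1) noise), one per species,
    # plus one shared latent per congeneric pair
    raw = np.empty((S, n))
    for j in range(S):
        raw[j] = W[j] @ env_arr + _ar1(rng, n, config.ar1_coeff, config.species_noise_sd)
    target_sd = float(np.std(raw, axis=1, ddof=0).mean())

    W_eff = W.copy()
    for gi, (_genus, rho) in enumerate(config.congeneric_pairs):
        a, b = 2 * gi, 2 * gi + 1
        W_shared = rng.normal(0.0, config.driver_weight_sd, size=E)
        shared_raw = W_shared @ env_arr + _ar1(rng, n, config.ar1_coeff, config.species_noise_sd)
        sd_shared = shared_raw.std(ddof=0) or 1.0
        sd_a = raw[a].std(ddof=0) or 1.0
        sd_b = raw[b].std(ddof=0) or 1.0
        shared_std = _standardize(shared_raw)
        indep_a, indep_b = _standardize(raw[a]), _standardize(raw[b])
        others = [j for j in range(S) if j not in (a, b)]
        other_exp = np.exp(baselines[others, None] + raw[others]).sum(axis=0)
        v = _solve_pair_mixing(
            rho, shared_std, indep_a, indep_b, other_exp,
            baselines[a], baselines[b], target_sd,
        )
        w, s = float(np.sqrt(abs(v))), float(np.sqrt(1.0 - abs(v)))
        sign = 1.0 if v >= 0 else -1.0
        raw[a] = target_sd * (w * shared_std + s * indep_a)
        raw[b] = target_sd * (sign * w * shared_std + s * indep_b)
        W_eff[a] = target_sd * (w * W_shared / sd_shared + s * W[a] / sd_a)
        W_eff[b] = target_sd * (sign * w * W_shared / sd_shared + s * W[b] / sd_b)

    log_abund = baselines[:, None] + raw
    # softmax per sample -> proportions on the simplex
    z = log_abund - log_abund.max(axis=0, keepdims=True)
    expz = np.exp(z)
    props = expz / expz.sum(axis=0, keepdims=True)
    proportions = pd.DataFrame(props, index=species, columns=samples)

    # -- reference transcripts
    T = config.transcripts_per_species
    refs: list[SpeciesReference] = []
    transcript_ids: list[str] = []
    lengths_all: list[int] = []
    for j, sp in enumerate(species):
        lens = np.maximum(
            100, rng.lognormal(config.length_log_mean, config.length_log_sd, size=T).astype(int)
        )
        transcripts = []
        for t_idx in range(T):
            tid = f"{sp}|tr{t_idx + 1:04d}"
            seq = (
                "".join(_BASES[rng.integers(0, 4, size=int(lens[t_idx]))])
                if config.generate_sequences
                else None
            )
            transcripts.append(Transcript(id=tid, length=int(lens[t_idx]), sequence=seq))
            transcript_ids.append(tid)
            lengths_all.append(int(lens[t_idx]))
        refs.append(
            SpeciesReference(
                species=sp,
                genus=taxonomy.loc[sp, "genus"],
                phylum=taxonomy.loc[sp, "phylum"],
                transcripts=transcripts,
            )
        )
    catalogue = ReferenceCatalogue(references=refs)
    n_transcripts = len(transcript_ids)
    transcript_index = pd.Index(transcript_ids, name="transcript")

    # within-species transcript weights (sum to 1 per species)
    weights = np.empty(n_transcripts)
    for j in range(S):
        weights[j * T : (j + 1) * T] = rng.dirichlet(np.full(T, 5.0))

    # -- planted modules with smooth sinusoidal time profiles
    labels = np.zeros(n_transcripts, dtype=int)
    if config.n_modules > 0 and config.module_fraction > 0:
        n_in_modules = int(round(config.module_fraction * n_transcripts))
        chosen = rng.choice(n_transcripts, size=n_in_modules, replace=False)
        labels[chosen] = rng.integers(1, config.n_modules + 1, size=n_in_modules)
    t_grid = np.arange(n)
    profiles = np.zeros((config.n_modules, n))
    for m in range(config.n_modules):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        freq = 1.0 + m  # distinct periods keep modules mutually separable
        profiles[m] = np.sin(2.0 * np.pi * freq * t_grid / n + phase)
        profiles[m] -= profiles[m].mean()
    module_profiles = pd.DataFrame(
        profiles, index=pd.RangeIndex(1, config.n_modules + 1, name="module"), columns=samples
    )

    # -- expected counts and NB draw
    sp_of_transcript = np.repeat(np.arange(S), T)
    mu = (
        config.total_reads_per_sample
        * props[sp_of_transcript, :]
        * weights[:, None]
    )
    module_mult = np.ones((n_transcripts, n))
    planted = labels > 0
    if planted.any() and config.module_amplitude > 0:
        module_mult[planted] = np.exp(
            config.module_amplitude * profiles[labels[planted] - 1]
        )
    mu = mu * module_mult
    nb_n = 1.0 / config.nb_dispersion
    nb_p = nb_n / (nb_n + np.maximum(mu, 1e-12))
    count_rng = rng if count_seed is None else np.random.default_rng(count_seed)
    counts_arr = count_rng.negative_binomial(nb_n, nb_p)
    counts = pd.DataFrame(counts_arr, index=transcript_index, columns=samples)
    transcript_species = pd.Series(
        np.array(species, dtype=object)[sp_of_transcript], index=transcript_index, name="species"
    )
    count_matrix = CountMatrix(counts=counts, transcript_species=transcript_species)

    # -- GO assignment with planted per-module enrichment
    go_ids = [f"GO:{7000000 + g:07d}" for g in range(config.go_terms)]
    module_go_map: dict[int, list[str]] = {}
    linked: set[int] = set()
    for m in range(1, config.n_modules + 1):
        start = (m - 1) * config.go_linked_per_module
        idxs = [i % config.go_terms for i in range(start, start + config.go_linked_per_module)]
        module_go_map[m] = [go_ids[i] for i in idxs]
        linked.update(idxs)
    prob = np.full((n_transcripts, config.go_terms), config.go_base_rate)
    for m, gos in module_go_map.items():
        rows = labels == m
        cols = [go_ids.index(g) for g in gos]
        prob[np.ix_(rows, cols)] = min(0.95, config.go_base_rate * config.go_enrichment_factor)
    member = rng.random((n_transcripts, config.go_terms)) < prob
    tr_idx, go_idx = np.nonzero(member)
    go_table = pd.DataFrame(
        {
            "transcript": np.array(transcript_ids, dtype=object)[tr_idx],
            "go": np.array(go_ids, dtype=object)[go_idx],
        }
    )

    truth = GroundTruth(
        species_proportions=proportions,
        transcript_module_labels=pd.Series(labels, index=transcript_index, name="module"),
        module_go_map=module_go_map,
        env=env,
        driver_weights=pd.DataFrame(W_eff, index=species, columns=env.index),
        module_profiles=module_profiles,
    )
    return SyntheticBundle(
        config=config,
        catalogue=catalogue,
        counts=count_matrix,
        env=env,
        go=go_table,
        taxonomy=taxonomy,
        truth=truth,
    )


def to_alignment_table(
    counts: CountMatrix, rng: np.random.Generator | int = 0, mapq: int = 60
) -> pd.DataFrame:
    """Expand a count matrix into one alignment row per read (mapq 60, unique hit).

    Intended for exercising the alignment-filtering path on small fixtures;
    row order is deterministic given the generator state.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    rows = []
    read_no = 0
    stacked = counts.counts.stack()
    for (transcript, sample), c in stacked[stacked > 0].items():
        for _ in range(int(c)):
            read_no += 1
            rows.append((sample, f"read_{read_no:08d}", transcript, mapq, 1))
    return pd.DataFrame(rows, columns=["sample", "read", "transcript", "mapq", "nhits"])


def collapse_census_fixture(
    n_singleton: int = 162,
    n_fully_correlated: int = 40,
    mixed_plan: list[tuple[int, int]] | None = None,
    n_short: int = 8,
    n_samples: int = 30,
    min_total_length: int = 2_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict[str, int]]:
    """Community with a known congeneric-collapse census.

    Builds RAT trajectories, taxonomy and reference lengths for a community
    whose collapse outcome is known by construction: ``n_singleton``
    one-species genera (kept), ``n_fully_correlated`` genera whose members
    are monotone transforms of one trajectory (collapse to one
    representative each), mixed genera per ``mixed_plan`` — a list of
    (n_correlated_pair_members, n_uncorrelated) per genus, each
    contributing 1 + n_uncorrelated kept species — and ``n_short`` kept
    species whose references fall below the length floor. The default plan
    (eight genera of 2+1 and three of 2+2) yields 25 mixed-genus survivors,
    hence 162 + 40 + 25 - 8 = 219 selected species overall.

    Returns (rat, taxonomy, lengths, expected category counts).
    """
    if mixed_plan is None:
        mixed_plan = [(2, 1)] * 8 + [(2, 2)] * 3
    rng = np.random.default_rng(seed)
    samples = [f"S{t + 1:02d}" for t in range(n_samples)]

    def fresh_trajectory() -> np.ndarray:
        return rng.random(n_samples)

    def uncorrelated_with(others: list[np.ndarray]) -> np.ndarray:
        # draw until Spearman with every reference trajectory is well below
        # the collapse threshold (margin for the simplex closure);
        # deterministic given the seed
        from scipy import stats as _st

        for _ in range(1000):
            cand = fresh_trajectory()
            if all(abs(_st.spearmanr(cand, o)[0]) <= 0.6 for o in others):
                return cand
        raise RuntimeError("could not draw an uncorrelated trajectory")

    rows, genera, lengths, kept_expected = [], [], [], []
    names: list[str] = []

    def add(species: str, genus: str, traj: np.ndarray, kept: bool) -> None:
        names.append(species)
        genera.append(genus)
        rows.append(traj)
        lengths.append(min_total_length + 1_000_000)
        if kept:
            kept_expected.append(species)

    for i in range(n_singleton):
        add(f"sing{i:03d}_sp", f"SingGenus{i:03d}", fresh_trajectory(), True)
    for i in range(n_fully_correlated):
        base = fresh_trajectory()
        g = f"CorrGenus{i:03d}"
        # pure scalings keep identical ranks even after the per-sample
        # simplex closure: Spearman exactly 1; the x2 copy has the higher
        # max RAT and becomes the representative
        add(f"corr{i:03d}_a", g, base, False)
        add(f"corr{i:03d}_b", g, base * 2.0, True)
    for i, (n_pair, n_uncorr) in enumerate(mixed_plan):
        g = f"MixGenus{i:03d}"
        base = fresh_trajectory()
        members = [base * (k + 1) for k in range(n_pair)]
        for k, traj in enumerate(members):
            add(f"mix{i:03d}_p{k}", g, traj, k == n_pair - 1)
        for k in range(n_uncorr):
            traj = uncorrelated_with(members)
            members.append(traj)
            add(f"mix{i:03d}_u{k}", g, traj, True)

    taxonomy = pd.DataFrame(
        {"genus": genera, "phylum": "Phylum_X"}, index=pd.Index(names, name="species")
    )
    rat = pd.DataFrame(rows, index=names, columns=samples)
    rat = rat.div(rat.sum(axis=0), axis=1)  # close to the simplex per sample
    lengths_s = pd.Series(lengths, index=names, name="l_j", dtype=int)

    # push n_short of the would-be-kept singleton species under the floor
    short = kept_expected[:n_short]
    lengths_s.loc[short] = min_total_length - 1

    expected = {
        "singleton": n_singleton,
        "fully_correlated_representatives": n_fully_correlated,
        "mixed_retained": sum(1 + u for _p, u in mixed_plan),
        "length_filtered": n_short,
    }
    expected["kept"] = (
        expected["singleton"]
        + expected["fully_correlated_representatives"]
        + expected["mixed_retained"]
        - expected["length_filtered"]
    )
    return rat, taxonomy, lengths_s, expected


# --------------------------------------------------------------------------
# Fixture I/O
# --------------------------------------------------------------------------

def write_fixture(bundle: SyntheticBundle, directory: str | Path) -> list[Path]:
    """Write a bundle as plain-text files; ``read_fixture`` round-trips it.

    Layout: references.fasta (headers ``<transcript> species=<sp>``),
    counts.tsv, env.tsv, taxonomy.tsv, go.tsv, config.yaml and a truth/
    subdirectory with proportions.tsv, module_labels.tsv,
    driver_weights.tsv, module_profiles.tsv and module_go.json.
    """
    if not bundle.catalogue.references:
        raise ValueError("cannot write an empty catalogue")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    written: list[Path] = []

    records = []
    for ref in bundle.catalogue.references:
        for t in ref.transcripts:
            records.append(
                SeqRecord(Seq(t.sequence or "N" * t.length), id=t.id,
                          description=f"species={ref.species}")
            )
    fasta = directory / "references.fasta"
    SeqIO.write(records, str(fasta), "fasta")
    written.append(fasta)

    def _tsv(df: pd.DataFrame, name: str, base: Path = directory, index: bool = True) -> None:
        p = base / name
        df.to_csv(p, sep="\t", index=index)
        written.append(p)

    _tsv(bundle.counts.counts, "counts.tsv")
    _tsv(bundle.env, "env.tsv")
    _tsv(bundle.taxonomy, "taxonomy.tsv")
    _tsv(bundle.go, "go.tsv", index=False)

    cfg = directory / "config.yaml"
    cfg.write_text(yaml.safe_dump(bundle.config.to_dict(), sort_keys=True))
    written.append(cfg)

    _tsv(bundle.truth.species_proportions, "proportions.tsv", truth_dir)
    _tsv(bundle.truth.transcript_module_labels.to_frame(), "module_labels.tsv", truth_dir)
    _tsv(bundle.truth.driver_weights, "driver_weights.tsv", truth_dir)
    _tsv(bundle.truth.module_profiles, "module_profiles.tsv", truth_dir)
    mg = truth_dir / "module_go.json"
    mg.write_text(json.dumps({str(k): v for k, v in bundle.truth.module_go_map.items()}, indent=1))
    written.append(mg)
    return written


def read_fixture(directory: str | Path) -> SyntheticBundle:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    config = SimulationConfig.from_dict(yaml.safe_load((directory / "config.yaml").read_text()))

    taxonomy = pd.read_csv(directory / "taxonomy.tsv", sep="\t", index_col=0)
    by_species: dict[str, list[Transcript]] = {sp: [] for sp in taxonomy.index}
    for rec in SeqIO.parse(str(directory / "references.fasta"), "fasta"):
        sp = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )["species"]
        by_species[sp].append(Transcript(id=rec.id, length=len(rec.seq), sequence=str(rec.seq)))
    catalogue = ReferenceCatalogue(
        references=[
            SpeciesReference(
                species=sp,
                genus=taxonomy.loc[sp, "genus"],
                phylum=taxonomy.loc[sp, "phylum"],
                transcripts=trs,
            )
            for sp, trs in by_species.items()
        ]
    )

    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    env = pd.read_csv(directory / "env.tsv", sep="\t", index_col=0)
    go_path = directory / "go.tsv"
    go = (
        pd.read_csv(go_path, sep="\t")
        if go_path.exists()
        else pd.DataFrame(columns=["transcript", "go"])
    )
    truth_dir = directory / "truth"
    truth = GroundTruth(
        species_proportions=pd.read_csv(truth_dir / "proportions.tsv", sep="\t", index_col=0),
        transcript_module_labels=pd.read_csv(
            truth_dir / "module_labels.tsv", sep="\t", index_col=0
        )["module"],
        module_go_map={
            int(k): v
            for k, v in json.loads((truth_dir / "module_go.json").read_text()).items()
        },
        env=env,
        driver_weights=pd.read_csv(truth_dir / "driver_weights.tsv", sep="\t", index_col=0),
        module_profiles=pd.read_csv(truth_dir / "module_profiles.tsv", sep="\t", index_col=0),
    )
    truth.module_profiles.index = truth.module_profiles.index.astype(int)
    return SyntheticBundle(
        config=config,
        catalogue=catalogue,
        counts=CountMatrix(counts=counts, transcript_species=catalogue.transcript_species_map()),
        env=env,
        go=go,
        taxonomy=taxonomy,
        truth=truth,
    )
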