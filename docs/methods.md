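# Methods

## Scope

`bloomdyn` reconstructs, as desk-scale tested code, the analysis chain of
a species-resolved bloom meta-transcriptome study: meta-reference
construction with congeneric collapse, relative-abundance-of-transcripts
(RAT) quantification, WGCNA-style co-expression module detection with
eigengenes, redundancy analysis (RDA) against environmental covariates,
and species-by-module GO enrichment with redundancy-aware term
clustering. Aligners (BWA-MEM) and annotation pipelines (blastx/UniProt)
are out of scope: alignments enter as tabular records (sample, read,
transcript, mapping quality, hit count) and GO annotations as a
transcript→term table.

## The synthetic community generator

No public generative model exists for these data, so the generator's
distributional choices are explicit stand-ins, chosen to reproduce the
statistical structure the downstream methods assume, with the recovery of
planted structure as the design contract.

**Abundances.** Each environmental variable is a standardized stationary
AR(1) series (default autocorrelation 0.6 — sampling twice weekly makes
consecutive conditions similar). Species log-abundance is
baseline + W·env + AR(1) noise; baselines spread with sd 0.7 so that
maximum RAT varies realistically across species, per-variable responses
have sd 0.2 on the standardized environment (combined driver effect
~0.6 sd, several-fold abundance swings over a season), and the noise
innovation sd is 0.5. A softmax maps log-abundance to per-sample
proportions, guaranteeing the simplex constraint; the closure this
induces is the same compositional effect real relative data carry.

**Congeneric pairs.** Each configured pair mixes a shared latent
trajectory with independent ones, τ = √|v|·S + √(1−|v|)·U. Because the
softmax denominator deflates pairwise correlations of the closed
proportions (by about −0.18 at ρ = 0 with 12 species), the signed mixing
weight v is solved numerically (Brent's method) so that the realized
Pearson correlation of the closed log-proportions equals 2·sin(πρ/6),
the Gaussian-copula value whose rank correlation is the target ρ.
Exact ρ = −1 is unattainable after closure; the solver clips at the
attainable boundary. Calibration error is within ±0.1 at 200 samples.

**Counts.** Transcript lengths are log-normal (median ~1.1 kb); within-
species weights are Dirichlet(5). Expected counts are
total_reads × species proportion × transcript weight × exp(A·profile),
where 85% of transcripts carry one of three module profiles — sinusoids
of distinct harmonic frequency and random phase, hence mutually
orthogonal on the log scale — with amplitude A = 3 (a ~20-fold peak-to-
trough swing, the scale of on/off transcriptional programs across bloom
stages; smaller amplitudes leave module signal below the species-trajectory
variance and no method could attribute transcripts to cross-species
modules). Counts are negative-binomial with a single shared dispersion
0.3. Module multipliers are not renormalized; the induced library-size
drift is absorbed by the median-of-ratios size factors, exactly as in
real data.

**GO labels.** Each of 50 terms marks transcripts at base rate 0.05; the
three terms linked to each module are 5× denser inside it.

**What the generator does not emulate:** sequence-level homology between
congeners (cross-mapping is emulated at the trajectory level, not the
read level), rRNA/metabarcoding data, batch structure across years,
raw-read error profiles, and GO hierarchy (terms are flat; overlap
between terms arises only by chance). Passing tests therefore demonstrate
algorithmic correctness and calibration on communities with this
structure, not performance on any particular field data set.

## Stage-by-stage choices

**Meta-reference.** Isoform selection keeps the longest transcript per
gene, the gene key parsed from the id by a configurable regex (default:
prefix before the last dot) because reference header dialects vary; ties
break to the lexicographically smaller id. Strain merging removes
redundancy with a deterministic greedy pass — sequences in decreasing
length order, dropped when ≥ 95% of their 21-mers already occur in kept
sequences. This is a documented, dependency-free redundancy remover, not
a reimplementation of CD-HIT-EST's cluster semantics; the identity
threshold and k are configurable.

**Congeneric collapse.** The mixed-genus rule is read as connected
components of the ρ > threshold graph: one highest-max-RAT representative
per multi-species component plus every uncorrelated species. This is the
only reading consistent with keeping both "the species with the maximum
RAT for the correlated group" and "all species displaying correlations
below threshold" simultaneously. ρ exactly equal to the threshold does
not collapse (strict inequality). Zero-variance RAT trajectories have
undefined rank correlation; such species are conservatively kept and
logged rather than silently dropped. The 2×10⁶-base length filter is
applied after the collapse. Collapse is idempotent and invariant to
species input order.

**Quantification.** Multi-mapping is defined operationally as hit count
> 1 in the alignment table (an optional adapter can emit this table from
BAM, but the core stays tabular and bit-testable). Samples with zero
aligned reads are retained as flagged all-zero RAT columns; downstream
stages decide what to do with them. The raw aligned-read proportion
(no length normalization) is provided as a companion statistic.

**Normalization.** Size factors are linear-median-of-ratios over
transcripts nonzero in every sample, with a total-count fallback (logged)
when none exists. The VST fits the dispersion trend α(μ) = a₀/μ + a₁ by
least squares on method-of-moments dispersions of overdispersed
transcripts, then applies the closed-form NB variance-stabilizing map; on
data with biological signal the fitted a₁ exceeds the count-level
dispersion, which is expected — the trend captures total variance, and
only the transformation's stabilizing shape matters downstream. Bit
equality with DESeq2's shrinkage machinery is a non-goal. Degenerate fits
fall back to log2(q+1), logged.

**Network and modules.** Correlation is the biweight midcorrelation
(median/MAD standardization, Tukey weights, c = 9; zero-MAD series fall
back to Pearson). The network is unsigned, |corr|^β with β = 6, the
WGCNA default. The adaptive dynamic-tree-cut algorithm is replaced by a
static height cut on the average-linkage dendrogram of 1−TOM plus the
minimum-size rule; the default height 0.95 sits below the level at which
distinct planted modules join in weak-network dendrograms (TOM
dissimilarities concentrate near 0.95–0.99) — it is a config knob, and
the fidelity gap versus adaptive cutting is the main known limitation of
the module stage. Everything is computed in a single block with a hard
cap (35,000 transcripts) that raises rather than approximates. Eigengene
sign is oriented positive against the module's mean profile. Merging
recomputes eigengenes after every step and stops when no pair exceeds the
Pearson threshold (strictly). Module label 0 is reserved for unassigned
transcripts and excluded from eigengenes and enrichment.

**RDA.** Explanatory variables are z-scored (mixed units make raw-scale
fitting meaningless) and gaps are linearly interpolated with a warning;
responses are centered. Fitted values use a pseudo-inverse on rank
deficiency (logged); axes come from the SVD of the fitted matrix;
eigenvalues are squared singular values over (n−1); the constrained
fraction is ‖Ŷ‖²_F/‖Y‖²_F. Output follows the "scaling 2" correlation-
biplot convention: explanatory scores are correlations of predictors with
sample axis scores. Permutation significance tests and variance
partitioning are non-goals.

**Enrichment.** The test universe per species is its analyzed (module-
labeled, coverage-surviving) transcripts — only those can appear in
modules. The two-sided Fisher p sums hypergeometric probabilities of
tables no more likely than observed (near-ties within 1e-7 relative
tolerance count as ties, the standard convention); the whole support of a
margin set can be scored at once. The odds ratio is the unconditional
sample ratio ad/bc (∞ recorded when bc = 0 with ad > 0), not the
conditional MLE. BH families are per species across that species'
(module, GO) tests, matching the per-species presentation of the results;
a global family is available by configuration. The significance gate
defaults to odds ratio > 3 and q < 0.01; q_max is exposed because a
looser q < 0.1 display threshold is also in circulation for this kind of
figure. GO terms are not propagated up the hierarchy; redundancy is
instead handled downstream by the overlap-distance clustering
(average linkage, deterministic term order, flat cut at 0.5).

## Problem sizes and determinism

Default synthetic runs use 12 species × 80 transcripts × 40 samples
(960 transcripts — small enough for exact, single-block network
computation while leaving ≥ 45 transcripts per planted module after
coverage filtering). Seed-sweep checks (collapse success, driver-sign
recovery, enrichment power and null calibration) use 20 seeds. Every
random draw flows from one `numpy` Generator seeded from the run seed, so
identical seeds give bit-identical outputs end to end; the pipeline
manifest records SHA-256 checksums of every stage output to make this
verifiable.
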