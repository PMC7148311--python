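# bloomdyn

Species-resolved expression dynamics of multi-species plankton-bloom
meta-transcriptomes.

When environmental RNA reads from a bloom time series are aligned
competitively against a meta-reference (the concatenated reference
transcriptomes of hundreds of species), three problems dominate the
analysis: attributing reads to species fairly despite very different
reference sizes, suppressing cross-mapping artefacts between closely
related congeners, and summarizing tens of thousands of transcript
trajectories into interpretable expression programs linked to the
environment. `bloomdyn` implements that workflow as a tested library plus
a set of narrative analysis scripts, exercised end to end on a synthetic
community generator with known ground truth.

## The statistics at the core

**Relative abundance of transcripts (RAT).** For sample *i* and species
*j* with *n_ij* retained reads (mapping quality ≥ 10, single-hit only) and
total reference length *l_j* bases:

    RAT_ij = (n_ij / l_j) / Σ_j (n_ij / l_j)

Per-sample RAT sums to 1, is invariant to sequencing depth, and aggregates
additively to phyla (the denominator is shared). Species with max RAT
above 0.03 are selected as focal.

**Congeneric collapse.** Same-genus species whose RAT trajectories are
Spearman-correlated above 0.75 mostly reflect cross-mapping, not
co-occurrence. Per genus: a single species is kept; a fully inter-correlated
genus keeps only its highest-max-RAT member; otherwise species are grouped
into connected components of the ρ > 0.75 graph, each multi-species
component keeps its best member, and uncorrelated species are kept.
References shorter than 2×10⁶ bases are then discarded.

**Co-expression modules.** Counts are coverage-filtered (mean ≥ 10),
variance-stabilized with a closed-form negative-binomial VST (parametric
dispersion trend α(μ) = a₀/μ + a₁), and correlated with the biweight
midcorrelation. The unsigned adjacency |corr|^6 and its topological
overlap matrix (TOM) feed average-linkage clustering of 1−TOM with a
static height cut and a minimum module size; modules whose eigengenes
(first principal component of the module submatrix) correlate above 0.75
are merged.

**Environment association.** Redundancy analysis (RDA): PCA of the part
of the eigengene matrix explained by least-squares regression on the
standardized environment table, reported with eigenvalues, sample/response
scores and correlation-biplot scores.

**GO enrichment.** Per (species, module) with > 450 species transcripts in
the module and per GO term with > 20 transcripts: two-sided Fisher exact
test, per-species Benjamini–Hochberg control, significance at odds ratio
> 3 and q < 0.01. GO redundancy is handled by clustering terms on the
overlap distance 1 − |GO_i ∩ GO_j| / min(|GO_i|, |GO_j|).

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
default synthetic community (12 species, 40 samples, two congeneric pairs
at ρ = 0.95 and 0.3, three planted modules, planted GO enrichments) and
write their tables under `results/`:

```sh
python analysis/01_simulate_community.py
python analysis/02_quantify_rat.py
python analysis/03_collapse_metaref.py
python analysis/04_detect_modules.py
python analysis/05_environment_rda.py
python analysis/06_go_enrichment.py
```

Representative output:

```
RAT computed for 12 species x 40 samples
  focal species (max RAT > 0.03): 12
  median species-wise Spearman(RAT, true proportion): 0.976
community collapse kept 11/12 species
  rho=0.95 genus survivors: ['Chaetoceros_b'] (expected 1)
  rho=0.30 genus survivors: ['Thalassiosira_a', 'Thalassiosira_b'] (expected 2)
census collapse kept 219 species (expected 219):
  singleton genera 162, collapsed representatives 40,
  mixed-genus retained 25, length-filtered 8
detected 4 modules, sizes {1: 276, 2: 273, 3: 267, 4: 118}
adjusted Rand index vs planted modules: 0.983
RDA on 4 eigengenes x 9 environmental variables
  constrained variance fraction: 0.527
```

Reading: RAT trajectories track the true species proportions almost
perfectly in rank; the tightly correlated congeneric pair collapses to one
representative while the weakly correlated pair survives; on the
category-structured census community the selection procedure returns a
219-species meta-reference from 278 candidates; the three planted modules
are recovered nearly exactly (the fourth detected module collects
background transcripts); and about half of the eigengene variance is
explained by the nine environmental drivers.

A `bloomdyn` command-line umbrella (`simulate`, `build-ref`, `quantify`,
`modules`, `rda`, `enrich`, `run-all`, `validate`) wraps the same library
calls for shell use.

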