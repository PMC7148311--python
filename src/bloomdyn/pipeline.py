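"""End-to-end orchestration: simulate or load data, then run every stage.

Stage order mirrors the two-pass study design: first-pass quantification
against the full meta-reference, congeneric collapse to the second-pass
meta-reference, re-quantification, co-expression module detection,
redundancy analysis against the environment, and GO enrichment. A JSON
manifest records parameters, per-stage row counts and output checksums so
reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import coexpr, enrich, envassoc, metaref, quant, synthdata

logger = logging.getLogger(__name__)

STAGES = ["quant_pass1", "collapse", "quant_pass2", "coexpr", "envassoc", "enrich"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    input_dir: str  # fixture directory (write_fixture layout)
    output_dir: str
    collapse: metaref.CollapseParams = field(default_factory=metaref.CollapseParams)
    modules: coexpr.ModuleParams = field(default_factory=coexpr.ModuleParams)
    enrichment: enrich.EnrichmentFilters = field(default_factory=enrich.EnrichmentFilters)
    rat_focal_threshold: float = 0.03
    seed: int = 1


def validate_config(config: PipelineConfig, check_paths: bool = True) -> list[str]:
    """Return the list of violations (empty when valid)."""
    violations: list[str] = []
    if check_paths and not Path(config.input_dir).is_dir():
        violations.append(f"input_dir {config.input_dir} does not exist")
    for maker, obj in [
        (metaref.CollapseParams, config.collapse),
        (coexpr.ModuleParams, config.modules),
        (enrich.EnrichmentFilters, config.enrichment),
    ]:
        try:
            maker(**{k: getattr(obj, k) for k in obj.__dataclass_fields__})
        except ValueError as exc:
            violations.append(str(exc))
    if not 0.0 <= config.rat_focal_threshold < 1.0:
        violations.append("rat_focal_threshold must be in [0, 1)")
    return violations


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a fixture directory; returns the manifest dict.

    Missing optional inputs degrade gracefully: without a GO table the
    enrichment stage is skipped with an explicit manifest entry. A stage
    failure aborts the run with the failing stage named; outputs written so
    far keep a ``.partial`` marker file next to them.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial_marker = out / ".partial"
    partial_marker.write_text("run in progress\n")

    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "collapse": vars(config.collapse),
            "modules": vars(config.modules),
            "enrichment": vars(config.enrichment),
            "rat_focal_threshold": config.rat_focal_threshold,
        },
        "stages": {},
        "outputs": {},
    }

    bundle = synthdata.read_fixture(config.input_dir)
    current_stage = "load"
    try:
        # -- pass 1: RAT against the full catalogue
        current_stage = "quant_pass1"
        t0 = time.monotonic()
        rat1 = quant.compute_rat(bundle.counts, bundle.catalogue)
        rat1.rat.to_csv(out / "rat_pass1.tsv", sep="\t")
        manifest["stages"][current_stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "n_species": int(rat1.rat.shape[0]),
            "n_samples": int(rat1.rat.shape[1]),
        }

        # -- congeneric collapse to the second-pass reference
        current_stage = "collapse"
        t0 = time.monotonic()
        kept, report = metaref.genus_collapse(
            rat1.rat, bundle.taxonomy, config.collapse, bundle.catalogue.lengths()
        )
        metaref2 = metaref.build_metaref(bundle.catalogue, kept, prefix_ids=False)
        report.species_log.to_csv(out / "collapse_report.tsv", sep="\t", index=False)
        manifest["stages"][current_stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "n_kept": len(kept),
            "n_input": len(bundle.catalogue),
        }

        # -- pass 2: restrict counts to kept species and recompute RAT
        current_stage = "quant_pass2"
        t0 = time.monotonic()
        keep_tr = bundle.counts.transcript_species.isin(kept)
        counts2 = quant.CountMatrix(
            counts=bundle.counts.counts.loc[keep_tr[bundle.counts.counts.index]],
            transcript_species=bundle.counts.transcript_species[keep_tr],
        )
        rat2 = quant.compute_rat(counts2, metaref2)
        focal = quant.select_focal_species(rat2, config.rat_focal_threshold)
        rat2.rat.to_csv(out / "rat_pass2.tsv", sep="\t")
        (out / "focal_species.txt").write_text("\n".join(focal) + "\n")
        manifest["stages"][current_stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "n_species": int(rat2.rat.shape[0]),
            "n_focal": len(focal),
        }

        # -- co-expression modules
        current_stage = "coexpr"
        t0 = time.monotonic()
        expr, modules = coexpr.run_coexpression(counts2, config.modules)
        modules.labels.to_frame().to_csv(out / "module_labels.tsv", sep="\t")
        modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        comp = coexpr.module_composition(
            modules.labels, counts2.transcript_species, bundle.taxonomy
        )
        comp.to_csv(out / "module_composition.tsv", sep="\t", index=False)
        manifest["stages"][current_stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "n_transcripts": int(expr.values.shape[0]),
            "n_modules": len(modules.module_ids),
        }

        # -- redundancy analysis
        current_stage = "envassoc"
        t0 = time.monotonic()
        if modules.eigengenes.empty:
            manifest["stages"][current_stage] = {"skipped": "no modules detected"}
        else:
            Y = modules.eigengenes.T  # sample x module
            X = bundle.env.T.loc[Y.index]
            result = envassoc.rda(Y, X)
            result.sample_scores.to_csv(out / "rda_sample_scores.tsv", sep="\t")
            result.biplot_scores.to_csv(out / "rda_biplot_scores.tsv", sep="\t")
            result.eigenvalues.to_csv(out / "rda_eigenvalues.tsv", sep="\t")
            corr = envassoc.eigengene_env_correlations(modules.eigengenes, bundle.env.T)
            corr.to_csv(out / "eigengene_env_correlations.tsv", sep="\t", index=False)
            manifest["stages"][current_stage] = {
                "seconds": round(time.monotonic() - t0, 3),
                "constrained_fraction": round(result.constrained_fraction, 6),
                "n_axes": len(result.eigenvalues),
            }

        # -- GO enrichment
        current_stage = "enrich"
        t0 = time.monotonic()
        if bundle.go is None or bundle.go.empty:
            manifest["stages"][current_stage] = {"skipped": "no GO table provided"}
        elif modules.eigengenes.empty:
            manifest["stages"][current_stage] = {"skipped": "no modules detected"}
        else:
            annotation = enrich.GOAnnotation(bundle.go)
            table = enrich.fisher_enrichment(
                modules.labels, counts2.transcript_species, annotation, config.enrichment
            )
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"][current_stage] = {
                "seconds": round(time.monotonic() - t0, 3),
                "n_tests": int(len(table)),
                "n_significant": int(table["significant"].sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    partial_marker.unlink(missing_ok=True)
    return manifest
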