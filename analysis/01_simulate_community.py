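"""Generate the baseline synthetic bloom community.

Simulates 40 samplings of a 12-species community (two congeneric pairs,
rho 0.95 and 0.3; three planted co-expression modules; planted per-module
GO enrichment) and writes the full fixture — references, counts,
environment, taxonomy, GO table and ground truth — under
results/fixture/.
"""

from pathlib import Path

from bloomdyn import synthdata

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = synthdata.SimulationConfig()
    bundle = synthdata.simulate_community(cfg)
    files = synthdata.write_fixture(bundle, OUT / "fixture")
    n_counts = bundle.counts.counts.to_numpy().sum()
    print(f"simulated {cfg.n_species} species x {cfg.n_samples} samples")
    print(f"  {len(bundle.counts.counts)} transcripts, {n_counts:,} total reads")
    print(f"  planted modules: {sorted(bundle.truth.module_go_map)}")
    print(f"  wrote {len(files)} files under {OUT / 'fixture'}")


if __name__ == "__main__":
    main()
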