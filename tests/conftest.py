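import pytest

from bloomdyn import coexpr, synthdata


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic community at the default study conditions."""
    return synthdata.simulate_community(synthdata.SimulationConfig())


@pytest.fixture(scope="session")
def synthetic_module_params():
    """Module detection parameters sized for synthetic communities."""
    return coexpr.ModuleParams(min_module_size=50)


@pytest.fixture(scope="session")
def default_modules(default_bundle, synthetic_module_params):
    """VST + module detection on the default community."""
    return coexpr.run_coexpression(default_bundle.counts, synthetic_module_params)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, small community for I/O and pipeline tests."""
    cfg = synthdata.SimulationConfig(
        n_samples=12,
        n_species=4,
        transcripts_per_species=10,
        congeneric_pairs=[("Pairg", 0.9)],
        total_reads_per_sample=50_000,
        n_modules=2,
        go_terms=10,
        seed=5,
    )
    return synthdata.simulate_community(cfg)
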