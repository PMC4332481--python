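import numpy as np
import pytest

from srnakit.cli import PipelineConfig, PipelineInputs, run_pipeline
from srnakit.synthetic import (
    SimulationConfig,
    generate_reference,
    simulate_reads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_simulation():
    """Seed-42 default-scale simulation shared by recovery/acceptance tests."""
    config = SimulationConfig(seed=42)
    reference = generate_reference(config)
    libraries = simulate_reads(reference, config)
    return config, reference, libraries


@pytest.fixture(scope="session")
def default_pipeline_results(default_simulation):
    _, reference, libraries = default_simulation
    inputs = PipelineInputs(
        genome=reference.genome,
        libraries=libraries,
        transcript_seqs=reference.transcript_seqs,
        transcript_models=reference.transcript_models,
        repeats=reference.repeats,
        known_mirnas=reference.known_mirnas,
    )
    return run_pipeline(inputs, PipelineConfig())


@pytest.fixture(scope="session")
def small_simulation():
    """A scaled-down simulation for fast file-based round trips."""
    config = SimulationConfig(
        seed=7,
        genome_length=60_000,
        n_hairpins=6,
        n_conserved=3,
        n_repeats=12,
        n_shared_repeats=3,
        n_phased=3,
        n_decoy_transcripts=8,
        n_cis=4,
        n_trans=2,
        n_trans_decoys=1,
        n_background=60,
    )
    reference = generate_reference(config)
    libraries = simulate_reads(reference, config)
    return config, reference, libraries
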