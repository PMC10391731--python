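import pytest
from hypothesis import HealthCheck, settings

import umiquant as uq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def refs():
    return uq.make_references()


@pytest.fixture(scope="session")
def zero_error_model():
    """Noise-free small sample: 500 heterozygous cells, 20% activated."""
    return uq.SampleModel(
        n_cells=500,
        activated_cell_fraction=0.2,
        templates_per_allele_per_cell=1.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        low_quality_prob=0.0,
        mean_reads_per_molecule=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_error_run(refs, zero_error_model):
    molecules = uq.simulate_sample(refs, zero_error_model)
    reads = uq.sequence_reads(molecules, refs, zero_error_model)
    return molecules, reads


@pytest.fixture(scope="session")
def default_run(refs):
    """One default-condition (non-induced) sample pushed through the pipeline."""
    model = uq.SampleModel(seed=7)
    return uq.simulate_and_quantify(refs, model, "default_run")
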