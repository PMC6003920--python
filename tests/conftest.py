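import numpy as np
import pytest

from locustde import SyntheticConfig, generate_transcriptome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_transcriptome():
    """200 valid + 10 artifact contigs with truth, shared across tests."""
    cfg = SyntheticConfig(
        n_transcripts=200,
        n_artifact_contigs=10,
        lib_size_sol=125_000,
        lib_size_greg=100_000,
        seed=42,
    )
    contigs, truth = generate_transcriptome(cfg)
    return cfg, contigs, truth
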