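import pytest

from whi3kit.synthetic_data import SimulationConfig, generate_transcriptome


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def genes(cfg):
    """One shared synthetic transcriptome (200 genes, seed 7)."""
    return generate_transcriptome(cfg)
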