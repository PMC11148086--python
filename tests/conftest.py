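import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def demo_genes():
    from okseq import demo_gene_model

    return demo_gene_model()


@pytest.fixture
def single_origin_track():
    """Noiseless track with one always-firing origin at 1,000,500 bp."""
    from okseq import SimConfig, SimOrigin, sample_track, simulate_fork_directionality

    cfg = SimConfig(chrom_length=2_000_000, origins=[SimOrigin(1_000_500, 1.0)], n_cells=1, seed=0)
    p = simulate_fork_directionality(cfg)
    return sample_track(p, 50.0, 0, noiseless=True), cfg
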