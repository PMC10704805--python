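import numpy as np
import pytest
from hypothesis import settings

from pairppi import PairSet, SyntheticWorldConfig, generate_world

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "proteins.fasta"
    path.write_text(">p1 first protein\nACDE\nFGHI\n>p2\nacd\n>p3\nMKLVW\n")
    return path


@pytest.fixture
def small_world():
    """Strong-signal world small enough for exhaustive checking."""
    return generate_world(
        SyntheticWorldConfig(
            n_proteins=50,
            latent_dim=4,
            embed_dim=8,
            signal=4.0,
            noise_sd=0.1,
            seed=7,
            n_positives=20,
            ratio=5,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pairs(items):
    return PairSet.from_items(items)
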