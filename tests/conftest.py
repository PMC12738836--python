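"""Shared fixtures: tiny model configs and small synthetic datasets."""

import numpy as np
import pytest

from plastleader.model import ModelConfig
from plastleader.synthetic import SyntheticSpec, MotifPlan, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest structurally valid architecture, for fast shape/contract tests."""
    return ModelConfig(seq_length=30, conv_channels=4, channel_attention_reduction=2,
                       lstm_hidden=4, attention_heads=2, fc_sizes=(6, 8), seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """60 + 60 short leaders with a planted discriminative motif."""
    spec = SyntheticSpec(
        n_per_class=60, length=60, at_fraction=0.7,
        class_motifs={"motif": [MotifPlan("AGGAGG", (-20, -1), 1.0)], "background": []},
        forbidden_motifs={"background": [("AGGAGG", (-20, -1))]},
        oligo_tract_rate=0.5, seed=3,
    )
    return generate_dataset(spec)


def random_leader_strings(n, length, at_fraction, seed):
    """Plain i.i.d. AT-rich nucleotide strings (test-local background draw)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ATCG"))
    probs = [at_fraction / 2, at_fraction / 2,
             (1 - at_fraction) / 2, (1 - at_fraction) / 2]
    return ["".join(rng.choice(bases, size=length, p=probs)) for _ in range(n)]
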