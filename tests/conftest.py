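"""Shared fixtures: small synthetic families and a quickly trained model.

The small benchmark uses short sequences (120 +- 15 residues, two 10-mer
motifs per family, window 160) so that training a fully separable model
takes about a second; heavier, full-size runs live in the acceptance
tests.
"""

import numpy as np
import pytest

from phagemark import synthetic_data as sd
from phagemark.encoding import EncodingSpec, encode_batch
from phagemark.cnn_classifier import ModelConfig, build_model, train

SMALL_LEN_W = 160


def small_profiles(seed: int = 100):
    targets = [
        sd.make_family_profile(f"F{i + 1}", n_motifs=2, motif_len=10,
                               length_mean=120, length_sd=15, seed=seed + i)
        for i in range(3)
    ]
    extras = [sd.perturb_profile(targets[i], divergence=0.35,
                                 name=f"novel{i + 1}", seed=seed + 50 + i)
              for i in range(2)]
    return targets, extras


@pytest.fixture(scope="session")
def small_bench():
    targets, extras = small_profiles()
    return sd.make_benchmark(
        targets, extras,
        sd.BenchmarkSpec(n_train=80, n_test=40, n_others=120, n_openset=300,
                         substitution_rate=0.0, seed=2),
    )


@pytest.fixture(scope="session")
def small_spec():
    return EncodingSpec(len_w=SMALL_LEN_W)


@pytest.fixture(scope="session")
def small_encoded(small_bench, small_spec):
    X, ids = encode_batch(small_bench["train"].records, small_spec)
    y = np.array(small_bench["train"].label_indices())
    return X, y, ids


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(len_w=SMALL_LEN_W, epochs=10, seed=3, learning_rate=2e-3)


@pytest.fixture(scope="session")
def small_model(small_bench, small_encoded, small_config):
    """A model trained to full separation on the motif-planted families."""
    X, y, _ = small_encoded
    model = build_model(small_config, small_bench["train"].category_order)
    return train(model, X, y)
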