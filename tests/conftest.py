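import itertools

import numpy as np
import pytest

from promstruct import (
    LabeledSequenceSet,
    PromoterSimConfig,
    PropertyScale,
    build_matrix,
    generate_background,
    generate_promoters,
    load_default_scales,
)
from promstruct.synthetic import Markov1Model


def make_di_scale(name="toy", special=None, default=0.0):
    """Complete 16-entry dinucleotide scale with a few overridden values."""
    values = {}
    for i, pair in enumerate(itertools.product("ACGT", repeat=2)):
        values["".join(pair)] = default + 0.01 * i
    if special:
        values.update(special)
    return PropertyScale.from_values(name, values)


def make_tri_scale(name="toy3", default=0.0):
    values = {
        "".join(t): default + 0.01 * i
        for i, t in enumerate(itertools.product("ACGT", repeat=3))
    }
    return PropertyScale.from_values(name, values)


@pytest.fixture(scope="session")
def default_scales():
    return load_default_scales()


@pytest.fixture(scope="session")
def lookup_scale():
    """Spec'd toy lookup: AA=1, AC=2, CA=3, CC=4, everything else distinct."""
    return make_di_scale(special={"AA": 1.0, "AC": 2.0, "CA": 3.0, "CC": 4.0})


@pytest.fixture
def uniform_scale():
    return make_di_scale(name="uniform", special=None, default=0.0).__class__.from_values(
        "uniform7", {"".join(p): 7.0 for p in itertools.product("ACGT", repeat=2)}
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-signal set shared by slower integration tests."""
    cfg = PromoterSimConfig(n=120, plant_prob=1.0, seed=11)
    pos, manifest = generate_promoters(cfg)
    neg = generate_background(cfg.background, 120, cfg.length, seed=12)
    return cfg, pos, neg, manifest


@pytest.fixture(scope="session")
def planted_matrix(planted_dataset, default_scales):
    cfg, pos, neg, _ = planted_dataset
    seq_set = LabeledSequenceSet.from_parts(pos, neg)
    return build_matrix(seq_set, default_scales)


@pytest.fixture(scope="session")
def null_matrix(default_scales):
    model = Markov1Model.uniform()
    pos = generate_background(model, 60, 251, seed=21)
    neg = generate_background(model, 60, 251, seed=22)
    seq_set = LabeledSequenceSet.from_parts(pos, neg)
    return build_matrix(seq_set, default_scales)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
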