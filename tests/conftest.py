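import numpy as np
import pytest

import bondheat as bh
from bondheat import model as mm
from bondheat import synthetic as syn


@pytest.fixture(scope="session")
def ethanol():
    return bh.parse_smiles("CCO", name="ethanol")


@pytest.fixture(scope="session")
def benzene():
    return bh.parse_smiles("c1ccccc1", name="benzene")


@pytest.fixture(scope="session")
def small_library():
    """Clean planted library shared across tests (seeded, deterministic)."""
    return syn.generate_library(30, 70, syn.default_plants(), seed=7)


@pytest.fixture(scope="session")
def small_fps(small_library):
    return [bh.fingerprint(m) for m in small_library.molecules]


@pytest.fixture(scope="session")
def small_dataset(small_library, small_fps):
    return mm.LabeledDataset(small_fps, small_library.labels)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    filtered = mm.filter_rare_features(small_dataset, 3)
    return mm.train(filtered, C=1.0, seed=0, _keep_estimator=True)


@pytest.fixture(scope="session")
def random_weight_model(small_dataset):
    """Model with seeded random weights over the observed feature space."""
    rng = np.random.default_rng(42)
    feats = small_dataset.feature_space()
    weights = {fid: float(w) for fid, w in zip(feats, rng.normal(size=len(feats)))}
    return mm.LinearModel(
        weights=weights, bias=float(rng.normal()), C=1.0,
        negative_class_weight=1.0, depth=4, hash_bits=22, min_count=1,
    )
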