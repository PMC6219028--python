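from __future__ import annotations

import numpy as np
import pytest

from ivus_texturekit.classifier import RFParams, train, _threshold_from_values
from ivus_texturekit.config import extract_frames, fit_selections
from ivus_texturekit.features import TextureConfig, Window
from ivus_texturekit.phantom import PhantomSpec, generate_dataset, generate_phantom


def random_window(rng: np.random.Generator, k: int = 5, low: int = 0, high: int = 256) -> Window:
    return Window(rng.integers(low, high, size=(k, k)))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20181106)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    # Small annulus keeps the classifier/evaluation tests fast; blob count is
    # reduced so the blob-boundary fraction stays comparable to full scale.
    return PhantomSpec(size=160, r1=28, r2=58, blobs_per_class=3, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_tables(small_spec):
    """Feature tables for 2 train + 1 test small phantom frames."""
    triples = generate_dataset(small_spec, 3, seed=11)
    train_table = extract_frames(triples[:2], TextureConfig(), "train")
    test_table = extract_frames(triples[2:], TextureConfig(), "test")
    return train_table, test_table


@pytest.fixture(scope="session")
def small_model(small_tables):
    train_table, _ = small_tables
    thr = _threshold_from_values(
        train_table.loc[train_table["label"] == "FT", "intensity"].to_numpy(float), 100.0
    )
    selections = fit_selections(train_table, 0.95, (21, 15, 18), thr)
    return train(train_table, selections, rf_params=RFParams(seed=3))
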