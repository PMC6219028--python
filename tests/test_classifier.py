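import numpy as np
import pandas as pd
import pytest

from ivus_texturekit.classifier import (
    MultiLevelModel,
    RFParams,
    ROUTE_HIGH_NET3,
    ROUTE_LOW_NET2,
    ROUTE_LOW_NET3,
    compute_intensity_threshold,
    load_model,
    predict,
    route,
    save_model,
    train,
)
from ivus_texturekit.errors import ClassCoverageError, DegenerateInputError
from ivus_texturekit.pipeline_io import GrayFrame, LabelMap
from ivus_texturekit.selection import apply_selection

from .oracles import percentile_oracle


def _frame_with_ft(intensities):
    n = max(8, len(intensities))
    px = np.zeros((n, n), dtype=np.uint8)
    lb = np.zeros((n, n), dtype=np.int64)
    for i, v in enumerate(intensities):
        px[0, i] = v
        lb[0, i] = 1  # FT
    return GrayFrame(px), LabelMap(lb)


def test_threshold_is_ft_maximum():
    frame, labels = _frame_with_ft([10, 50, 42])
    assert compute_intensity_threshold(labels, frame) == 50.0


def test_threshold_singleton_any_percentile():
    frame, labels = _frame_with_ft([77])
    for pct in (5, 50, 100):
        assert compute_intensity_threshold(labels, frame, pct) == 77.0


def test_threshold_percentile_matches_sort_oracle():
    values = list(range(1, 101))
    frame, labels = _frame_with_ft(values)
    for pct in (10, 25, 50, 99, 100):
        assert compute_intensity_threshold(labels, frame, pct) == percentile_oracle(
            [float(v) for v in values], pct
        )


def test_threshold_requires_ft_pixels():
    frame = GrayFrame(np.zeros((8, 8), dtype=np.uint8))
    labels = LabelMap(np.zeros((8, 8), dtype=np.int64))
    with pytest.raises(DegenerateInputError):
        compute_intensity_threshold(labels, frame)


def test_route_strict_inequality():
    assert route(50, 51) == "high"
    assert route(50, 50) == "low"  # boundary goes low: FT's own max stays low
    assert (np.asarray(route(255, np.arange(256))) == "low").all()


def test_train_missing_class_rejected(small_tables):
    train_table, _ = small_tables
    no_dc = train_table[train_table["label"] != "DC"]
    from ivus_texturekit.config import fit_selections
    from ivus_texturekit.classifier import _threshold_from_values

    thr = _threshold_from_values(
        train_table.loc[train_table["label"] == "FT", "intensity"].to_numpy(float), 100.0
    )
    sels = fit_selections(train_table, 0.95, (21, 15, 18), thr)
    with pytest.raises(ClassCoverageError):
        train(no_dc, sels)


def test_training_set_fit_is_strong(small_model, small_tables, small_spec):
    """Each net nearly reproduces its training pool on well-separated pixels.

    "Well separated" means the 5x5 window sits inside a single tissue blob;
    windows straddling a blob boundary mix two tissues and are genuinely
    ambiguous, so they are excluded from this closed-loop check.
    """
    from scipy.ndimage import binary_erosion

    from ivus_texturekit.phantom import generate_dataset
    from ivus_texturekit.pipeline_io import LABEL_CODES

    train_table, _ = small_tables
    triples = generate_dataset(small_spec, 3, seed=11)  # the fixture's frames
    pure = {}
    for fi, (_, _, labmap) in enumerate(triples[:2]):
        mask = np.zeros(labmap.shape, dtype=bool)
        for code in LABEL_CODES.values():
            if code:
                mask |= binary_erosion(labmap.labels == code, np.ones((5, 5)))
        pure[fi] = mask
    rows = train_table["row"].to_numpy(int)
    cols = train_table["col"].to_numpy(int)
    frames = train_table["frame"].to_numpy(int)
    is_pure = np.array([pure[f][r, c] for f, r, c in zip(frames, rows, cols)])

    labels = train_table["label"].to_numpy(object)
    intensity = train_table["intensity"].to_numpy(float)
    pools = {
        1: (intensity <= small_model.threshold, np.isin(labels, ("NC", "DC"))),
        2: (np.isin(labels, ("FT", "FFT")), labels == "FFT"),
        3: (np.isin(labels, ("NC", "DC")), labels == "DC"),
    }
    for net_id, (mask, positive) in pools.items():
        mask = mask & is_pure
        sel = small_model.selections[net_id]
        X = sel.standardize(apply_selection(train_table.loc[mask], sel))
        acc = (small_model.nets[net_id].predict(X) == positive[mask]).mean()
        assert acc >= 0.95, f"net {net_id} training accuracy {acc:.3f}"


def test_seeded_determinism(small_tables):
    train_table, test_table = small_tables
    from ivus_texturekit.config import fit_selections
    from ivus_texturekit.classifier import _threshold_from_values

    thr = _threshold_from_values(
        train_table.loc[train_table["label"] == "FT", "intensity"].to_numpy(float), 100.0
    )
    sels = fit_selections(train_table, 0.95, (21, 15, 18), thr)
    m1 = train(train_table, sels, rf_params=RFParams(seed=5))
    m2 = train(train_table, sels, rf_params=RFParams(seed=5))
    p1, p2 = predict(m1, test_table), predict(m2, test_table)
    assert (p1.labels == p2.labels).all()
    assert np.array_equal(p1.score_net1, p2.score_net1, equal_nan=True)


def test_route_tags_partition_and_match_labels(small_model, small_tables):
    _, test_table = small_tables
    pred = predict(small_model, test_table)
    tags = set(pred.routes)
    assert tags <= {ROUTE_LOW_NET2, ROUTE_LOW_NET3, ROUTE_HIGH_NET3}
    assert not np.any(pred.routes == None)  # noqa: E711 — every pixel routed once

    net2 = pred.routes == ROUTE_LOW_NET2
    assert set(pred.labels[net2]) <= {"FT", "FFT"}
    assert set(pred.labels[~net2]) <= {"NC", "DC"}
    # no pixel scored by both leaf nets
    assert not np.any(~np.isnan(pred.score_net2) & ~np.isnan(pred.score_net3))
    # high pixels bypass net 1
    high = test_table["intensity"].to_numpy(float) > small_model.threshold
    assert (pred.routes[high] == ROUTE_HIGH_NET3).all()
    assert np.isnan(pred.score_net1[high]).all()


def test_high_route_forces_ncdc(small_model, small_tables):
    _, test_table = small_tables
    pred = predict(small_model, test_table)
    high = test_table["intensity"].to_numpy(float) > small_model.threshold
    assert high.any()
    assert set(pred.labels[high]) <= {"NC", "DC"}


def test_model_round_trip(tmp_path, small_model, small_tables):
    _, test_table = small_tables
    save_model(small_model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert back.threshold == small_model.threshold
    assert back.selections == small_model.selections
    p1, p2 = predict(small_model, test_table), predict(back, test_table)
    assert (p1.labels == p2.labels).all()
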