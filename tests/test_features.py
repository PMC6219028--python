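"""Texture-feature correctness: trivial closed-form cases, brute-force
oracle agreement, and invariants of the whole-frame extraction path."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivus_texturekit import FEATURE_NAMES, TextureConfig, extract_all
from ivus_texturekit.errors import BoundsError, DegenerateInputError, ParameterError
from ivus_texturekit.features import (
    FEATURE_FAMILIES,
    LBPNeighborhood,
    Window,
    compute_feature_vector,
    compute_fos,
    compute_glcm_features,
    compute_glrlm_features,
    compute_lbp_features,
    compute_lem_features,
    cooccurrence_matrix,
    extract_window,
    laws_masks,
    run_length_matrix,
)
from ivus_texturekit.pipeline_io import GrayFrame, LabelMap, PlaqueMask

from .oracles import fos_oracle, glcm_oracle, glrlm_oracle, lbp_oracle, lem_oracle

pytestmark = pytest.mark.timeout(600)


# ---------------------------------------------------------------------------
# Inventory
# ---------------------------------------------------------------------------


def test_feature_inventory_counts():
    assert len(FEATURE_NAMES) == 54
    assert len(set(FEATURE_NAMES)) == 54
    sizes = {fam: len(names) for fam, names in FEATURE_FAMILIES.items()}
    assert sizes == {"intensity": 1, "fos": 5, "glcm": 17, "lem": 18, "glrlm": 11, "lbp": 2}
    assert len(laws_masks()) == 9  # nine texture images feed the 18 LEM values


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def test_extract_window_constant_and_reflect():
    frame = GrayFrame(np.full((20, 20), 100, dtype=np.uint8))
    assert (extract_window(frame, (10, 10), 5).values == 100).all()

    ramp = GrayFrame((np.arange(100, dtype=np.uint8).reshape(10, 10)))
    win = extract_window(ramp, (0, 0), 3)
    # out-of-frame cells mirror in-frame neighbors (no edge repetition)
    assert win.values[0, 0] == ramp.pixels[1, 1]
    assert win.values[1, 0] == ramp.pixels[0, 1]
    assert win.values[0, 1] == ramp.pixels[1, 0]


def test_extract_window_contract_errors():
    frame = GrayFrame(np.zeros((10, 10), dtype=np.uint8))
    with pytest.raises(ParameterError):
        extract_window(frame, (5, 5), 4)
    with pytest.raises(BoundsError):
        extract_window(frame, (10, 2), 5)


# ---------------------------------------------------------------------------
# Trivial closed-form cases
# ---------------------------------------------------------------------------


def test_fos_trivial_cases():
    const = compute_fos(Window(np.full((5, 5), 7)))
    assert const == {
        "fos_mean": 7.0,
        "fos_variance": 0.0,
        "fos_std": 0.0,
        "fos_kurtosis": 0.0,
        "fos_skewness": 0.0,
    }
    vals = np.zeros(25)
    vals[:5] = 10  # twenty 0s, five 10s — frozen from the literal-formula oracle
    mixed = compute_fos(Window(vals.reshape(5, 5)))
    assert mixed["fos_mean"] == pytest.approx(2.0)
    assert mixed["fos_variance"] == pytest.approx(16.0)
    assert mixed["fos_std"] == pytest.approx(4.0)
    assert mixed["fos_skewness"] == pytest.approx(1.5)
    assert mixed["fos_kurtosis"] == pytest.approx(0.25)


def test_glcm_trivial_cases():
    const = compute_glcm_features(Window(np.full((5, 5), 42)))
    assert const["glcm_energy"] == pytest.approx(1.0)
    assert const["glcm_entropy"] == pytest.approx(0.0)
    assert const["glcm_contrast"] == pytest.approx(0.0)
    assert const["glcm_dissimilarity"] == pytest.approx(0.0)
    assert const["glcm_maximum_probability"] == pytest.approx(1.0)

    checker = (np.indices((5, 5)).sum(axis=0) % 2) * 255
    cb = compute_glcm_features(Window(checker), d=1, theta=135)
    assert cb["glcm_contrast"] == pytest.approx(0.0)  # diagonal neighbors share a level


def test_glrlm_trivial_cases():
    const = compute_glrlm_features(Window(np.full((5, 5), 99)), theta=0)
    assert const["glrlm_rp"] == pytest.approx(0.2)  # 5 runs of length 5
    assert const["glrlm_sre"] == pytest.approx(1 / 25)
    assert const["glrlm_lre"] == pytest.approx(25.0)
    assert const["glrlm_gln"] == pytest.approx(5.0)
    assert const["glrlm_rln"] == pytest.approx(5.0)

    stripes = np.tile(np.array([0, 255, 0, 255, 0]), (5, 1))  # all runs length 1
    alt = compute_glrlm_features(Window(stripes), theta=0)
    assert alt["glrlm_rp"] == pytest.approx(1.0)
    assert alt["glrlm_sre"] == pytest.approx(1.0)
    assert alt["glrlm_lre"] == pytest.approx(1.0)


def test_lem_trivial_and_sign_invariants(rng):
    const = compute_lem_features(Window(np.full((5, 5), 123)))
    assert all(v == 0.0 for v in const.values())  # every mask has a zero-sum axis

    for _ in range(10):
        w = Window(rng.integers(0, 256, (5, 5)))
        feats = compute_lem_features(w)
        for name in laws_masks():
            mss, mas = feats[f"lem_mss_{name}"], feats[f"lem_mas_{name}"]
            assert mss >= 0 and mas >= 0
            assert (mss == 0) == (mas == 0)


def test_lbp_trivial_cases():
    flat = compute_lbp_features(LBPNeighborhood(5, tuple([5] * 8)))
    assert flat == {"lbp_basic": 255.0, "lbp_riu2": 8.0}  # s(0) = 1

    dark = compute_lbp_features(LBPNeighborhood(200, tuple([10] * 8)))
    assert dark == {"lbp_basic": 0.0, "lbp_riu2": 0.0}

    # circular bit pattern 1,0,0,0,0,0,0,1 under the documented ordering
    neigh = LBPNeighborhood(100, (150, 50, 50, 50, 50, 50, 50, 150))
    two_bits = compute_lbp_features(neigh)
    assert two_bits["lbp_riu2"] == 2.0  # U = 2 -> uniform, two set bits
    assert two_bits["lbp_basic"] == 2**0 + 2**7

    with pytest.raises(ParameterError):
        LBPNeighborhood(0, (1, 2, 3))


# ---------------------------------------------------------------------------
# Brute-force oracle agreement (the core correctness evidence)
# ---------------------------------------------------------------------------


def _random_windows(n, seed=4):
    rng = np.random.default_rng(seed)
    wins = [rng.integers(0, 256, (5, 5)) for _ in range(n - 2)]
    wins.append(rng.integers(0, 4, (5, 5)) * 80)  # few-level windows stress ties
    wins.append(np.full((5, 5), int(rng.integers(0, 256))))
    return wins


@pytest.mark.parametrize("theta,ng,symmetric", [(135, 16, False), (0, 8, False), (45, 16, True), (90, 4, False)])
def test_glcm_matches_exhaustive_pair_oracle(theta, ng, symmetric):
    for arr in _random_windows(30, seed=theta + ng):
        ours = compute_glcm_features(Window(arr), d=1, theta=theta, ng=ng, symmetric=symmetric)
        ref = glcm_oracle(arr, d=1, theta=theta, ng=ng, symmetric=symmetric)
        for name in ours:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name


@pytest.mark.parametrize("theta,ng", [(0, 16), (90, 16), (45, 8), (135, 16)])
def test_glrlm_matches_scanline_oracle(theta, ng):
    for arr in _random_windows(30, seed=theta + ng + 1):
        ours = compute_glrlm_features(Window(arr), theta=theta, ng=ng)
        ref = glrlm_oracle(arr, theta=theta, ng=ng)
        for name in ours:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name


def test_lem_matches_loop_convolution_oracle():
    for arr in _random_windows(20, seed=9):
        ours = compute_lem_features(Window(arr))
        ref = lem_oracle(arr)
        for name in ours:
            assert ours[name] == pytest.approx(ref[name], rel=1e-12, abs=1e-9), name


def test_fos_matches_literal_formula_oracle():
    for arr in _random_windows(30, seed=2):
        ours = compute_fos(Window(arr))
        ref = fos_oracle(arr)
        for name in ours:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 255), min_size=9, max_size=9))
def test_lbp_matches_bitwise_oracle(vals):
    center, neighbors = vals[0], vals[1:]
    ours = compute_lbp_features(LBPNeighborhood(center, tuple(neighbors)))
    assert ours == lbp_oracle(center, neighbors)


# ---------------------------------------------------------------------------
# Matrix-level invariants
# ---------------------------------------------------------------------------


def test_cooccurrence_normalization_and_run_conservation(rng):
    for _ in range(20):
        w = Window(rng.integers(0, 256, (5, 5)))
        P = cooccurrence_matrix(w)
        assert P.counts.sum() == 16  # 4x4 valid diagonal pairs
        assert P.normalized.sum() == pytest.approx(1.0)
        R = run_length_matrix(w)
        lengths = np.arange(1, 6)
        assert (R.counts * lengths[None, :]).sum() == 25  # runs cover every pixel
        assert R.counts.sum() == R.n_runs


# ---------------------------------------------------------------------------
# Whole-frame extraction
# ---------------------------------------------------------------------------


def test_extract_all_row_and_column_contract(small_phantom):
    frame, mask, labels = small_phantom
    sub = PlaqueMask(mask.flags & (np.arange(frame.shape[0])[:, None] % 7 == 0))
    table = extract_all(frame, sub, labels)
    assert len(table) == sub.n_pixels
    assert list(table.columns[3:]) == list(FEATURE_NAMES)
    assert np.isfinite(table[list(FEATURE_NAMES)].to_numpy()).all()


def test_extract_all_matches_per_window_route(small_phantom, rng):
    frame, mask, labels = small_phantom
    table = extract_all(frame, mask, labels)
    for i in rng.choice(len(table), size=25, replace=False):
        r, c = int(table.iloc[i]["row"]), int(table.iloc[i]["col"])
        single = compute_feature_vector(frame, (r, c))
        for name in FEATURE_NAMES:
            assert table.iloc[i][name] == pytest.approx(single[name], abs=1e-9), name


def test_extract_all_deterministic_and_intensity_raw(small_phantom):
    frame, mask, labels = small_phantom
    a = extract_all(frame, mask, labels)
    b = extract_all(frame, mask, labels)
    assert a.equals(b)
    rows = a["row"].to_numpy(int)
    cols = a["col"].to_numpy(int)
    assert (a["intensity"].to_numpy() == frame.pixels[rows, cols]).all()


def test_extract_all_constant_frame_interior_rows_identical():
    frame = GrayFrame(np.full((20, 20), 77, dtype=np.uint8))
    flags = np.zeros((20, 20), dtype=bool)
    flags[8:12, 8:12] = True
    table = extract_all(frame, PlaqueMask(flags))
    feats = table[list(FEATURE_NAMES)].to_numpy()
    assert np.ptp(feats, axis=0).max() == 0.0


def test_extract_all_empty_mask_rejected():
    frame = GrayFrame(np.zeros((10, 10), dtype=np.uint8))
    with pytest.raises(DegenerateInputError):
        extract_all(frame, PlaqueMask(np.zeros((10, 10), dtype=bool)))


def test_extract_all_diagonal_glrlm_fallback(small_phantom):
    frame, mask, labels = small_phantom
    sub = PlaqueMask(mask.flags & (np.arange(frame.shape[0])[:, None] % 31 == 0))
    cfg = TextureConfig(glrlm_theta=135)
    table = extract_all(frame, sub, labels, cfg)
    i = len(table) // 2
    r, c = int(table.iloc[i]["row"]), int(table.iloc[i]["col"])
    win = extract_window(frame, (r, c), 5)
    ref = glrlm_oracle(win.values, theta=135, ng=16)
    for name, val in ref.items():
        assert table.iloc[i][name] == pytest.approx(val, abs=1e-9)


def test_shift_invariance_on_unquantized_path(rng):
    """Adding a constant leaves contrast/dissimilarity (Ng=256) and every
    zero-sum Laws feature unchanged; 16-level quantization breaks this."""
    arr = rng.integers(0, 200, (5, 5))
    shifted = arr + 30
    a = compute_glcm_features(Window(arr), ng=256)
    b = compute_glcm_features(Window(shifted), ng=256)
    assert b["glcm_contrast"] == pytest.approx(a["glcm_contrast"], abs=1e-9)
    assert b["glcm_dissimilarity"] == pytest.approx(a["glcm_dissimilarity"], abs=1e-9)
    la, lb = compute_lem_features(Window(arr)), compute_lem_features(Window(shifted))
    for name in la:
        assert lb[name] == pytest.approx(la[name], rel=1e-9, abs=1e-9)
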