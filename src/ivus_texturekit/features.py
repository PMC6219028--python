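"""Per-pixel texture features for IVUS plaque characterization.

For every plaque pixel a 54-entry feature vector is computed from a square
window centered on it (5x5 for all families, 3x3 for LBP):

* intensity (1) — the raw center-pixel gray value, untouched by quantization;
* first-order statistics (5) — population mean, variance, standard deviation,
  excess kurtosis and skewness over the 25 window pixels;
* gray-level co-occurrence matrix (17) — Haralick-style features of the
  normalized co-occurrence matrix at pixel distance 1, angle 135 degrees,
  16 uniform gray bins;
* Laws energy measures (18) — mean square sum (MSS) and mean absolute sum
  (MAS) of the responses of the nine symmetric 5x5 Laws masks;
* extended gray-level run-length matrix (11) — the five classical run-length
  features plus the six gray-level-weighted extensions, horizontal runs;
* local binary pattern (2) — the basic 8-bit code and its rotation-invariant
  uniform variant (riu2).

Border handling reflects the *frame* (``numpy.pad`` ``mode='reflect'``) so
every mask pixel receives a full window; the mask constrains window centers
only, not window contents.

Two computational routes exist: the per-window functions below (the
definitional API) and a vectorized bulk path used by :func:`extract_all`.
Both are exercised against each other and against brute-force oracles in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    DegenerateInputError,
    DimensionError,
    ParameterError,
)
from .pipeline_io import GrayFrame, LabelMap, PlaqueMask

# ---------------------------------------------------------------------------
# Canonical feature inventory
# ---------------------------------------------------------------------------

FOS_NAMES = ("fos_mean", "fos_variance", "fos_std", "fos_kurtosis", "fos_skewness")

GLCM_NAMES = (
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_maximum_probability",
    "glcm_variance",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_idmn",
)

#: The nine symmetric Laws masks (transpose-averaged where asymmetric).
LAWS_MASK_NAMES = ("e5l5", "s5l5", "r5l5", "e5e5", "s5e5", "r5e5", "s5s5", "r5s5", "r5r5")
LEM_NAMES = tuple(f"lem_mss_{m}" for m in LAWS_MASK_NAMES) + tuple(
    f"lem_mas_{m}" for m in LAWS_MASK_NAMES
)

GLRLM_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_rp",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
)

LBP_NAMES = ("lbp_basic", "lbp_riu2")

#: Canonical column order of the 54-feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    ("intensity",) + FOS_NAMES + GLCM_NAMES + LEM_NAMES + GLRLM_NAMES + LBP_NAMES
)

FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "intensity": ("intensity",),
    "fos": FOS_NAMES,
    "glcm": GLCM_NAMES,
    "lem": LEM_NAMES,
    "glrlm": GLRLM_NAMES,
    "lbp": LBP_NAMES,
}

assert len(FEATURE_NAMES) == 54


@dataclass(frozen=True)
class TextureConfig:
    """Knobs of the extraction stage; defaults reproduce the method settings."""

    window: int = 5
    lbp_window: int = 3
    ng: int = 16  # quantized gray levels for GLCM / GLRLM
    glcm_d: int = 1
    glcm_theta: int = 135
    glcm_symmetric: bool = False
    glrlm_theta: int = 0
    padding: str = "reflect"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.lbp_window % 2 == 0:
            raise ParameterError("window sizes must be odd")
        if self.ng < 2:
            raise ParameterError("ng must be >= 2")
        if self.glcm_theta not in _GLCM_OFFSETS:
            raise ParameterError(f"glcm_theta must be one of {sorted(_GLCM_OFFSETS)}")
        if self.glrlm_theta not in (0, 45, 90, 135):
            raise ParameterError("glrlm_theta must be one of 0, 45, 90, 135")


@dataclass(frozen=True)
class Window:
    """A K x K patch of gray values centered on a frame pixel."""

    values: np.ndarray
    center: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError(f"window must be square, got {v.shape}")
        if v.shape[0] % 2 == 0:
            raise ParameterError("window size must be odd")
        if v.min() < 0 or v.max() > 255:
            raise ParameterError("window values outside [0, 255]")
        object.__setattr__(self, "values", v.astype(np.int64))

    @property
    def size(self) -> int:
        return self.values.shape[0]


def extract_window(frame: GrayFrame, center: tuple[int, int], k: int = 5) -> Window:
    """The K x K window centered on ``center``, reflect-padded at borders."""
    if k % 2 == 0:
        raise ParameterError(f"window size must be odd, got {k}")
    r, c = center
    if not (0 <= r < frame.height and 0 <= c < frame.width):
        raise BoundsError(f"center {center} outside frame of shape {frame.shape}")
    pad = k // 2
    padded = np.pad(frame.pixels, pad, mode="reflect")
    return Window(padded[r : r + k, c : c + k], center=(r, c))


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------


def compute_fos(window: Window) -> dict[str, float]:
    """Population moments over all window pixels.

    Kurtosis is *excess* kurtosis; for a zero-variance window skewness and
    kurtosis are defined as 0.
    """
    out = _fos_bulk(window.values.reshape(1, -1).astype(np.float64))
    return dict(zip(FOS_NAMES, out[0]))


def _fos_bulk(flat: np.ndarray) -> np.ndarray:
    """(n, K*K) float windows -> (n, 5) FOS features."""
    mean = flat.mean(axis=1)
    centered = flat - mean[:, None]
    var = (centered**2).mean(axis=1)
    std = np.sqrt(var)
    ok = var > 0
    safe_std = np.where(ok, std, 1.0)
    z = centered / safe_std[:, None]
    kurt = np.where(ok, (z**4).mean(axis=1) - 3.0, 0.0)
    skew = np.where(ok, (z**3).mean(axis=1), 0.0)
    return np.column_stack([mean, var, std, kurt, skew])


# ---------------------------------------------------------------------------
# Gray-level quantization (shared by GLCM and GLRLM)
# ---------------------------------------------------------------------------


def quantize(values: np.ndarray, ng: int) -> np.ndarray:
    """Uniform binning of [0, 255] into ``ng`` levels (0-based bin index)."""
    q = (np.asarray(values, dtype=np.int64) * ng) // 256
    return np.minimum(q, ng - 1)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

# Offset (dr, dc) pairing pixel (r, c) with (r + dr, c + dc).  At 135 degrees
# the neighbor is the upper-left diagonal pixel (r - 1, c - 1).
_GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Ng x Ng pair counts at offset (d, theta); first index = reference pixel."""

    counts: np.ndarray
    d: int
    theta: int
    ng: int

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise DegenerateInputError("co-occurrence matrix has no pixel pairs")
        return self.counts / total


def cooccurrence_matrix(
    window: Window, d: int = 1, theta: int = 135, ng: int = 16, symmetric: bool = False
) -> CooccurrenceMatrix:
    if theta not in _GLCM_OFFSETS:
        raise ParameterError(f"theta must be one of {sorted(_GLCM_OFFSETS)}")
    q = quantize(window.values, ng)
    dr, dc = (d * o for o in _GLCM_OFFSETS[theta])
    k = window.size
    counts = np.zeros((ng, ng), dtype=np.int64)
    for r in range(k):
        for c in range(k):
            rr, cc = r + dr, c + dc
            if 0 <= rr < k and 0 <= cc < k:
                counts[q[r, c], q[rr, cc]] += 1
    if symmetric:
        counts = counts + counts.T
    if counts.sum() == 0:
        raise DegenerateInputError(f"no valid pixel pair at offset d={d}, theta={theta}")
    return CooccurrenceMatrix(counts, d=d, theta=theta, ng=ng)


def compute_glcm_features(
    window: Window, d: int = 1, theta: int = 135, ng: int = 16, symmetric: bool = False
) -> dict[str, float]:
    """The 17 co-occurrence features (Haralick definitions, natural log).

    Gray-level indices in the weighting formulas are 1-based bin indices.
    ``0 * log 0`` is taken as 0 throughout; the information measure of
    correlation is the first Haralick variant (IMC1), defined as 0 when both
    marginal entropies vanish.
    """
    P = cooccurrence_matrix(window, d=d, theta=theta, ng=ng, symmetric=symmetric)
    out = _glcm_features_bulk(P.normalized.reshape(1, -1), ng)
    return dict(zip(GLCM_NAMES, out[0]))


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0 * log 0 := 0 convention."""
    return np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)


def _glcm_features_bulk(p_flat: np.ndarray, ng: int) -> np.ndarray:
    """(n, ng*ng) normalized matrices -> (n, 17) features, vectorized."""
    n = p_flat.shape[0]
    p = p_flat.reshape(n, ng, ng)
    i = np.arange(1, ng + 1, dtype=np.float64)  # 1-based row (reference) index
    j = i  # 1-based column (neighbor) index
    ii = i[:, None] * np.ones((1, ng))
    jj = np.ones((ng, 1)) * j[None, :]

    px = p.sum(axis=2)  # (n, ng)
    py = p.sum(axis=1)
    mu_x = px @ i
    mu_y = py @ j

    flat = p.reshape(n, ng * ng)
    iif, jjf = ii.ravel(), jj.ravel()

    autocorrelation = flat @ (iif * jjf)
    contrast = flat @ ((iif - jjf) ** 2)
    dissimilarity = flat @ np.abs(iif - jjf)
    energy = (flat**2).sum(axis=1)
    entropy = -_xlogx(flat).sum(axis=1)
    homogeneity = flat @ (1.0 / (1.0 + (iif - jjf) ** 2))
    max_prob = flat.max(axis=1)
    idmn = flat @ (1.0 / (1.0 + ((iif - jjf) ** 2) / float(ng) ** 2))

    spread = iif[None, :] + jjf[None, :] - (mu_x + mu_y)[:, None]
    cluster_shade = (flat * spread**3).sum(axis=1)
    cluster_prominence = (flat * spread**4).sum(axis=1)

    variance = (flat * (iif[None, :] - mu_x[:, None]) ** 2).sum(axis=1)

    # Sum / difference distributions: k = i + j in 2..2Ng, k = |i - j| in 0..Ng-1.
    sum_idx = (ii + jj).astype(np.int64).ravel() - 2  # 0..2Ng-2
    diff_idx = np.abs(ii - jj).astype(np.int64).ravel()  # 0..Ng-1
    S = np.zeros((ng * ng, 2 * ng - 1))
    S[np.arange(ng * ng), sum_idx] = 1.0
    D = np.zeros((ng * ng, ng))
    D[np.arange(ng * ng), diff_idx] = 1.0
    p_sum = flat @ S  # (n, 2Ng-1), support k = 2..2Ng
    p_diff = flat @ D  # (n, Ng),   support k = 0..Ng-1

    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kd = np.arange(0, ng, dtype=np.float64)
    sum_average = p_sum @ ks
    sum_variance = (p_sum * (ks[None, :] - sum_average[:, None]) ** 2).sum(axis=1)
    sum_entropy = -_xlogx(p_sum).sum(axis=1)
    diff_mean = p_diff @ kd
    difference_variance = (p_diff * (kd[None, :] - diff_mean[:, None]) ** 2).sum(axis=1)
    difference_entropy = -_xlogx(p_diff).sum(axis=1)

    # IMC1 = (HXY - HXY1) / max(HX, HY); 0 when both marginal entropies are 0.
    hx = -_xlogx(px).sum(axis=1)
    hy = -_xlogx(py).sum(axis=1)
    pxy = px[:, :, None] * py[:, None, :]
    hxy1 = -(p * np.where(pxy > 0, np.log(np.where(pxy > 0, pxy, 1.0)), 0.0)).reshape(
        n, -1
    ).sum(axis=1)
    denom = np.maximum(hx, hy)
    imc1 = np.where(denom > 0, (entropy - hxy1) / np.where(denom > 0, denom, 1.0), 0.0)

    return np.column_stack(
        [
            autocorrelation,
            contrast,
            cluster_prominence,
            cluster_shade,
            dissimilarity,
            energy,
            entropy,
            homogeneity,
            max_prob,
            variance,
            sum_average,
            sum_variance,
            sum_entropy,
            difference_variance,
            difference_entropy,
            imc1,
            idmn,
        ]
    )


# ---------------------------------------------------------------------------
# Laws energy measures
# ---------------------------------------------------------------------------

_LAWS_VECTORS = {
    "l5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),  # level
    "e5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),  # edge
    "s5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),  # spot
    "r5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),  # ripple
}


def laws_masks() -> dict[str, np.ndarray]:
    """The nine 5x5 masks; asymmetric pairs are transpose-averaged."""
    masks = {}
    for name in LAWS_MASK_NAMES:
        a, b = _LAWS_VECTORS[name[:2]], _LAWS_VECTORS[name[2:]]
        m = np.outer(a, b)
        masks[name] = (m + m.T) / 2.0 if name[:2] != name[2:] else m
    return masks


_LAWS_MASKS = laws_masks()


def compute_lem_features(window: Window) -> dict[str, float]:
    """MSS and MAS of the nine Laws texture images of the window.

    Each mask is cross-correlated with the reflect-padded window, giving a
    same-size texture image; MSS is the mean of its squared responses, MAS
    the mean of its absolute responses.  (Correlation and convolution differ
    only in sign for these masks, which the energy statistics ignore.)
    """
    k = window.size
    if k != 5:
        raise ParameterError("Laws energy measures are defined on 5x5 windows")
    padded = np.pad(window.values.astype(np.float64), 2, mode="reflect")
    patches = np.lib.stride_tricks.sliding_window_view(padded, (5, 5))
    out = {}
    for name, mask in _LAWS_MASKS.items():
        tex = np.einsum("uvab,ab->uv", patches, mask)
        out[f"lem_mss_{name}"] = float((tex**2).mean())
        out[f"lem_mas_{name}"] = float(np.abs(tex).mean())
    return {name: out[name] for name in LEM_NAMES}


def _laws_operators(k: int = 5) -> np.ndarray:
    """(9, k*k, k*k) linear operators: flat window -> flat texture image.

    Encodes the window-local reflect padding so the bulk path matches the
    per-window definition exactly.
    """
    pad = k // 2
    reflect = np.pad(np.arange(k), pad, mode="reflect")  # padded index -> window index
    ops = np.zeros((len(LAWS_MASK_NAMES), k * k, k * k))
    for mi, name in enumerate(LAWS_MASK_NAMES):
        mask = _LAWS_MASKS[name]
        for u in range(k):
            for v in range(k):
                for a in range(k):
                    for b in range(k):
                        r, c = reflect[u + a], reflect[v + b]
                        ops[mi, u * k + v, r * k + c] += mask[a, b]
    return ops


_LAWS_OPS = _laws_operators(5)


def _lem_bulk(flat: np.ndarray) -> np.ndarray:
    """(n, 25) float windows -> (n, 18) LEM features (9 MSS then 9 MAS)."""
    n = flat.shape[0]
    mss = np.empty((n, 9))
    mas = np.empty((n, 9))
    for mi in range(9):
        tex = flat @ _LAWS_OPS[mi].T  # (n, 25) texture responses
        mss[:, mi] = (tex**2).mean(axis=1)
        mas[:, mi] = np.abs(tex).mean(axis=1)
    return np.column_stack([mss, mas])


# ---------------------------------------------------------------------------
# Extended GLRLM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunLengthMatrix:
    """Counts of maximal runs by (gray level, run length) along one direction."""

    counts: np.ndarray  # (ng, max_len)
    theta: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def _scan_lines(q: np.ndarray, theta: int) -> list[np.ndarray]:
    k = q.shape[0]
    if theta == 0:
        return [q[r, :] for r in range(k)]
    if theta == 90:
        return [q[:, c] for c in range(k)]
    if theta == 45:
        return [np.diag(np.fliplr(q), d) for d in range(-(k - 1), k)]
    if theta == 135:
        return [np.diag(q, d) for d in range(-(k - 1), k)]
    raise ParameterError("theta must be one of 0, 45, 90, 135")


def run_length_matrix(window: Window, theta: int = 0, ng: int = 16) -> RunLengthMatrix:
    if window.values.size == 0:
        raise DegenerateInputError("empty window")
    q = quantize(window.values, ng)
    k = window.size
    counts = np.zeros((ng, k), dtype=np.int64)
    for line in _scan_lines(q, theta):
        start = 0
        for pos in range(1, len(line) + 1):
            if pos == len(line) or line[pos] != line[start]:
                counts[line[start], pos - start - 1] += 1
                start = pos
    return RunLengthMatrix(counts, theta=theta, n_pixels=int(q.size))


def compute_glrlm_features(window: Window, theta: int = 0, ng: int = 16) -> dict[str, float]:
    """The 11 extended run-length features.

    Gray-level weights use the 1-based bin index; run lengths are 1-based by
    construction.
    """
    rlm = run_length_matrix(window, theta=theta, ng=ng)
    out = _glrlm_features_bulk(rlm.counts[None, :, :].astype(np.float64), rlm.n_pixels)
    return dict(zip(GLRLM_NAMES, out[0]))


def _glrlm_features_bulk(R: np.ndarray, n_pixels: int) -> np.ndarray:
    """(n, ng, max_len) run counts -> (n, 11) features."""
    n, ng, kmax = R.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]  # 1-based gray level
    j = np.arange(1, kmax + 1, dtype=np.float64)[None, :]  # run length
    nr = R.sum(axis=(1, 2))
    if np.any(nr == 0):
        raise DegenerateInputError("run-length matrix with no runs")

    def w(weight: np.ndarray) -> np.ndarray:
        return (R * weight[None, :, :]).sum(axis=(1, 2)) / nr

    ones = np.ones((ng, kmax))
    sre = w(ones / j**2)
    lre = w(ones * j**2)
    lgre = w(ones / i**2)
    hgre = w(ones * i**2)
    srlge = w(ones / (i**2 * j**2))
    srhge = w(i**2 / j**2)
    lrlge = w(j**2 / i**2)
    lrhge = w(i**2 * j**2)
    gln = (R.sum(axis=2) ** 2).sum(axis=1) / nr
    rln = (R.sum(axis=1) ** 2).sum(axis=1) / nr
    rp = nr / float(n_pixels)
    return np.column_stack([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


# ---------------------------------------------------------------------------
# Local binary pattern
# ---------------------------------------------------------------------------

#: Clockwise circular order starting at the top-left neighbor; bit n carries
#: weight 2**n in acquisition order.
LBP_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


@dataclass(frozen=True)
class LBPNeighborhood:
    """Center gray value plus its 8 neighbors in the documented circular order."""

    center_value: int
    neighbor_values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.neighbor_values) != 8:
            raise ParameterError(
                f"LBP requires exactly 8 neighbors, got {len(self.neighbor_values)}"
            )

    @classmethod
    def from_window(cls, window: Window) -> "LBPNeighborhood":
        if window.size != 3:
            raise ParameterError("LBP neighborhoods come from 3x3 windows")
        v = window.values
        return cls(
            center_value=int(v[1, 1]),
            neighbor_values=tuple(int(v[1 + dr, 1 + dc]) for dr, dc in LBP_OFFSETS),
        )


def compute_lbp_features(neigh: LBPNeighborhood) -> dict[str, float]:
    """Basic LBP code and the rotation-invariant uniform (riu2) code.

    The sign function maps a nonnegative difference to 1 (a flat neighborhood
    therefore codes as 255).  riu2 is the number of 1 bits when the circular
    0/1 transition count U is at most 2, else N + 1 = 9.
    """
    s = np.array(
        [1 if gn - neigh.center_value >= 0 else 0 for gn in neigh.neighbor_values],
        dtype=np.int64,
    )
    basic = int((s * (2 ** np.arange(8))).sum())
    u = int(np.abs(s - np.roll(s, 1)).sum())
    riu2 = int(s.sum()) if u <= 2 else 9
    return {"lbp_basic": float(basic), "lbp_riu2": float(riu2)}


# ---------------------------------------------------------------------------
# Whole-frame extraction
# ---------------------------------------------------------------------------


def compute_feature_vector(
    frame: GrayFrame, center: tuple[int, int], config: TextureConfig = TextureConfig()
) -> dict[str, float]:
    """The full 54-feature vector of a single pixel (per-window route)."""
    win = extract_window(frame, center, config.window)
    out: dict[str, float] = {"intensity": float(frame.pixels[center])}
    out.update(compute_fos(win))
    out.update(
        compute_glcm_features(
            win,
            d=config.glcm_d,
            theta=config.glcm_theta,
            ng=config.ng,
            symmetric=config.glcm_symmetric,
        )
    )
    out.update(compute_lem_features(win))
    out.update(compute_glrlm_features(win, theta=config.glrlm_theta, ng=config.ng))
    lbp_win = extract_window(frame, center, config.lbp_window)
    out.update(compute_lbp_features(LBPNeighborhood.from_window(lbp_win)))
    return {name: out[name] for name in FEATURE_NAMES}


def _glcm_bulk(q_flat: np.ndarray, config: TextureConfig, k: int) -> np.ndarray:
    """(n, k*k) quantized windows -> (n, 17) GLCM features (chunked dense path)."""
    ng = config.ng
    dr, dc = (config.glcm_d * o for o in _GLCM_OFFSETS[config.glcm_theta])
    ref, nb = [], []
    for r in range(k):
        for c in range(k):
            rr, cc = r + dr, c + dc
            if 0 <= rr < k and 0 <= cc < k:
                ref.append(r * k + c)
                nb.append(rr * k + cc)
    ref_idx = np.array(ref)
    nb_idx = np.array(nb)
    if ref_idx.size == 0:
        raise DegenerateInputError("no valid pixel pair at the GLCM offset")

    n = q_flat.shape[0]
    out = np.empty((n, 17))
    chunk = 32768
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        qi = q_flat[lo:hi]
        i_codes = qi[:, ref_idx]
        j_codes = qi[:, nb_idx]
        rows = np.repeat(np.arange(hi - lo), ref_idx.size)
        codes = rows * (ng * ng) + (i_codes * ng + j_codes).ravel()
        counts = np.bincount(codes, minlength=(hi - lo) * ng * ng).astype(np.float64)
        counts = counts.reshape(hi - lo, ng * ng)
        if config.glcm_symmetric:
            counts = counts + counts.reshape(hi - lo, ng, ng).transpose(0, 2, 1).reshape(
                hi - lo, ng * ng
            )
        p = counts / counts.sum(axis=1, keepdims=True)
        out[lo:hi] = _glcm_features_bulk(p, ng)
    return out


def _glrlm_bulk(q: np.ndarray, config: TextureConfig) -> np.ndarray:
    """(n, k, k) quantized windows -> (n, 11) GLRLM features (0/90 degrees)."""
    ng = config.ng
    if config.glrlm_theta == 90:
        q = q.transpose(0, 2, 1)
    n, k, _ = q.shape
    lines = q.reshape(n * k, k)
    starts = np.ones((n * k, k), dtype=bool)
    starts[:, 1:] = lines[:, 1:] != lines[:, :-1]
    run_id = np.cumsum(starts, axis=1) - 1  # id of the run each pixel belongs to
    line_idx = np.arange(n * k)[:, None] * k
    lengths = np.bincount((line_idx + run_id).ravel(), minlength=n * k * k).reshape(n * k, k)
    li, pos = np.nonzero(starts)
    run_len = lengths[li, run_id[li, pos]]
    level = lines[li, pos]
    win = li // k
    codes = win * (ng * k) + level * k + (run_len - 1)
    R = np.bincount(codes, minlength=n * ng * k).astype(np.float64).reshape(n, ng, k)
    return _glrlm_features_bulk(R, k * k)


def _lbp_bulk(frame: GrayFrame, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    padded = np.pad(frame.pixels.astype(np.int64), 1, mode="reflect")
    center = frame.pixels[rows, cols].astype(np.int64)
    s = np.empty((rows.size, 8), dtype=np.int64)
    for bit, (dr, dc) in enumerate(LBP_OFFSETS):
        s[:, bit] = padded[rows + 1 + dr, cols + 1 + dc] - center >= 0
    basic = s @ (2 ** np.arange(8))
    u = np.abs(s - np.roll(s, 1, axis=1)).sum(axis=1)
    riu2 = np.where(u <= 2, s.sum(axis=1), 9)
    return np.column_stack([basic, riu2]).astype(np.float64)


def extract_all(
    frame: GrayFrame,
    mask: PlaqueMask,
    labels: LabelMap | None = None,
    config: TextureConfig = TextureConfig(),
) -> pd.DataFrame:
    """One 54-feature row per plaque pixel (vectorized bulk route).

    Returns a feature table with columns ``row, col, label`` followed by the
    canonical 54 feature names.  The ``label`` column holds tissue names or
    ``None`` when no label map is given.  Deterministic given frame + config.
    """
    if mask.shape != frame.shape:
        raise DimensionError(f"mask shape {mask.shape} != frame shape {frame.shape}")
    if labels is not None and labels.shape != frame.shape:
        raise DimensionError(f"label shape {labels.shape} != frame shape {frame.shape}")
    rows, cols = np.nonzero(mask.flags)
    if rows.size == 0:
        raise DegenerateInputError("plaque mask has no true pixels")

    k = config.window
    pad = k // 2
    padded = np.pad(frame.pixels, pad, mode="reflect")
    wins = np.lib.stride_tricks.sliding_window_view(padded, (k, k))[rows, cols]
    flat = wins.reshape(rows.size, k * k)
    flat_f = flat.astype(np.float64)
    q_flat = quantize(flat, config.ng)

    intensity = frame.pixels[rows, cols].astype(np.float64)
    fos = _fos_bulk(flat_f)
    glcm = _glcm_bulk(q_flat, config, k)
    lem = _lem_bulk(flat_f)
    if config.glrlm_theta in (0, 90):
        glrlm = _glrlm_bulk(q_flat.reshape(-1, k, k), config)
    else:  # diagonal scan lines: per-window fallback
        glrlm = np.array(
            [
                list(
                    compute_glrlm_features(
                        Window(flat[n].reshape(k, k)), theta=config.glrlm_theta, ng=config.ng
                    ).values()
                )
                for n in range(rows.size)
            ]
        )
    lbp = _lbp_bulk(frame, rows, cols)

    data = np.column_stack([intensity, fos, glcm, lem, glrlm, lbp])
    df = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    df.insert(0, "row", rows)
    df.insert(1, "col", cols)
    if labels is not None:
        df.insert(2, "label", pd.Series(labels.names()[rows, cols], dtype=object))
    else:
        df.insert(2, "label", pd.Series([None] * rows.size, dtype=object))
    return df
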