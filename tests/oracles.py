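"""Independent brute-force oracles for the texture features and metrics.

Everything here is written as literal formula evaluation — nested loops,
dict accumulation, explicit sorting — deliberately avoiding the vectorized
routes used by the package, so agreement is evidence of correctness rather
than of shared code.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# First-order statistics: literal population moments
# ---------------------------------------------------------------------------


def fos_oracle(window: np.ndarray) -> dict[str, float]:
    vals = [float(v) for row in window for v in row]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    std = math.sqrt(var)
    if var == 0:
        kurt = skew = 0.0
    else:
        kurt = sum(((v - mean) / std) ** 4 for v in vals) / n - 3.0
        skew = sum(((v - mean) / std) ** 3 for v in vals) / n
    return {
        "fos_mean": mean,
        "fos_variance": var,
        "fos_std": std,
        "fos_kurtosis": kurt,
        "fos_skewness": skew,
    }


# ---------------------------------------------------------------------------
# GLCM: exhaustive pair enumeration + literal Haralick formulas
# ---------------------------------------------------------------------------

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize_oracle(v: int, ng: int) -> int:
    return min((int(v) * ng) // 256, ng - 1)


def glcm_oracle(
    window: np.ndarray, d: int = 1, theta: int = 135, ng: int = 16, symmetric: bool = False
) -> dict[str, float]:
    k = window.shape[0]
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    counts: dict[tuple[int, int], int] = {}
    for r in range(k):
        for c in range(k):
            rr, cc = r + dr, c + dc
            if 0 <= rr < k and 0 <= cc < k:
                i = quantize_oracle(window[r, c], ng)
                j = quantize_oracle(window[rr, cc], ng)
                counts[(i, j)] = counts.get((i, j), 0) + 1
                if symmetric:
                    counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    p = {ij: c / total for ij, c in counts.items()}

    # 1-based indices in every weighting formula
    def P(i, j):
        return p.get((i - 1, j - 1), 0.0)

    lv = range(1, ng + 1)
    px = {i: sum(P(i, j) for j in lv) for i in lv}
    py = {j: sum(P(i, j) for i in lv) for j in lv}
    mu_x = sum(i * px[i] for i in lv)
    mu_y = sum(j * py[j] for j in lv)

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    autocorrelation = sum(i * j * P(i, j) for i in lv for j in lv)
    contrast = sum((i - j) ** 2 * P(i, j) for i in lv for j in lv)
    cluster_prom = sum((i + j - mu_x - mu_y) ** 4 * P(i, j) for i in lv for j in lv)
    cluster_shade = sum((i + j - mu_x - mu_y) ** 3 * P(i, j) for i in lv for j in lv)
    dissimilarity = sum(abs(i - j) * P(i, j) for i in lv for j in lv)
    energy = sum(P(i, j) ** 2 for i in lv for j in lv)
    entropy = -sum(xlogx(P(i, j)) for i in lv for j in lv)
    homogeneity = sum(P(i, j) / (1 + (i - j) ** 2) for i in lv for j in lv)
    max_prob = max(p.values())
    variance = sum((i - mu_x) ** 2 * P(i, j) for i in lv for j in lv)

    p_sum = {k2: 0.0 for k2 in range(2, 2 * ng + 1)}
    p_diff = {k2: 0.0 for k2 in range(ng)}
    for i in lv:
        for j in lv:
            p_sum[i + j] += P(i, j)
            p_diff[abs(i - j)] += P(i, j)
    sum_average = sum(k2 * v for k2, v in p_sum.items())
    sum_variance = sum((k2 - sum_average) ** 2 * v for k2, v in p_sum.items())
    sum_entropy = -sum(xlogx(v) for v in p_sum.values())
    diff_mean = sum(k2 * v for k2, v in p_diff.items())
    diff_variance = sum((k2 - diff_mean) ** 2 * v for k2, v in p_diff.items())
    diff_entropy = -sum(xlogx(v) for v in p_diff.values())

    hx = -sum(xlogx(v) for v in px.values())
    hy = -sum(xlogx(v) for v in py.values())
    hxy1 = -sum(
        P(i, j) * math.log(px[i] * py[j]) if px[i] * py[j] > 0 and P(i, j) > 0 else 0.0
        for i in lv
        for j in lv
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    idmn = sum(P(i, j) / (1 + (i - j) ** 2 / ng**2) for i in lv for j in lv)

    return {
        "glcm_autocorrelation": autocorrelation,
        "glcm_contrast": contrast,
        "glcm_cluster_prominence": cluster_prom,
        "glcm_cluster_shade": cluster_shade,
        "glcm_dissimilarity": dissimilarity,
        "glcm_energy": energy,
        "glcm_entropy": entropy,
        "glcm_homogeneity": homogeneity,
        "glcm_maximum_probability": max_prob,
        "glcm_variance": variance,
        "glcm_sum_average": sum_average,
        "glcm_sum_variance": sum_variance,
        "glcm_sum_entropy": sum_entropy,
        "glcm_difference_variance": diff_variance,
        "glcm_difference_entropy": diff_entropy,
        "glcm_imc1": imc1,
        "glcm_idmn": idmn,
    }


# ---------------------------------------------------------------------------
# Laws energy: manual reflect padding + nested-loop convolution
# ---------------------------------------------------------------------------

_LAWS = {
    "l5": [1.0, 4.0, 6.0, 4.0, 1.0],
    "e5": [-1.0, -2.0, 0.0, 2.0, 1.0],
    "s5": [-1.0, 0.0, 2.0, 0.0, -1.0],
    "r5": [1.0, -4.0, 6.0, -4.0, 1.0],
}
LAWS_PAIRS = ("e5l5", "s5l5", "r5l5", "e5e5", "s5e5", "r5e5", "s5s5", "r5s5", "r5r5")


def _reflect_index(t: int, k: int) -> int:
    # mirror without repeating the edge sample: ... 2 1 0 1 2 3 4 3 2 ...
    period = 2 * (k - 1)
    t = abs(t) % period
    return t if t < k else period - t


def lem_oracle(window: np.ndarray) -> dict[str, float]:
    k = window.shape[0]
    out = {}
    for name in LAWS_PAIRS:
        a, b = _LAWS[name[:2]], _LAWS[name[2:]]
        mask = [[a[r] * b[c] for c in range(5)] for r in range(5)]
        if name[:2] != name[2:]:
            mask = [[(mask[r][c] + mask[c][r]) / 2.0 for c in range(5)] for r in range(5)]
        sq = ab = 0.0
        for u in range(k):
            for v in range(k):
                resp = 0.0
                for ar in range(5):
                    for bc in range(5):
                        r = _reflect_index(u + ar - 2, k)
                        c = _reflect_index(v + bc - 2, k)
                        resp += mask[ar][bc] * float(window[r, c])
                sq += resp * resp
                ab += abs(resp)
        out[f"lem_mss_{name}"] = sq / (k * k)
        out[f"lem_mas_{name}"] = ab / (k * k)
    return out


# ---------------------------------------------------------------------------
# GLRLM: scan-line run extraction + literal formulas
# ---------------------------------------------------------------------------


def glrlm_oracle(window: np.ndarray, theta: int = 0, ng: int = 16) -> dict[str, float]:
    k = window.shape[0]
    q = [[quantize_oracle(window[r, c], ng) for c in range(k)] for r in range(k)]
    if theta == 0:
        lines = [q[r] for r in range(k)]
    elif theta == 90:
        lines = [[q[r][c] for r in range(k)] for c in range(k)]
    elif theta == 45:
        lines = [
            [q[r][c] for r in range(k - 1, -1, -1) for c in range(k) if r + c == s]
            for s in range(2 * k - 1)
        ]
    elif theta == 135:
        lines = [
            [q[r][c] for r in range(k) for c in range(k) if c - r == d]
            for d in range(-(k - 1), k)
        ]
    runs: list[tuple[int, int]] = []  # (gray level 0-based, run length)
    for line in lines:
        idx = 0
        while idx < len(line):
            j = idx
            while j < len(line) and line[j] == line[idx]:
                j += 1
            runs.append((line[idx], j - idx))
            idx = j
    nr = len(runs)
    npix = k * k

    def total(f):
        return sum(f(g + 1, length) for g, length in runs)  # 1-based gray index

    sre = total(lambda i, j: 1.0 / j**2) / nr
    lre = total(lambda i, j: float(j**2)) / nr
    lgre = total(lambda i, j: 1.0 / i**2) / nr
    hgre = total(lambda i, j: float(i**2)) / nr
    srlge = total(lambda i, j: 1.0 / (i**2 * j**2)) / nr
    srhge = total(lambda i, j: i**2 / j**2) / nr
    lrlge = total(lambda i, j: j**2 / i**2) / nr
    lrhge = total(lambda i, j: float(i**2 * j**2)) / nr
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for g, length in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[length] = by_length.get(length, 0) + 1
    gln = sum(v**2 for v in by_level.values()) / nr
    rln = sum(v**2 for v in by_length.values()) / nr
    rp = nr / npix
    return {
        "glrlm_sre": sre,
        "glrlm_lre": lre,
        "glrlm_gln": gln,
        "glrlm_rln": rln,
        "glrlm_rp": rp,
        "glrlm_lgre": lgre,
        "glrlm_hgre": hgre,
        "glrlm_srlge": srlge,
        "glrlm_srhge": srhge,
        "glrlm_lrlge": lrlge,
        "glrlm_lrhge": lrhge,
    }


# ---------------------------------------------------------------------------
# LBP: bit-by-bit evaluation
# ---------------------------------------------------------------------------


def lbp_oracle(center: int, neighbors: list[int]) -> dict[str, float]:
    bits = [1 if gn - center >= 0 else 0 for gn in neighbors]
    basic = sum(b * 2**n for n, b in enumerate(bits))
    u = abs(bits[-1] - bits[0]) + sum(abs(bits[n] - bits[n - 1]) for n in range(1, 8))
    riu2 = sum(bits) if u <= 2 else 9
    return {"lbp_basic": float(basic), "lbp_riu2": float(riu2)}


# ---------------------------------------------------------------------------
# PCA scores via an independent route (SVD of the standardized data)
# ---------------------------------------------------------------------------


def pca_scores_oracle(X: np.ndarray, variance_target: float) -> tuple[np.ndarray, int]:
    """Max-|loading| score per column over the retained components."""
    n = X.shape[0]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = svals**2 / n
    evar = eigvals / eigvals.sum()
    cum = np.cumsum(evar)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(m, len(eigvals))
    loadings = vt[:m].T * np.sqrt(eigvals[:m])[None, :]
    return np.abs(loadings).max(axis=1), m


# ---------------------------------------------------------------------------
# AUC as tie-adjusted pairwise concordance; percentile by sort + ceil
# ---------------------------------------------------------------------------


def auc_concordance_oracle(scores: np.ndarray, truth: np.ndarray) -> float:
    pos = [float(s) for s, t in zip(scores, truth) if t]
    neg = [float(s) for s, t in zip(scores, truth) if not t]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def percentile_oracle(values: list[float], pct: float) -> float:
    ordered = sorted(values)
    rank = math.ceil(pct / 100.0 * len(ordered))
    return ordered[max(rank, 1) - 1]
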