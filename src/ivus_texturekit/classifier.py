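"""Intensity-routed multi-level tissue classifier.

Four steps per pixel:

1. Pixels brighter than the FT-intensity threshold (the maximum gray value
   over training fibrous-tissue pixels, optionally a lower percentile) are
   routed directly to net 3 — only necrotic core and dense calcium exceed
   fibrous tissue in brightness.
2. Net 1 splits the remaining low-intensity pixels into the FT/FFT and
   NC/DC groups.
3. Net 2 resolves the FT/FFT group into FT or FFT.
4. Net 3 resolves the NC/DC group (plus the bypassed high-intensity pixels)
   into NC or DC.

Each net is a random forest (100 trees, depth 10, fixed seed) trained on its
own PCA-selected, standardized feature subset.  Training pools follow tissue
identity, not cascaded routing: net 2 sees all FT/FFT-labeled pixels and
net 3 all NC/DC-labeled pixels.  Positive classes are the NC/DC group for
net 1, FFT for net 2 and DC for net 3; scores are the forests'
positive-class probabilities (tree-averaged vote fractions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ClassCoverageError, DegenerateInputError, ParameterError, SchemaError
from .pipeline_io import GrayFrame, LabelMap, LABEL_CODES, save_json, load_json
from .selection import SelectionResult, apply_selection

NET_POSITIVE = {1: "NCDC", 2: "FFT", 3: "DC"}
ROUTE_LOW_NET2 = "low->net1->net2"
ROUTE_LOW_NET3 = "low->net1->net3"
ROUTE_HIGH_NET3 = "high->net3"


@dataclass(frozen=True)
class RFParams:
    """Random-forest settings: 100 trees of depth at most 10, seeded."""

    n_trees: int = 100
    max_depth: int = 10
    seed: int = 0

    def build(self, net_id: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            random_state=self.seed + net_id,
            n_jobs=1,
        )


@dataclass
class MultiLevelModel:
    threshold: float
    nets: dict[int, RandomForestClassifier]
    selections: dict[int, SelectionResult]
    rf_params: RFParams
    net_positive: dict[int, str] = field(default_factory=lambda: dict(NET_POSITIVE))

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ParameterError(f"threshold {self.threshold} outside [0, 255]")


@dataclass
class RoutedPrediction:
    """Per-pixel final labels, route tags, and per-net positive-class scores."""

    labels: np.ndarray  # object array over {FT, FFT, NC, DC}
    routes: np.ndarray  # object array over the three route tags
    score_net1: np.ndarray  # NaN where a net did not see the pixel
    score_net2: np.ndarray
    score_net3: np.ndarray

    def to_frame(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": matrix["row"].to_numpy(),
                "col": matrix["col"].to_numpy(),
                "label": self.labels,
                "route": self.routes,
                "score_net1": self.score_net1,
                "score_net2": self.score_net2,
                "score_net3": self.score_net3,
            }
        )


def compute_intensity_threshold(
    labels: LabelMap, frame: GrayFrame, percentile: float = 100.0
) -> float:
    """Threshold = the given percentile of gray values over FT pixels.

    The default (100) is the FT maximum.  Percentiles use the nearest-rank
    definition, so the threshold is always an observed FT intensity.
    """
    ft = frame.pixels[labels.labels == LABEL_CODES["FT"]]
    return _threshold_from_values(ft.astype(np.float64), percentile)


def _threshold_from_values(values: np.ndarray, percentile: float) -> float:
    if values.size == 0:
        raise DegenerateInputError("no FT pixels to derive the intensity threshold")
    if not 0 < percentile <= 100:
        raise ParameterError("percentile must be in (0, 100]")
    return float(np.percentile(values, percentile, method="inverted_cdf"))


def route(threshold: float, intensity: float | np.ndarray) -> np.ndarray | str:
    """'high' iff intensity strictly exceeds the threshold, else 'low'.

    The boundary goes low: the FT maximum itself must stay on the FT side.
    """
    arr = np.asarray(intensity)
    out = np.where(arr > threshold, "high", "low")
    return out if arr.ndim else str(out)


def _binary_pool(
    matrix: pd.DataFrame, mask: np.ndarray, positive: np.ndarray, net_id: int
) -> tuple[pd.DataFrame, np.ndarray]:
    pool = matrix.loc[mask]
    y = positive[mask]
    if y.size == 0 or y.all() or not y.any():
        raise ClassCoverageError(f"net {net_id} training pool lacks one of its two classes")
    return pool, y


def train(
    matrix: pd.DataFrame,
    selections: dict[int, SelectionResult],
    rf_params: RFParams = RFParams(),
    threshold_percentile: float = 100.0,
    max_train_pixels_per_net: int | None = None,
) -> MultiLevelModel:
    """Fit the threshold and the three nets from a labeled feature table.

    ``max_train_pixels_per_net`` caps each net's pool by seeded random
    subsampling (seed derived from ``rf_params.seed``); ``None`` uses every
    labeled pixel.
    """
    labels = matrix["label"].to_numpy(dtype=object)
    present = set(labels)
    missing = {"FT", "FFT", "NC", "DC"} - present
    if missing:
        raise ClassCoverageError(f"training labels missing classes: {sorted(missing)}")

    intensity = matrix["intensity"].to_numpy(dtype=np.float64)
    threshold = _threshold_from_values(intensity[labels == "FT"], threshold_percentile)

    in_ncdc = np.isin(labels, ("NC", "DC"))
    pools = {
        1: _binary_pool(matrix, intensity <= threshold, in_ncdc, 1),
        2: _binary_pool(matrix, np.isin(labels, ("FT", "FFT")), labels == "FFT", 2),
        3: _binary_pool(matrix, in_ncdc, labels == "DC", 3),
    }

    rng = np.random.default_rng(rf_params.seed)
    nets: dict[int, RandomForestClassifier] = {}
    for net_id, (pool, y) in pools.items():
        if max_train_pixels_per_net is not None and len(pool) > max_train_pixels_per_net:
            keep = rng.choice(len(pool), size=max_train_pixels_per_net, replace=False)
            keep.sort()
            pool, y = pool.iloc[keep], y[keep]
            if y.all() or not y.any():
                raise ClassCoverageError(
                    f"net {net_id} subsampled pool lacks one of its two classes"
                )
        sel = selections[net_id]
        X = sel.standardize(apply_selection(pool, sel))
        net = rf_params.build(net_id)
        net.fit(X, y.astype(np.int64))
        nets[net_id] = net
    return MultiLevelModel(
        threshold=threshold, nets=nets, selections=selections, rf_params=rf_params
    )


def _positive_proba(net: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = net.predict_proba(X)
    pos_col = int(np.nonzero(net.classes_ == 1)[0][0])
    return proba[:, pos_col]


def predict(model: MultiLevelModel, matrix: pd.DataFrame) -> RoutedPrediction:
    """Route every pixel through the cascade and emit labels, tags, scores."""
    for sel in model.selections.values():
        missing = [f for f in sel.selected if f not in matrix.columns]
        if missing:
            raise SchemaError(f"matrix missing features required by net {sel.net_id}: {missing}")
    n = len(matrix)
    intensity = matrix["intensity"].to_numpy(dtype=np.float64)
    high = intensity > model.threshold

    labels_out = np.empty(n, dtype=object)
    routes = np.empty(n, dtype=object)
    s1 = np.full(n, np.nan)
    s2 = np.full(n, np.nan)
    s3 = np.full(n, np.nan)

    def scores_for(net_id: int, idx: np.ndarray) -> np.ndarray:
        sel = model.selections[net_id]
        X = sel.standardize(apply_selection(matrix.iloc[idx], sel))
        return _positive_proba(model.nets[net_id], X)

    low_idx = np.nonzero(~high)[0]
    to_net3_high = np.nonzero(high)[0]
    if low_idx.size:
        s1[low_idx] = scores_for(1, low_idx)
    to_ncdc = low_idx[s1[low_idx] >= 0.5] if low_idx.size else low_idx
    to_ftfft = low_idx[s1[low_idx] < 0.5] if low_idx.size else low_idx

    if to_ftfft.size:
        s2[to_ftfft] = scores_for(2, to_ftfft)
        labels_out[to_ftfft] = np.where(s2[to_ftfft] >= 0.5, "FFT", "FT")
        routes[to_ftfft] = ROUTE_LOW_NET2
    net3_idx = np.concatenate([to_ncdc, to_net3_high])
    if net3_idx.size:
        s3[net3_idx] = scores_for(3, net3_idx)
        labels_out[net3_idx] = np.where(s3[net3_idx] >= 0.5, "DC", "NC")
    routes[to_ncdc] = ROUTE_LOW_NET3
    routes[to_net3_high] = ROUTE_HIGH_NET3

    return RoutedPrediction(
        labels=labels_out, routes=routes, score_net1=s1, score_net2=s2, score_net3=s3
    )


# ---------------------------------------------------------------------------
# Model persistence: JSON metadata + joblib-serialized forests
# ---------------------------------------------------------------------------


def save_model(model: MultiLevelModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "threshold": model.threshold,
        "rf_params": {
            "n_trees": model.rf_params.n_trees,
            "max_depth": model.rf_params.max_depth,
            "seed": model.rf_params.seed,
        },
        "net_positive": {str(k): v for k, v in model.net_positive.items()},
        "selections": {str(k): sel.to_dict() for k, sel in model.selections.items()},
        "rf_defaults": {  # recorded for reproducibility of unstated RF details
            "criterion": model.nets[1].criterion,
            "max_features": str(model.nets[1].max_features),
            "bootstrap": model.nets[1].bootstrap,
        },
    }
    save_json(meta, directory / "model.json")
    for net_id, net in model.nets.items():
        joblib.dump(net, directory / f"net{net_id}.joblib")


def load_model(directory: str | Path) -> MultiLevelModel:
    directory = Path(directory)
    meta = load_json(directory / "model.json")
    rf = RFParams(**meta["rf_params"])
    selections = {int(k): SelectionResult.from_dict(v) for k, v in meta["selections"].items()}
    nets = {net_id: joblib.load(directory / f"net{net_id}.joblib") for net_id in (1, 2, 3)}
    return MultiLevelModel(
        threshold=float(meta["threshold"]),
        nets=nets,
        selections=selections,
        rf_params=rf,
        net_positive={int(k): v for k, v in meta["net_positive"].items()},
    )
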