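"""Per-net and overall performance metrics.

Sensitivity = TP / (TP + FN), specificity = TN / (TN + FP) and accuracy =
(TP + TN) / total are reported as percentages.  ROC curves sweep every
distinct observed score (tree-vote fractions have granularity 1/n_trees)
and AUC is the trapezoid area, which equals the tie-adjusted probability
that a random positive outscores a random negative.

Per-net evaluation pools follow ground-truth tissue membership by default
(net 1: low-intensity pixels with group truth; net 2: FT/FFT pixels;
net 3: NC/DC pixels).  High-intensity pixels whose true tissue is FT or FFT
are structurally forced toward net 3 by the cascade but carry no defined
NC-vs-DC truth; they are excluded from net-3 binary metrics and reported as
``n_foreign_high``.  A routed-pool mode evaluates each net on the pixels the
cascade actually sent to it instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classifier import (
    MultiLevelModel,
    RFParams,
    RoutedPrediction,
    ROUTE_HIGH_NET3,
    ROUTE_LOW_NET3,
    _positive_proba,
    predict,
)
from .errors import UndefinedRateError
from .pipeline_io import CLASSES
from .selection import apply_selection


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, pred_pos: np.ndarray, truth_pos: np.ndarray) -> "ConfusionCounts":
        pred_pos = np.asarray(pred_pos, dtype=bool)
        truth_pos = np.asarray(truth_pos, dtype=bool)
        return cls(
            tp=int((pred_pos & truth_pos).sum()),
            tn=int((~pred_pos & ~truth_pos).sum()),
            fp=int((pred_pos & ~truth_pos).sum()),
            fn=int((~pred_pos & truth_pos).sum()),
        )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent."""
    if c.tp + c.fn == 0:
        raise UndefinedRateError("sensitivity undefined: no positive pixels")
    if c.tn + c.fp == 0:
        raise UndefinedRateError("specificity undefined: no negative pixels")
    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    acc = 100.0 * (c.tp + c.tn) / c.total
    return sens, spec, acc


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points (1-specificity, sensitivity) and trapezoid AUC."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if truth.all() or not truth.any():
        raise UndefinedRateError("ROC undefined: single-class truth")
    fpr, tpr, _ = roc_curve(truth.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class NetReport:
    net_id: int
    positive: str
    confusion: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    roc: list[tuple[float, float]]
    n_pixels: int
    n_foreign_high: int = 0  # high-intensity FT/FFT-truth pixels (net 3 only)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d


@dataclass
class EvalReport:
    nets: dict[int, NetReport]
    confusion_4class: dict[str, dict[str, int]]  # truth -> predicted -> count
    overall_accuracy: float  # percent
    n_pixels: int
    threshold: float
    pool_mode: str

    def to_dict(self) -> dict:
        return {
            "nets": {str(k): v.to_dict() for k, v in self.nets.items()},
            "confusion_4class": self.confusion_4class,
            "overall_accuracy": self.overall_accuracy,
            "n_pixels": self.n_pixels,
            "threshold": self.threshold,
            "pool_mode": self.pool_mode,
        }


def _net_report(
    net_id: int,
    positive: str,
    scores: np.ndarray,
    truth_pos: np.ndarray,
    n_foreign_high: int = 0,
) -> NetReport:
    conf = ConfusionCounts.from_predictions(scores >= 0.5, truth_pos)
    sens, spec, acc = metrics(conf)
    roc, auc = roc_auc(scores, truth_pos)
    return NetReport(
        net_id=net_id,
        positive=positive,
        confusion=conf,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        roc=roc,
        n_pixels=int(truth_pos.size),
        n_foreign_high=n_foreign_high,
    )


def evaluate_net(model: MultiLevelModel, matrix: pd.DataFrame, net_id: int) -> NetReport:
    """Metrics for a single net on its ground-truth pool.

    Unlike :func:`evaluate_model` this does not require every net's pool to
    be two-class — useful when a regime stresses one net only (e.g. the
    FT/FFT-overlap phantom, where no bright-class pixel may fall below the
    routing threshold and net 1's pool degenerates).
    """
    labels = matrix["label"].to_numpy(dtype=object)
    intensity = matrix["intensity"].to_numpy(dtype=np.float64)
    pools = {
        1: intensity <= model.threshold,
        2: np.isin(labels, ("FT", "FFT")),
        3: np.isin(labels, ("NC", "DC")),
    }
    truth_pos_all = {1: np.isin(labels, ("NC", "DC")), 2: labels == "FFT", 3: labels == "DC"}
    idx = np.nonzero(pools[net_id])[0]
    truth_pos = truth_pos_all[net_id][idx]
    if idx.size == 0 or truth_pos.all() or not truth_pos.any():
        raise UndefinedRateError(f"net {net_id} evaluation pool lacks one of its classes")
    sel = model.selections[net_id]
    scores = _positive_proba(
        model.nets[net_id], sel.standardize(apply_selection(matrix.iloc[idx], sel))
    )
    return _net_report(net_id, model.net_positive[net_id], scores, truth_pos)


def evaluate_model(
    model: MultiLevelModel, matrix: pd.DataFrame, routed_pools: bool = False
) -> EvalReport:
    """Table-style report: per-net confusion/rates/ROC plus the overall
    4-class confusion from routed predictions."""
    labels = matrix["label"].to_numpy(dtype=object)
    if any(l not in CLASSES for l in labels):
        raise UndefinedRateError("evaluation requires a fully labeled feature table")
    intensity = matrix["intensity"].to_numpy(dtype=np.float64)
    low = intensity <= model.threshold
    in_ncdc = np.isin(labels, ("NC", "DC"))
    in_ftfft = ~in_ncdc

    routed = predict(model, matrix)

    def net_scores(net_id: int, idx: np.ndarray) -> np.ndarray:
        sel = model.selections[net_id]
        X = sel.standardize(apply_selection(matrix.iloc[idx], sel))
        return _positive_proba(model.nets[net_id], X)

    if routed_pools:
        pools = {
            1: np.nonzero(low)[0],
            2: np.nonzero(routed.routes == "low->net1->net2")[0],
            3: np.nonzero(np.isin(routed.routes, (ROUTE_LOW_NET3, ROUTE_HIGH_NET3)))[0],
        }
        pools = {k: v[np.isin(labels[v], ("FT", "FFT") if k == 2 else CLASSES)] for k, v in pools.items()}
        # nets 2/3 routed pools may contain foreign-truth pixels; restrict to
        # pixels whose truth defines the binary task
        pools[2] = pools[2][in_ftfft[pools[2]]]
        pools[3] = pools[3][in_ncdc[pools[3]]]
        mode = "routed"
    else:
        pools = {
            1: np.nonzero(low)[0],
            2: np.nonzero(in_ftfft)[0],
            3: np.nonzero(in_ncdc)[0],
        }
        mode = "ground-truth"
    n_foreign_high = int((~low & in_ftfft).sum())

    nets: dict[int, NetReport] = {}
    truth_pos_by_net = {1: in_ncdc, 2: labels == "FFT", 3: labels == "DC"}
    for net_id, idx in pools.items():
        truth_pos = truth_pos_by_net[net_id][idx]
        if idx.size == 0 or truth_pos.all() or not truth_pos.any():
            raise UndefinedRateError(f"net {net_id} evaluation pool lacks one of its classes")
        nets[net_id] = _net_report(
            net_id,
            model.net_positive[net_id],
            net_scores(net_id, idx),
            truth_pos,
            n_foreign_high=n_foreign_high if net_id == 3 else 0,
        )

    confusion = {t: {p: 0 for p in CLASSES} for t in CLASSES}
    for t, p in zip(labels, routed.labels):
        confusion[t][p] += 1
    overall = 100.0 * float((labels == routed.labels).mean())

    return EvalReport(
        nets=nets,
        confusion_4class=confusion,
        overall_accuracy=overall,
        n_pixels=len(matrix),
        threshold=model.threshold,
        pool_mode=mode,
    )


def baseline_intensity_accuracy(
    train_matrix: pd.DataFrame,
    test_matrix: pd.DataFrame,
    classes: tuple[str, str] = ("FT", "FFT"),
    rf_params: RFParams = RFParams(),
) -> float:
    """Accuracy (percent) of a forest trained on the intensity column alone.

    Reference point for showing that windowed texture features carry signal
    beyond raw brightness on the FT-vs-FFT task.
    """
    neg, pos = classes
    tr = train_matrix[train_matrix["label"].isin(classes)]
    te = test_matrix[test_matrix["label"].isin(classes)]
    if tr.empty or te.empty:
        raise UndefinedRateError("baseline needs both classes in train and test")
    net = rf_params.build(0)
    net.fit(tr[["intensity"]].to_numpy(), (tr["label"] == pos).to_numpy(dtype=np.int64))
    pred = net.predict(te[["intensity"]].to_numpy()).astype(bool)
    truth = (te["label"] == pos).to_numpy(dtype=bool)
    return 100.0 * float((pred == truth).mean())
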