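"""PCA-based selection of original texture features.

Plain PCA yields linear combinations, not named features; here the retained
principal components are mapped back to the original 54 features through
their loadings.  Columns are z-scored, the correlation matrix is
eigendecomposed, the fewest components reaching the cumulative
explained-variance target are retained, and each original feature is scored
by its maximum absolute loading (eigenvector entry scaled by the component's
singular value) over the retained components.  The selection is either the
top-k features by score or, when k is not given, all features whose score
exceeds a quantile of the score distribution.

Zero-variance columns are excluded from standardization (no division by
zero) and can never be selected.  A fixed eigenvector sign convention makes
the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, SchemaError
from .features import FEATURE_NAMES


@dataclass(frozen=True)
class SelectionResult:
    """Per-net feature subset with the standardization used to derive it."""

    net_id: int
    selected: tuple[str, ...]
    scores: dict[str, float]
    explained_variance: tuple[float, ...]
    center: dict[str, float]
    scale: dict[str, float]
    n_components: int

    def __post_init__(self) -> None:
        unknown = [f for f in self.selected if f not in FEATURE_NAMES]
        if unknown:
            raise SchemaError(f"selection names unknown features: {unknown}")
        if len(set(self.selected)) != len(self.selected):
            raise SchemaError("selection contains duplicate features")

    def standardize(self, subset: pd.DataFrame) -> np.ndarray:
        """Apply the stored (center, scale) to a column-subset table."""
        c = np.array([self.center[f] for f in self.selected])
        s = np.array([self.scale[f] for f in self.selected])
        return (subset[list(self.selected)].to_numpy(dtype=np.float64) - c) / s

    def to_dict(self) -> dict:
        return {
            "net_id": self.net_id,
            "selected": list(self.selected),
            "scores": self.scores,
            "explained_variance": list(self.explained_variance),
            "center": self.center,
            "scale": self.scale,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            net_id=int(d["net_id"]),
            selected=tuple(d["selected"]),
            scores={k: float(v) for k, v in d["scores"].items()},
            explained_variance=tuple(float(v) for v in d["explained_variance"]),
            center={k: float(v) for k, v in d["center"].items()},
            scale={k: float(v) for k, v in d["scale"].items()},
            n_components=int(d["n_components"]),
        )


def fit_pca_selector(
    matrix: pd.DataFrame,
    variance_target: float = 0.95,
    k: int | None = None,
    score_quantile: float = 0.5,
    net_id: int = 0,
    always_include: tuple[str, ...] = (),
) -> SelectionResult:
    """Rank the 54 features by PCA loadings and pick a subset.

    Parameters
    ----------
    matrix
        Feature table containing the canonical feature columns (>= 2 rows).
    variance_target
        Retain the fewest principal components whose cumulative explained
        variance reaches this fraction.
    k
        Select the top-k features by score.  When ``None``, select all
        features whose score strictly exceeds the ``score_quantile`` quantile
        of the scores.
    always_include
        Features selected regardless of rank (they count toward k).  Raw
        intensity belongs here for the leaf nets: it drives the routing
        stage, but under multiplicative speckle it is so collinear with the
        window-statistics block that no unsupervised loading rule reliably
        surfaces it on its own.
    """
    unknown = [f for f in always_include if f not in FEATURE_NAMES]
    if unknown:
        raise SchemaError(f"always_include names unknown features: {unknown}")
    if k is not None and (k < 1 or k > len(FEATURE_NAMES)):
        raise ParameterError(f"k must be in [1, {len(FEATURE_NAMES)}], got {k}")
    if k is not None and k < len(always_include):
        raise ParameterError(f"k={k} smaller than the {len(always_include)} forced features")
    X = matrix[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError("PCA selection needs at least 2 rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population std
    active = std > 0
    n_active = int(active.sum())
    if n_active < 2:
        raise DegenerateInputError("fewer than 2 non-constant feature columns")
    if k is not None and k > n_active:
        raise ParameterError(f"k={k} exceeds the {n_active} non-constant features")

    Z = (X[:, active] - mean[active]) / std[active]
    corr = (Z.T @ Z) / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # Sign convention: the entry of largest magnitude in each eigenvector is
    # made positive (earliest such entry on ties).
    for c in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, c]))
        if eigvecs[pivot, c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]

    total = eigvals.sum()
    evar = eigvals / total if total > 0 else eigvals
    cum = np.cumsum(evar)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(m, len(eigvals))

    loadings = eigvecs[:, :m] * np.sqrt(eigvals[:m])[None, :]
    active_scores = np.abs(loadings).max(axis=1)

    scores = np.zeros(len(FEATURE_NAMES))
    scores[active] = active_scores
    score_by_name = {f: float(scores[i]) for i, f in enumerate(FEATURE_NAMES)}

    active_idx = np.nonzero(active)[0]
    forced = {FEATURE_NAMES.index(f) for f in always_include}
    # Stable ranking: descending score, canonical order breaking ties
    # (scores within 1e-12 are treated as tied).
    rounded = np.round(active_scores / 1e-12) * 1e-12
    rank = sorted(range(n_active), key=lambda i: (-rounded[i], i))
    rank = [i for i in rank if active_idx[i] not in forced]
    if k is not None:
        chosen = set(forced) | {active_idx[i] for i in rank[: k - len(forced)]}
    else:
        cutoff = float(np.quantile(active_scores, score_quantile))
        chosen = set(forced) | {active_idx[i] for i in rank if active_scores[i] > cutoff}
        if not chosen:  # all scores tied at the cutoff: keep the top one
            chosen = {active_idx[rank[0]]}
    selected = tuple(f for i, f in enumerate(FEATURE_NAMES) if i in chosen)

    # a forced constant column gets unit scale so standardization stays finite
    return SelectionResult(
        net_id=net_id,
        selected=selected,
        scores=score_by_name,
        explained_variance=tuple(float(v) for v in evar),
        center={f: float(mean[i]) for i, f in enumerate(FEATURE_NAMES) if i in chosen},
        scale={
            f: float(std[i]) if std[i] > 0 else 1.0
            for i, f in enumerate(FEATURE_NAMES)
            if i in chosen
        },
        n_components=m,
    )


def apply_selection(matrix: pd.DataFrame, sel: SelectionResult) -> pd.DataFrame:
    """Column-subset of ``matrix`` in the selection's order (raw values).

    Use :meth:`SelectionResult.standardize` on the result to reuse the
    training-time standardization at prediction time.
    """
    missing = [f for f in sel.selected if f not in matrix.columns]
    if missing:
        raise SchemaError(f"matrix missing selected columns: {missing}")
    return matrix[list(sel.selected)].copy()
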