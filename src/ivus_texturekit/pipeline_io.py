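"""Reading and writing the pipeline's standard artifacts.

Conventions
-----------
* Grayscale IVUS frames: single-channel 8-bit PNG or TIFF.
* Plaque masks and tissue label maps: indexed 8-bit PNG with the palette
  0 = NONE (outside plaque), 1 = FT, 2 = FFT, 3 = NC, 4 = DC.  Masks may
  alternatively use 0/255 (a common binary-mask convention); any other value
  is rejected.
* Feature tables: CSV with header ``row,col,label,<54 canonical feature
  names>``.  Coordinates are row-major, 0-based ``(row, col)``.
* Reports and selection results: JSON.

Frames whose values fall outside [0, 255] are rejected, never clipped:
raw intensity is itself a classification feature, so silent coercion would
corrupt the threshold stage downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, LabelPaletteError, SchemaError

#: Tissue classes, in palette-index order (index 0 is NONE).
CLASSES: tuple[str, ...] = ("FT", "FFT", "NC", "DC")

#: Palette for indexed label PNGs.
LABEL_PALETTE: dict[int, str] = {0: "NONE", 1: "FT", 2: "FFT", 3: "NC", 4: "DC"}
LABEL_CODES: dict[str, int] = {name: code for code, name in LABEL_PALETTE.items()}

MIN_FRAME_SIDE = 5  # minimum window support


@dataclass(frozen=True)
class GrayFrame:
    """A single grayscale IVUS frame, 8-bit values in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"frame must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_FRAME_SIDE or px.shape[1] < MIN_FRAME_SIDE:
            raise DimensionError(
                f"frame must be at least {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE}, got {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            raise FormatError(f"frame must hold integer gray values, got dtype {px.dtype}")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("frame values outside [0, 255]; refusing to clip")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PlaqueMask:
    """Boolean map of plaque pixels (between intima and media-adventitia)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        fl = np.asarray(self.flags)
        if fl.ndim != 2:
            raise DimensionError(f"mask must be 2-D, got shape {fl.shape}")
        object.__setattr__(self, "flags", fl.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape

    @property
    def n_pixels(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel tissue labels as palette codes (0 = NONE outside plaque)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.labels)
        if lb.ndim != 2:
            raise DimensionError(f"label map must be 2-D, got shape {lb.shape}")
        if not np.issubdtype(lb.dtype, np.integer):
            raise LabelPaletteError(f"label map must be integer-coded, got dtype {lb.dtype}")
        bad = set(np.unique(lb)) - set(LABEL_PALETTE)
        if bad:
            raise LabelPaletteError(f"unknown label codes {sorted(bad)}; palette is {LABEL_PALETTE}")
        object.__setattr__(self, "labels", lb.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def names(self) -> np.ndarray:
        """Label names as an object array ('NONE' outside the plaque)."""
        lut = np.array([LABEL_PALETTE[c] for c in range(5)], dtype=object)
        return lut[self.labels]


def _read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return np.asarray(arr)


def load_frame(path: str | Path) -> GrayFrame:
    arr = _read_image(path)
    if arr.ndim == 3:
        raise FormatError(f"{path}: multi-channel image; frames must be single-channel")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: frames must be 8-bit, got dtype {arr.dtype}")
    return GrayFrame(arr)


def load_mask(path: str | Path, frame: GrayFrame | None = None) -> PlaqueMask:
    arr = _read_image(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel")
    if frame is not None and arr.shape != frame.shape:
        raise DimensionError(f"{path}: mask shape {arr.shape} != frame shape {frame.shape}")
    values = set(np.unique(arr))
    if not (values <= {0, 1} or values <= {0, 255}):
        raise LabelPaletteError(f"{path}: mask values must be 0/1 or 0/255, got {sorted(values)}")
    return PlaqueMask(arr > 0)


def load_labels(path: str | Path, mask: PlaqueMask | None = None) -> LabelMap:
    arr = _read_image(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be single-channel")
    if mask is not None and arr.shape != mask.shape:
        raise DimensionError(f"{path}: label shape {arr.shape} != mask shape {mask.shape}")
    labels = LabelMap(arr.astype(np.int64))
    if mask is not None and np.any((labels.labels != 0) & ~mask.flags):
        raise LabelPaletteError(f"{path}: nonzero labels outside the plaque mask")
    return labels


def load_dataset(
    frame_path: str | Path,
    mask_path: str | Path,
    label_path: str | Path | None = None,
) -> tuple[GrayFrame, PlaqueMask, LabelMap | None]:
    """Load a frame, its plaque mask, and (optionally) its label map.

    All three images must share the frame's dimensions; mask/label palette
    violations raise :class:`LabelPaletteError` rather than being coerced.
    """
    frame = load_frame(frame_path)
    mask = load_mask(mask_path, frame)
    labels = load_labels(label_path, mask) if label_path is not None else None
    return frame, mask, labels


def save_frame(frame: GrayFrame, path: str | Path) -> None:
    iio.imwrite(Path(path), frame.pixels)


def save_mask(mask: PlaqueMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.flags.astype(np.uint8))


def save_labels(labels: LabelMap, path: str | Path) -> None:
    iio.imwrite(Path(path), labels.labels)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

COORD_COLUMNS = ("row", "col", "label")


def validate_feature_table(matrix: pd.DataFrame) -> None:
    """Check the canonical schema: row, col, label + the 54 feature names."""
    from .features import FEATURE_NAMES  # local import to avoid a cycle

    missing = [c for c in COORD_COLUMNS if c not in matrix.columns]
    missing += [c for c in FEATURE_NAMES if c not in matrix.columns]
    if missing:
        raise SchemaError(f"feature table missing canonical columns: {missing[:6]}...")


def save_feature_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV (full float precision; lossless round-trip)."""
    from .features import FEATURE_NAMES

    validate_feature_table(matrix)
    cols = list(COORD_COLUMNS) + list(FEATURE_NAMES)
    matrix[cols].to_csv(Path(path), index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    validate_feature_table(df)
    df["label"] = df["label"].where(df["label"].notna(), None).astype(object)
    return df


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
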