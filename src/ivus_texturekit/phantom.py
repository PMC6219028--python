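"""Synthetic IVUS-like phantoms with speckle noise.

The phantom emulates a cross-sectional coronary frame: an annular plaque
region (between "intima" radius r1 and "media-adventitia" radius r2)
partitioned into contiguous blobs of the four tissue classes by seeded
Voronoi assignment, with brightness ordered FFT < FT < NC < DC and
multiplicative unit-mean gamma speckle.  A few Lloyd relaxation passes even
out blob areas, and classes claim cells largest-first by remaining target
deficit, so empirical class proportions track the requested mixing
proportions.

The speckle factor for class ``c`` is Gamma(shape=1/sigma_c^2,
scale=sigma_c^2) — unit mean, standard deviation sigma_c — so local texture
contrast scales with tissue brightness, as in coherent ultrasound.
Per-class sigma overrides allow a "hard" regime in which FT and FFT overlap
in brightness but differ in speckle contrast, forcing texture-driven
discrimination.

Everything is fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .pipeline_io import CLASSES, GrayFrame, LABEL_CODES, LabelMap, PlaqueMask

#: Default class mean intensities (artifact convention, brightness-ordered).
DEFAULT_MU = {"FFT": 60.0, "FT": 90.0, "NC": 150.0, "DC": 210.0}

#: Dim background outside the plaque: dark lumen, mid-gray adventitia.
_LUMEN_MU = 15.0
_OUTER_MU = 35.0


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 400
    r1: float = 70.0
    r2: float = 120.0
    mu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU))
    sigma: float = 0.1
    class_sigma: dict[str, float] = field(default_factory=dict)
    blobs_per_class: int = 6
    proportions: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CLASSES}
    )
    lloyd_iters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r1 < self.r2 < self.size / 2:
            raise ParameterError("need 0 < r1 < r2 < size/2")
        if set(self.mu) != set(CLASSES) or set(self.proportions) != set(CLASSES):
            raise ParameterError(f"mu and proportions must cover exactly {CLASSES}")
        if not (self.mu["FFT"] < self.mu["FT"] < self.mu["NC"] < self.mu["DC"]):
            raise ParameterError("class means must be ordered FFT < FT < NC < DC")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ParameterError("proportions must sum to 1")
        if self.sigma < 0 or any(s < 0 for s in self.class_sigma.values()):
            raise ParameterError("speckle scale must be nonnegative")
        if self.blobs_per_class < 1:
            raise ParameterError("blobs_per_class must be >= 1")

    def sigma_for(self, cls: str) -> float:
        return self.class_sigma.get(cls, self.sigma)

    @classmethod
    def hard_ft_fft(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """Preset with heavy FT/FFT brightness overlap but distinct speckle
        contrast, so only texture separates the two."""
        mu = dict(DEFAULT_MU, FT=86.0, FFT=80.0)
        return cls(
            mu=mu, class_sigma={"FT": 0.05, "FFT": 0.16}, seed=seed, **overrides
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _speckle(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    if sigma == 0:
        return np.ones(n)
    shape = 1.0 / sigma**2
    return rng.gamma(shape, scale=1.0 / shape, size=n)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayFrame, PlaqueMask, LabelMap]:
    """One frame + plaque mask + four-class label map, seed-determined."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    center = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - center, xx - center)
    annulus = (r > spec.r1) & (r <= spec.r2)
    ann_pts = np.column_stack(np.nonzero(annulus)).astype(np.float64)

    # Blob slots per class proportional to the mixing proportions.
    total_blobs = 4 * spec.blobs_per_class
    slots = {c: max(1, round(total_blobs * spec.proportions[c])) for c in CLASSES}
    n_seeds = sum(slots.values())

    # Area-uniform seed placement in the annulus (polar draw).
    u = rng.random(n_seeds)
    rad = np.sqrt(u * (spec.r2**2 - spec.r1**2) + spec.r1**2)
    ang = rng.random(n_seeds) * 2 * np.pi
    seeds = np.column_stack([center + rad * np.sin(ang), center + rad * np.cos(ang)])

    # Lloyd relaxation evens out blob areas.
    for _ in range(spec.lloyd_iters):
        owner = cKDTree(seeds).query(ann_pts)[1]
        for s in range(n_seeds):
            cell = ann_pts[owner == s]
            if len(cell):
                seeds[s] = cell.mean(axis=0)
    owner = cKDTree(seeds).query(ann_pts)[1]

    # Classes claim cells largest-first by remaining target deficit, so the
    # empirical class fractions track the mixing proportions tightly while
    # every blob stays contiguous.
    areas = np.bincount(owner, minlength=n_seeds) / len(ann_pts)
    remaining = dict(slots)
    covered = {c: 0.0 for c in CLASSES}
    class_of_seed = np.empty(n_seeds, dtype=np.int64)
    for s in np.argsort(-areas):
        c = max(
            (c for c in CLASSES if remaining[c] > 0),
            key=lambda c: spec.proportions[c] - covered[c],
        )
        class_of_seed[s] = LABEL_CODES[c]
        remaining[c] -= 1
        covered[c] += areas[s]

    labels = np.zeros((n, n), dtype=np.int64)
    pr, pc = ann_pts[:, 0].astype(int), ann_pts[:, 1].astype(int)
    labels[pr, pc] = class_of_seed[owner]

    # Brightness: class mean times unit-mean gamma speckle, then the frame's
    # 8-bit rounding; values are clipped only by the sensor range.
    img = np.zeros((n, n), dtype=np.float64)
    lumen = r <= spec.r1
    outer = r > spec.r2
    img[lumen] = _LUMEN_MU * _speckle(rng, spec.sigma, int(lumen.sum()))
    img[outer] = _OUTER_MU * _speckle(rng, spec.sigma, int(outer.sum()))
    for c in CLASSES:
        sel = labels == LABEL_CODES[c]
        img[sel] = spec.mu[c] * _speckle(rng, spec.sigma_for(c), int(sel.sum()))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return GrayFrame(pixels), PlaqueMask(annulus), LabelMap(labels)


def derive_frame_seeds(seed: int, n_frames: int) -> list[int]:
    """Deterministic child seeds for a multi-frame dataset (each < 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n_frames)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_dataset(
    spec: PhantomSpec, n_frames: int, seed: int | None = None
) -> list[tuple[GrayFrame, PlaqueMask, LabelMap]]:
    """Independent frames from per-frame derived seeds."""
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    base = spec.seed if seed is None else seed
    return [
        generate_phantom(replace(spec, seed=s)) for s in derive_frame_seeds(base, n_frames)
    ]
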