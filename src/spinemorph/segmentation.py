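"""Vertebral-body segmentation stage as a pluggable contract.

Two backends produce a binary :class:`SegmentationMask` on the standard
grid:

* ``oracle`` — binarizes a supplied ground-truth label raster (phantom
  output), optionally corrupted by a seeded model (interior holes,
  satellite blobs, boundary jitter) to exercise mask post-processing;
* ``model``  — a trained NumPy U-net (see :mod:`spinemorph.nn`); requesting
  it without weights is an explicit error, never a silent fallback.

Also provides the Dice overlap coefficient used as both training loss and
evaluation metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import StandardSlice
from .nn import NumpyUNet, UNetSpec, build_unet  # re-exported

__all__ = [
    "SegmentationMask",
    "CorruptionConfig",
    "corrupt_mask",
    "segment",
    "dice",
    "UNetSpec",
    "NumpyUNet",
    "build_unet",
]


@dataclass
class SegmentationMask:
    """Binary raster on the StandardSlice grid with a provenance tag."""

    values: np.ndarray
    provenance: str  # 'oracle' | 'model'
    spacing: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ValueError("segmentation mask must be 2-D")


@dataclass(frozen=True)
class CorruptionConfig:
    """Seeded corruption of an oracle mask (all sizes in pixels)."""

    n_holes: int = 3
    hole_radius: tuple[float, float] = (1.0, 3.0)
    n_satellites: int = 2
    satellite_radius: tuple[float, float] = (1.0, 2.5)
    satellite_distance: tuple[float, float] = (30.0, 80.0)
    boundary_jitter: int = 1  # iterations of random erode-or-dilate patches


def corrupt_mask(mask: np.ndarray, config: CorruptionConfig,
                 seed: int = 0) -> np.ndarray:
    """Apply the corruption model; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    out = np.asarray(mask).astype(bool).copy()
    rows, cols = np.nonzero(out)
    if rows.size == 0:
        return out
    yy, xx = np.mgrid[0:out.shape[0], 0:out.shape[1]]

    for _ in range(config.n_holes):
        i = rng.integers(rows.size)
        r = rng.uniform(*config.hole_radius)
        out[(yy - rows[i]) ** 2 + (xx - cols[i]) ** 2 <= r * r] = False

    centroid = np.array([rows.mean(), cols.mean()])
    for _ in range(config.n_satellites):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(*config.satellite_distance)
        cy = centroid[0] + dist * np.sin(ang)
        cx = centroid[1] + dist * np.cos(ang)
        r = rng.uniform(*config.satellite_radius)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        out |= blob

    for _ in range(config.boundary_jitter):
        i = rng.integers(rows.size)
        patch = (yy - rows[i]) ** 2 + (xx - cols[i]) ** 2 <= 9.0
        if rng.random() < 0.5:
            eroded = ndimage.binary_erosion(out)
            out[patch] = eroded[patch]
        else:
            dilated = ndimage.binary_dilation(out)
            out[patch] = dilated[patch]
    return out


def segment(
    slice_: StandardSlice,
    backend: str = "oracle",
    *,
    labels: np.ndarray | None = None,
    model: NumpyUNet | None = None,
    corruption: CorruptionConfig | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> SegmentationMask:
    """Produce the binary vertebra mask for a standardized slice."""
    if backend == "oracle":
        if labels is None:
            raise ValueError("oracle backend requires the ground-truth labels")
        labels = np.asarray(labels)
        if labels.shape != slice_.pixels.shape:
            raise ValueError("labels and slice must share the grid")
        values = labels > 0
        if corruption is not None:
            values = corrupt_mask(values, corruption, seed=seed)
        return SegmentationMask(values=values, provenance="oracle",
                                spacing=slice_.spacing,
                                meta={"corruption_seed": seed
                                      if corruption else None})
    if backend == "model":
        if model is None:
            raise ValueError(
                "model backend requested but no trained model supplied; "
                "refusing to fall back silently"
            )
        values = model.predict_mask(slice_.pixels, threshold=threshold)
        return SegmentationMask(values=values, provenance="model",
                                spacing=slice_.spacing,
                                meta={"threshold": threshold})
    raise ValueError(f"unknown segmentation backend {backend!r}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|); two empty masks are defined as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)
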