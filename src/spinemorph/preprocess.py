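"""Mid-sagittal slice selection and standardization.

The working input is a sagittal T2-weighted volume.  The eligible sequence
must satisfy TE >= 80 ms, TR >= 3000 ms, slice thickness 2-4 mm and
in-plane spacing <= 0.8 mm; among several candidates the smallest in-plane
spacing wins.  Only the central slice is kept (the center-left one for an
even slice count, i.e. index ``floor((n - 1) / 2)`` 0-based), resampled to
0.6 x 0.6 mm, center-placed on a 448 x 320 canvas, and intensity-mapped by
``min(v / 2500, 1)`` from the 12-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    CANVAS_SHAPE,
    DEFAULT_ORIENTATION,
    STANDARD_SPACING_MM,
    StandardSlice,
)

__all__ = [
    "SeriesDescriptor",
    "ImageVolume",
    "NoEligibleSequenceError",
    "select_sequence",
    "select_center_slice",
    "standardize",
    "read_nifti_volume",
    "read_dicom_series",
]

#: Sequence eligibility bounds.
TE_MIN_MS = 80.0
TR_MIN_MS = 3000.0
SLICE_THICKNESS_RANGE_MM = (2.0, 4.0)
IN_PLANE_SPACING_MAX_MM = 0.8

#: 12-bit intensity scale and the informative-range divisor.
INTENSITY_SCALE = 4096.0
INTENSITY_DIVISOR = 2500.0


class NoEligibleSequenceError(ValueError):
    """No series in the study satisfies the sequence requirements."""


@dataclass
class SeriesDescriptor:
    """Acquisition metadata of one series plus a handle to its voxels."""

    plane: str  # 'sagittal' | 'axial' | 'coronal' | ...
    te_ms: float
    tr_ms: float
    slice_thickness_mm: float
    in_plane_spacing_mm: float
    series_id: str = ""
    volume: "ImageVolume | None" = None

    def eligible(self) -> bool:
        lo, hi = SLICE_THICKNESS_RANGE_MM
        return (
            self.plane.lower() == "sagittal"
            and self.te_ms >= TE_MIN_MS
            and self.tr_ms >= TR_MIN_MS
            and lo <= self.slice_thickness_mm <= hi
            and self.in_plane_spacing_mm <= IN_PLANE_SPACING_MAX_MM
        )


@dataclass
class ImageVolume:
    """Voxel stack (slices x rows x cols) with spacing and orientation."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]  # (slice, row, col)
    orientation: str = DEFAULT_ORIENTATION
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 2-D or 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if self.voxels.shape[0] < 1:
            raise ValueError("volume needs at least one slice")


def select_sequence(series: list[SeriesDescriptor]) -> SeriesDescriptor:
    """Pick the eligible sagittal T2 series; smallest in-plane spacing wins."""
    if not series:
        raise NoEligibleSequenceError("study contains no series")
    candidates = [s for s in series if s.eligible()]
    if not candidates:
        raise NoEligibleSequenceError(
            "no eligible sequence: need sagittal, TE >= 80 ms, TR >= 3000 ms, "
            "slice thickness 2-4 mm, in-plane spacing <= 0.8 mm"
        )
    return min(candidates, key=lambda s: s.in_plane_spacing_mm)


def select_center_slice(volume: ImageVolume | int) -> int:
    """Central slice index; for an even count the center-left slice.

    With 0-based indexing both cases reduce to ``floor((n - 1) / 2)``.
    """
    n = volume if isinstance(volume, int) else volume.voxels.shape[0]
    if n < 1:
        raise ValueError("volume needs at least one slice")
    return (n - 1) // 2


def _resample(arr: np.ndarray, spacing: tuple[float, float],
              is_mask: bool) -> np.ndarray:
    factors = (spacing[0] / STANDARD_SPACING_MM,
               spacing[1] / STANDARD_SPACING_MM)
    if abs(factors[0] - 1.0) < 1e-9 and abs(factors[1] - 1.0) < 1e-9:
        return np.asarray(arr, dtype=arr.dtype)
    order = 0 if is_mask else 1
    return ndimage.zoom(np.asarray(arr, dtype=float), factors, order=order,
                        prefilter=False, grid_mode=False)


def _fit_canvas(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Symmetric center-crop / zero-pad to the target shape."""
    out = arr
    for axis, target in enumerate(shape):
        cur = out.shape[axis]
        if cur > target:
            start = (cur - target) // 2
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif cur < target:
            before = (target - cur) // 2
            after = target - cur - before
            pad = [(0, 0)] * out.ndim
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant")
    return out


def standardize(
    raster: np.ndarray,
    spacing: float | tuple[float, float],
    *,
    is_mask: bool = False,
    canvas_shape: tuple[int, int] = CANVAS_SHAPE,
    orientation: str = DEFAULT_ORIENTATION,
) -> StandardSlice:
    """Resample to 0.6 mm, fit the 448 x 320 canvas, map intensities to [0,1].

    Unit-range inputs (e.g. phantom renders) are first rescaled by the
    2500 divisor so that the clip behaves identically on one code path;
    this keeps standardization idempotent.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))  # type: ignore[assignment]
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise ValueError("pixel spacing must be strictly positive")
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2:
        raise ValueError("standardize expects a single 2-D slice")

    arr = _resample(arr, spacing, is_mask)
    arr = _fit_canvas(arr, canvas_shape)

    if is_mask:
        pixels = (arr > 0.5).astype(np.float32)
    else:
        if arr.size and np.nanmax(arr) <= 1.0:
            arr = arr * INTENSITY_DIVISOR
        pixels = np.clip(arr / INTENSITY_DIVISOR, 0.0, 1.0).astype(np.float32)

    return StandardSlice(
        pixels=pixels,
        spacing=(STANDARD_SPACING_MM, STANDARD_SPACING_MM),
        orientation=orientation,
        meta={"canvas": canvas_shape, "source_spacing": tuple(spacing)},
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_nifti_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI file as an ImageVolume (slices x rows x cols)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    if data.ndim == 2:
        data = data[None]
        spacing = (1.0, float(zooms[0]), float(zooms[1]))
    elif data.ndim == 3:
        # our writer stores (rows, cols, slices); move slices first
        data = np.moveaxis(data, 2, 0)
        spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    else:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
    return ImageVolume(voxels=data, spacing_mm=spacing,
                       meta={"path": str(path)})


def read_dicom_series(directory: str | Path) -> list[SeriesDescriptor]:
    """Scan a directory of DICOM files into per-series descriptors.

    Requires the optional ``pydicom`` dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM input requires the optional 'pydicom' package; "
            "install it or supply NIfTI input instead"
        ) from exc

    directory = Path(directory)
    by_series: dict[str, list] = {}
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        by_series.setdefault(str(getattr(ds, "SeriesInstanceUID", f.name)),
                             []).append(ds)

    out: list[SeriesDescriptor] = []
    for uid, datasets in by_series.items():
        ds = datasets[0]
        datasets.sort(key=lambda d: float(getattr(d, "SliceLocation", 0.0)))
        voxels = np.stack([d.pixel_array for d in datasets])
        row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
        thickness = float(getattr(ds, "SliceThickness", 0.0))
        orient = getattr(ds, "ImageOrientationPatient", None)
        plane = _plane_from_orientation(orient)
        vol = ImageVolume(voxels=voxels,
                          spacing_mm=(thickness or 1.0, row_sp, col_sp))
        out.append(SeriesDescriptor(
            plane=plane,
            te_ms=float(getattr(ds, "EchoTime", 0.0)),
            tr_ms=float(getattr(ds, "RepetitionTime", 0.0)),
            slice_thickness_mm=thickness,
            in_plane_spacing_mm=max(row_sp, col_sp),
            series_id=uid,
            volume=vol,
        ))
    return out


def _plane_from_orientation(orient) -> str:
    if orient is None:
        return "unknown"
    v = np.asarray([float(x) for x in orient], dtype=float)
    normal = np.cross(v[:3], v[3:])
    axis = int(np.argmax(np.abs(normal)))
    return {0: "sagittal", 1: "coronal", 2: "axial"}[axis]
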