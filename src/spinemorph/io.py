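"""Readers/writers for the pipeline's standard formats (NIfTI, PNG, CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import StandardSlice

__all__ = ["write_nifti", "write_png", "read_png", "slice_from_nifti"]


def write_nifti(array: np.ndarray, spacing: tuple[float, float],
                path: str | Path) -> None:
    """Store a 2-D raster as NIfTI with the in-plane spacing in the header."""
    import nibabel as nib

    arr = np.asarray(array)
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    img = nib.Nifti1Image(arr[..., None].astype(np.float32), affine)
    img.header.set_zooms((spacing[1], spacing[0], 1.0))
    nib.save(img, str(path))


def slice_from_nifti(path: str | Path):
    """Load a single-slice NIfTI written by :func:`write_nifti`."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError("expected a single-slice NIfTI")
        data = data[..., 0]
    return data, (float(zooms[1]), float(zooms[0]))


def write_png(array: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    arr = np.asarray(array, dtype=float)
    if arr.max() > 1.0:
        arr = arr / arr.max()
    Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(str(path))


def read_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path)), dtype=float) / 255.0


def slice_to_nifti(slc: StandardSlice, path: str | Path) -> None:
    write_nifti(slc.pixels, slc.spacing, path)
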