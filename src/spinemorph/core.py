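"""Shared working-canvas types and conventions.

The pipeline operates on a single standardized mid-sagittal slice: a
448 x 320 raster at 0.6 x 0.6 mm pixel spacing with intensities in [0, 1].
Image convention throughout: the anterior aspect of the spine faces the
left image border (small column index) and the cranial direction faces the
top row (small row index).

Millimetre coordinates are obtained from 0-based pixel indices by
multiplying with the pixel spacing: ``x = col * spacing``, ``y = row *
spacing``.  ``y`` therefore increases caudally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard canvas shape (rows, cols) after slice standardization.
CANVAS_SHAPE: tuple[int, int] = (448, 320)

#: Standard in-plane pixel spacing in millimetres.
STANDARD_SPACING_MM: float = 0.6

#: Orientation tag written by every stage that creates a raster.
DEFAULT_ORIENTATION: str = "anterior-left,cranial-top"


class GeometryError(ValueError):
    """Raised when a requested geometry is degenerate or infeasible."""


@dataclass
class StandardSlice:
    """One standardized mid-sagittal image: the pipeline's working canvas.

    Attributes
    ----------
    pixels:
        2-D float array, intensities in [0, 1].
    spacing:
        (row, col) pixel spacing in millimetres.
    orientation:
        Which image edges are anterior/cranial (see module docstring).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (STANDARD_SPACING_MM, STANDARD_SPACING_MM)
    orientation: str = DEFAULT_ORIENTATION
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("StandardSlice.pixels must be 2-D")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("pixel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]
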