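"""Shared domain types.

Conventions used throughout the package:

* Images are 2-D ``float`` arrays, row 0 at the top (vitreous side),
  intensities in ``[0, 1]``.
* Boundaries are per-column integer row indices.  The RNFL band in column
  ``c`` occupies the half-open row interval ``[upper[c], lower[c])``, so
  band thickness in pixels is exactly ``lower - upper``.
* Categorical masks use the labels ``ABOVE=0`` (vitreous / pre-retinal
  background), ``RNFL=1`` (the hyperreflective band), ``BELOW=2``
  (deeper retinal / choroidal background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ABOVE = 0
RNFL = 1
BELOW = 2
N_CLASSES = 3


@dataclass
class BoundarySet:
    """Per-column row indices of the anterior (ILM) and posterior RNFL boundary.

    ``upper[c] < lower[c]`` must hold in every column; the band is the
    half-open interval ``[upper[c], lower[c])``.
    """

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=np.int64)
        self.lower = np.asarray(self.lower, dtype=np.int64)
        if self.upper.shape != self.lower.shape or self.upper.ndim != 1:
            raise ValueError("upper and lower must be 1-D arrays of equal length")
        if np.any(self.upper >= self.lower):
            bad = int(np.argmax(self.upper >= self.lower))
            raise ValueError(f"upper >= lower at column {bad}")
        if np.any(self.upper < 0):
            raise ValueError("negative boundary row")

    @property
    def width(self) -> int:
        return self.upper.shape[0]

    def thickness(self) -> np.ndarray:
        """Per-column band thickness in pixels."""
        return self.lower - self.upper

    def validate_for(self, height: int) -> None:
        if np.any(self.lower > height):
            bad = int(np.argmax(self.lower > height))
            raise ValueError(f"lower boundary exceeds image height at column {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BoundarySet):
            return NotImplemented
        return bool(
            np.array_equal(self.upper, other.upper)
            and np.array_equal(self.lower, other.lower)
        )


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce a 2-D [0,1] intensity raster."""
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer with halves going up (toward +inf)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)
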