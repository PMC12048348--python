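"""Core containers for calibrated 4D scanning-diffraction data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .optics import AcquisitionGeometry

__all__ = ["Dataset4D", "Calibration"]


@dataclass
class Dataset4D:
    """A calibrated 4D stack: 2D scan grid of 2D diffraction patterns.

    Axes are ``(scan_y, scan_x, k_y, k_x)`` in storage order.  ``beam_center``
    is the detector coordinate of the direct beam as ``(x, y)`` pixels
    (columns, rows), sub-pixel; ``None`` means the geometric detector centre.

    Units: ``scan_step`` nm per scan pixel, ``detector_cal`` 1/A per detector
    pixel, ``rotation_offset`` the scan-to-detector azimuth rotation in
    degrees (added to detector azimuths to express them in the scan frame).
    """

    counts: np.ndarray
    scan_step: float = 1.0
    detector_cal: float = 1.0
    rotation_offset: float = 0.0
    beam_center: tuple | None = None
    geometry: AcquisitionGeometry | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 4:
            raise DataError(f"counts must be 4D, got ndim={c.ndim}")
        if min(c.shape) < 8:
            raise DataError(f"all dims must be >= 8, got shape {c.shape}")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.isfinite(c)):
                raise DataError("counts contain non-finite values")
        if c.size and float(c.min()) < 0:
            raise DataError("counts must be non-negative")
        if not self.detector_cal > 0:
            raise DataError("detector_cal must be positive")
        self.counts = c
        if self.beam_center is not None:
            bx, by = self.beam_center
            ny, nx = c.shape[2:]
            if not (0 <= bx <= nx - 1 and 0 <= by <= ny - 1):
                raise DataError("beam_center outside detector bounds")
            self.beam_center = (float(bx), float(by))

    @property
    def scan_shape(self):
        return self.counts.shape[:2]

    @property
    def detector_shape(self):
        return self.counts.shape[2:]

    @property
    def center(self):
        """Effective beam centre ``(x, y)`` px (geometric centre if unset)."""
        if self.beam_center is not None:
            return self.beam_center
        ny, nx = self.detector_shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)

    def replace_counts(self, counts, **updates) -> "Dataset4D":
        kw = dict(
            scan_step=self.scan_step,
            detector_cal=self.detector_cal,
            rotation_offset=self.rotation_offset,
            beam_center=self.beam_center,
            geometry=self.geometry,
            flags=list(self.flags),
        )
        kw.update(updates)
        return Dataset4D(counts, **kw)


@dataclass
class Calibration:
    """Per-pattern centering shifts plus the elliptical-distortion correction.

    ``center_shift_map[y, x] = (dx, dy)`` is the shift *applied* to pattern
    ``(y, x)`` to bring its direct beam to the geometric centre (storage
    pixel units).  ``affine`` acts on corrected detector vectors,
    ``k_corr = affine @ k_meas`` in ``(x, y)`` components.
    """

    center_shift_map: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(2))
    rotation_offset: float = 0.0

    def __post_init__(self):
        a = np.asarray(self.affine, dtype=float)
        if a.shape != (2, 2):
            raise ValueError("affine must be 2x2")
        det = np.linalg.det(a)
        if not det > 0:
            raise ValueError("affine must be invertible with det > 0")
        self.affine = a
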