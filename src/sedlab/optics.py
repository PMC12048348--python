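"""Acquisition-geometry arithmetic for nanobeam diffraction.

The probe is diffraction limited: with convergence semiangle ``alpha`` and
relativistic electron wavelength ``lambda(kV)`` the probe diameter is
``d_diff = 1.22 lambda / alpha`` and the diffraction discs have reciprocal
diameter ``2 alpha / lambda``.  The per-scan electron fluence follows from
probe current, dwell time and the disc-like probe area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = [
    "AcquisitionGeometry",
    "electron_wavelength_A",
    "probe_diameter",
    "fluence_per_scan",
    "disc_diameter_reciprocal",
    "electrons_per_pattern",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Microscope settings that fix the probe and dose.

    Parameters
    ----------
    kv : accelerating voltage in kV.
    alpha_mrad : convergence semiangle in mrad.
    current_pa : probe current in pA.
    dwell_ms : dwell time per probe position in ms.
    """

    kv: float = 300.0
    alpha_mrad: float = 0.8
    current_pa: float = 1.0
    dwell_ms: float = 1.0

    def __post_init__(self):
        for name in ("kv", "alpha_mrad", "current_pa", "dwell_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def electron_wavelength_A(kv: float) -> float:
    """Relativistic electron de Broglie wavelength in Angstrom.

    ``lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))`` with CODATA
    constants; full precision is kept, rounding is left to display code.
    """
    if not 10.0 < kv < 1000.0:
        raise ValueError("accelerating voltage must be in (10, 1000) kV")
    v = kv * 1e3
    h = constants.h
    m0 = constants.m_e
    e = constants.e
    c = constants.c
    p = np.sqrt(2.0 * m0 * e * v * (1.0 + e * v / (2.0 * m0 * c**2)))
    return h / p * 1e10


def probe_diameter(geom: AcquisitionGeometry) -> float:
    """Diffraction-limited probe diameter ``1.22 lambda / alpha`` in nm."""
    if not geom.alpha_mrad > 0:
        raise ValueError("convergence semiangle must be positive")
    lam_A = electron_wavelength_A(geom.kv)
    alpha = geom.alpha_mrad * 1e-3
    return 1.22 * lam_A / alpha * 0.1  # Angstrom -> nm


def electrons_per_pattern(geom: AcquisitionGeometry) -> float:
    """Electrons delivered per probe position, ``I * t / e``."""
    return geom.current_pa * 1e-12 * geom.dwell_ms * 1e-3 / constants.e


def fluence_per_scan(geom: AcquisitionGeometry) -> float:
    """Electron fluence of a single scan in e-/A^2, disc-like probe assumed."""
    d_A = probe_diameter(geom) * 10.0
    area = np.pi * d_A**2 / 4.0
    return electrons_per_pattern(geom) / area


def disc_diameter_reciprocal(geom: AcquisitionGeometry) -> float:
    """Diffraction-disc diameter ``2 alpha / lambda`` in 1/A."""
    lam_A = electron_wavelength_A(geom.kv)
    return 2.0 * geom.alpha_mrad * 1e-3 / lam_A
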