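"""Pattern-level preprocessing: centering, distortion correction, binning,
annular dark-field and mean-pattern images.

The direct beam is localised in every pattern by cross-correlation with a
soft disc template and moved to the geometric detector centre with sub-pixel
Fourier-shift interpolation; an affine matrix then corrects residual
elliptical distortion.  ADF formation integrates each pattern over an
annulus (defaults 0.12-1.0 1/A); annulus and aperture membership are decided
by pixel-centre radius.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .datamodel import Calibration, Dataset4D
from .errors import CenteringError
from .optics import disc_diameter_reciprocal

__all__ = [
    "center_and_correct",
    "bin_patterns",
    "adf_image",
    "mean_pattern",
    "sqrt_display",
]


def _disc_template(shape, radius, softness=1.0):
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y, x = np.ogrid[:ny, :nx]
    r = np.hypot(y - cy, x - cx)
    t = 0.5 * (1.0 - np.tanh((r - radius) / max(softness, 1e-6)))
    return t - t.mean()


def _parabolic(c_m, c_0, c_p):
    den = c_m - 2.0 * c_0 + c_p
    if den == 0:
        return 0.0
    return float(np.clip(0.5 * (c_m - c_p) / den, -1.0, 1.0))


def _locate_beam(patterns, template_f, significance):
    """Correlation peak offsets (dx, dy) from centre for a batch of patterns."""
    n, ny, nx = patterns.shape
    pf = np.fft.fft2(patterns)
    corr = np.fft.ifft2(pf * template_f.conj()).real
    corr = np.fft.fftshift(corr, axes=(1, 2))
    offsets = np.empty((n, 2))
    bad = np.zeros(n, dtype=bool)
    flat = corr.reshape(n, -1)
    idx = flat.argmax(axis=1)
    mu = flat.mean(axis=1)
    sd = flat.std(axis=1)
    for i in range(n):
        py, px = np.unravel_index(idx[i], (ny, nx))
        if sd[i] == 0 or (flat[i, idx[i]] - mu[i]) / sd[i] < significance:
            bad[i] = True
            offsets[i] = 0.0
            continue
        dy = dx = 0.0
        if 0 < py < ny - 1:
            dy = _parabolic(corr[i, py - 1, px], corr[i, py, px], corr[i, py + 1, px])
        if 0 < px < nx - 1:
            dx = _parabolic(corr[i, py, px - 1], corr[i, py, px], corr[i, py, px + 1])
        # fftshifted lag: index ny//2, nx//2 is zero displacement
        offsets[i] = (px + dx - nx // 2, py + dy - ny // 2)
    return offsets, bad


def _fourier_shift_batch(patterns, shifts):
    """Shift each pattern by its ``(dx, dy)`` with periodic Fourier interpolation."""
    n, ny, nx = patterns.shape
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    phase = np.exp(-2j * np.pi * (ky * shifts[:, 1, None, None]
                                  + kx * shifts[:, 0, None, None]))
    out = np.fft.ifft2(np.fft.fft2(patterns) * phase).real
    return np.clip(out, 0.0, None)


def _apply_affine(patterns, affine):
    """Resample patterns so that ``k_corr = affine @ k_meas`` about the centre."""
    inv = np.linalg.inv(affine)  # output -> input, (x, y) components
    m_rc = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    ny, nx = patterns.shape[1:]
    c = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
    offset = c - m_rc @ c
    out = np.empty_like(patterns, dtype=float)
    for i in range(patterns.shape[0]):
        out[i] = ndimage.affine_transform(patterns[i], m_rc, offset=offset,
                                          order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, None)


def center_and_correct(
    ds: Dataset4D,
    reference_disc_radius: float | None = None,
    affine: np.ndarray | None = None,
    significance: float = 5.0,
    batch: int = 256,
):
    """Centre the direct beam in every pattern, then correct distortion.

    Parameters
    ----------
    reference_disc_radius : template disc radius in detector px; defaults to
        the diffraction-disc radius from the acquisition geometry, or 3 px.
    affine : 2x2 elliptical-distortion correction, ``k_corr = affine @ k_meas``;
        identity when omitted.

    Returns ``(centred_dataset, Calibration)``; raises
    :class:`~sedlab.errors.CenteringError` listing scan positions whose
    correlation peak falls below ``significance`` standard deviations.
    """
    ny_s, nx_s = ds.scan_shape
    det_shape = ds.detector_shape
    if reference_disc_radius is None:
        if ds.geometry is not None:
            reference_disc_radius = (
                disc_diameter_reciprocal(ds.geometry) / 2.0 / ds.detector_cal)
        else:
            reference_disc_radius = 3.0
    # template is rendered about the geometric centre, so correlation lags
    # measure the beam offset from that centre directly
    template = _disc_template(det_shape, reference_disc_radius)
    template_f = np.fft.fft2(template)

    flat = np.asarray(ds.counts, dtype=float).reshape(-1, *det_shape)
    n = flat.shape[0]
    shifts = np.empty((n, 2))
    out = np.empty_like(flat)
    bad_idx = []
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        offsets, bad = _locate_beam(flat[sl], template_f, significance)
        if bad.any():
            bad_idx.extend(start + np.flatnonzero(bad))
        shifts[sl] = -offsets
        out[sl] = _fourier_shift_batch(flat[sl], shifts[sl])
    if bad_idx:
        raise CenteringError([tuple(np.unravel_index(i, (ny_s, nx_s)))
                              for i in bad_idx])
    if affine is not None and not np.allclose(affine, np.eye(2)):
        out = _apply_affine(out, np.asarray(affine, dtype=float))
        cal_affine = np.asarray(affine, dtype=float)
    else:
        cal_affine = np.eye(2)

    centred = ds.replace_counts(out.reshape(ds.counts.shape), beam_center=None)
    calib = Calibration(
        center_shift_map=shifts.reshape(ny_s, nx_s, 2),
        affine=cal_affine,
        rotation_offset=ds.rotation_offset,
    )
    return centred, calib


def bin_patterns(ds: Dataset4D, factor: int) -> Dataset4D:
    """Sum detector pixels in ``factor x factor`` blocks.

    Trailing rows/columns that do not fill a block are cropped (documented
    convention); ``detector_cal`` is multiplied by the factor and the beam
    centre is remapped to the binned grid.  Total counts over the retained
    region are conserved exactly for integer input.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("binning factor must be a positive integer")
    if factor == 1:
        return ds.replace_counts(ds.counts.copy())
    ny_s, nx_s = ds.scan_shape
    ky, kx = ds.detector_shape
    ky2, kx2 = (ky // factor) * factor, (kx // factor) * factor
    c = ds.counts[:, :, :ky2, :kx2]
    c = c.reshape(ny_s, nx_s, ky2 // factor, factor, kx2 // factor, factor)
    binned = c.sum(axis=(3, 5))
    bc = ds.center
    new_bc = ((bc[0] - (factor - 1) / 2.0) / factor,
              (bc[1] - (factor - 1) / 2.0) / factor)
    return ds.replace_counts(
        binned,
        detector_cal=ds.detector_cal * factor,
        beam_center=new_bc,
    )


def _radius_map(ds: Dataset4D):
    ny, nx = ds.detector_shape
    bx, by = ds.center
    y, x = np.ogrid[:ny, :nx]
    return np.hypot(y - by, x - bx) * ds.detector_cal


def adf_image(ds: Dataset4D, r_in: float = 0.12, r_out: float = 1.0) -> np.ndarray:
    """Annular dark-field image: per-position counts with ``r_in <= |k| <= r_out``.

    Radii in 1/A; membership by pixel-centre radius.  A truncated annulus
    (``r_out`` beyond the detector edge) warns and integrates what is there.
    """
    if not 0 <= r_in < r_out:
        raise ValueError("require 0 <= r_in < r_out")
    r = _radius_map(ds)
    ny, nx = ds.detector_shape
    bx, by = ds.center
    edge = min(bx, nx - 1 - bx, by, ny - 1 - by) * ds.detector_cal
    if r_out > edge:
        warnings.warn(f"outer radius {r_out} 1/A beyond detector edge "
                      f"({edge:.3f} 1/A); annulus truncated", stacklevel=2)
    mask = (r >= r_in) & (r <= r_out)
    flat = ds.counts.reshape(*ds.scan_shape, -1)
    return flat[:, :, mask.ravel()].sum(axis=-1)


def mean_pattern(ds: Dataset4D, scan_mask: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic mean diffraction pattern over (masked) scan positions."""
    if scan_mask is None:
        return np.asarray(ds.counts, dtype=float).mean(axis=(0, 1))
    scan_mask = np.asarray(scan_mask, dtype=bool)
    if scan_mask.shape != ds.scan_shape:
        raise ValueError("scan_mask shape must equal the scan shape")
    if not scan_mask.any():
        raise ValueError("scan_mask selects no positions")
    return np.asarray(ds.counts, dtype=float)[scan_mask].mean(axis=0)


def sqrt_display(image: np.ndarray) -> np.ndarray:
    """Square-root intensity transform for display of diffraction data."""
    return np.sqrt(np.clip(np.asarray(image, dtype=float), 0.0, None))
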