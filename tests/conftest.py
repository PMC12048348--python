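import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sedlab._geometry import unit_from_azimuth
from sedlab.burgers import model_f
from sedlab.datamodel import Dataset4D
from sedlab.discs import GVector, VDFImage
from sedlab.optics import AcquisitionGeometry
from sedlab.simulate import fixture_spec, simulate_dataset

settings.register_profile(
    "sedlab", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("sedlab")


def gaussian_disc(shape, center_xy, sigma, total):
    """Render a Gaussian disc with a given integrated intensity."""
    ny, nx = shape
    y, x = np.mgrid[:ny, :nx]
    g = np.exp(-((x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2)
               / (2 * sigma**2))
    return total * g / g.sum()


def make_tiny_dataset(scan=(8, 8), det=(32, 32), discs=(), beam=200.0,
                      seed=None, **kw):
    """Small deterministic 4D stack: a central beam plus fixed discs in
    every pattern (optionally Poisson sampled)."""
    ny, nx = det
    bc = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    pat = gaussian_disc(det, bc, 2.0, beam)
    for cx, cy, tot in discs:
        pat += gaussian_disc(det, (cx, cy), 1.5, tot)
    counts = np.broadcast_to(pat, (*scan, *det)).copy()
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    kw.setdefault("geometry", AcquisitionGeometry())
    return Dataset4D(counts, **kw)


@pytest.fixture(scope="session")
def mixed_case():
    """Standard mixed-character simulated dataset with its ground truth."""
    spec = fixture_spec("mixed", seed=1)
    ds, gt = simulate_dataset(spec)
    return spec, ds, gt


def contour_scene(phi, f, line, width_nm=16.0, peak=300.0, u_hat=None,
                  shape=(64, 64), step=4.0, anchor_t=0.5, noise_seed=None,
                  twist_deg=0.0):
    """Analytic single-reflection VDF: a straight bend contour displaced by
    ``f`` (nm) along the line on the far side, optionally twisted/noisy."""
    ny, nx = shape
    xs = np.arange(nx) * step
    ys = np.arange(ny) * step
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    far = np.asarray(line.side_of(pts)) > 0
    if u_hat is None:
        u_hat = line.points[-1] - line.points[0]
        u_hat = u_hat / np.hypot(*u_hat)
    anchor = line.point_at(anchor_t * line.length)
    r = pts.astype(float).copy()
    if f:
        r[far] -= f * u_hat
    if twist_deg:
        from sedlab._geometry import rotation_matrix_storage
        pivot = anchor + f * u_hat
        rot = rotation_matrix_storage(-twist_deg)
        r[far] = (r[far] - pivot) @ rot.T + pivot
    d = (r - anchor) @ unit_from_azimuth(phi)
    img = peak * np.exp(-d.reshape(ny, nx) ** 2 / (2 * width_nm**2))
    if noise_seed is not None:
        img = np.random.default_rng(noise_seed).poisson(img).astype(float)
    g = GVector(k=0.3 * np.array([np.cos(np.radians(phi)),
                                  np.sin(np.radians(phi))]), phi=float(phi))
    return VDFImage(img, g, 0.02, step), anchor


def planted_f(phi, A=12.0, B=2.5, C=65.0):
    return float(model_f(phi, A, B, C))
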