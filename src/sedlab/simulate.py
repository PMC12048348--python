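"""Ground-truthed synthetic 4D datasets of a bent thin crystal containing an
in-plane dislocation.

The scene is deliberately geometric: each reflection g produces one straight
bend contour, oriented perpendicular to the scan-frame g direction
(spherical-curvature limit of a slowly, irregularly bent film), anchored at
a seeded point on the dislocation line so that every contour crosses the
line inside the field of view.  On the far side of the line the contour
locus is rigidly displaced along the line by ``f(phi) = A*arctan(B*cos^2
(phi-C))`` — the displacement law is planted directly, because the purpose
of the generator is closed-loop validation of the measurement-and-fit
chain, not of an elasticity model.  Contour intensity follows a Gaussian
rocking profile in the deviation variable; counts are Poisson at a per-
pattern dose of ``current*dwell/e`` (about 6.2e3 electrons at 1 pA x 1 ms).
Optional extras: a handedness twist of the contours whose g lies near the
line direction, and a uniform mid-scan contour jump emulating stage/beam
reorientation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import ang_sep_mod180, azimuth_math, rotation_matrix_storage, \
    unit_from_azimuth, wrap_180, wrap_360
from .burgers import model_f
from .contours import DislocationLine
from .datamodel import Dataset4D
from .io import save_dataset
from .optics import AcquisitionGeometry, electrons_per_pattern

__all__ = [
    "Reflection",
    "SimulationSpec",
    "GroundTruth",
    "simulate_dataset",
    "expected_counts",
    "standard_spec",
    "FIXTURE_KINDS",
    "fixture_spec",
    "make_fixture_suite",
]


@dataclass
class Reflection:
    """One planted reflection: detector k-vector (1/A, y-up), contour width
    (nm, Gaussian sigma of the band) and peak intensity fraction of dose."""

    k: tuple
    width_nm: float = 16.0
    strength: float = 0.05
    hkl: tuple | None = None


@dataclass
class SimulationSpec:
    """Everything needed to render one dataset, all randomness from `seed`."""

    scan_shape: tuple = (64, 64)
    scan_step: float = 4.0  # nm / scan px
    detector_shape: tuple = (96, 96)
    detector_cal: float = 0.012  # 1/A / detector px
    rotation_offset: float = 0.0  # deg, detector -> scan azimuth
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    reflections: list = field(default_factory=list)
    curvature_radius_um: float = 2.0  # recorded effective curvature scale
    curvature_skew_deg: float = 35.0  # contour-orientation spread about g
    line: DislocationLine | None = None
    A_true: float = 12.0  # nm
    B_true: float = 2.5
    C_true: float = 60.0  # deg, rotation-corrected frame
    handedness: int = 0  # +1 right, -1 left, 0 none
    twist_deg: float = 10.0
    artifact_row: int | None = None
    artifact_shift_px: float = 3.0
    dose: float | None = None  # electrons / pattern; default current*dwell/e
    sigma_disc_px: float = 1.7
    seed: int = 0

    def __post_init__(self):
        if self.A_true < 0:
            raise ValueError("A_true must be >= 0")
        ny, nx = self.detector_shape
        cal = self.detector_cal
        half = (min(ny, nx) - 1) / 2.0 * cal
        for r in self.reflections:
            if np.hypot(*r.k) > half:
                raise ValueError(f"reflection {r.k} outside the detector")
        min_sep = 0.08  # one disc diameter at 300 kV
        for i, r in enumerate(self.reflections):
            for r2 in self.reflections[i + 1:]:
                if np.hypot(r.k[0] - r2.k[0], r.k[1] - r2.k[1]) < min_sep:
                    raise ValueError(
                        f"reflections {r.k} and {r2.k} overlap within one "
                        "disc diameter")


@dataclass
class GroundTruth:
    """What was planted, for closed-loop comparison."""

    seed: int
    A_true: float
    B_true: float
    C_true: float | None
    b_azimuth: float | None  # deg mod 180, scan frame (None when A=0)
    u_azimuth: float | None
    handedness: str  # right | left | none
    dose: float
    artifact_rows: list
    line_points_nm: list
    positive_sense: int
    reflections: list  # dicts: phi_scan, phi_detector, k, f_nm, anchor_nm, ...

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


def expected_counts(spec: SimulationSpec) -> float:
    """Expected electrons per pattern: ``current*dwell/e`` or the explicit
    dose override."""
    if spec.dose is not None:
        return float(spec.dose)
    return electrons_per_pattern(spec.geometry)


def _gauss_stamp(shape_yx, center_xy, sigma):
    """Gaussian disc rendered at a fractional detector position, sum = 1.
    Returns (slice_y, slice_x, stamp) or None if fully outside."""
    ny, nx = shape_yx
    cx, cy = center_xy
    h = int(np.ceil(3 * sigma)) + 1
    y0, y1 = int(np.floor(cy)) - h, int(np.floor(cy)) + h + 1
    x0, x1 = int(np.floor(cx)) - h, int(np.floor(cx)) + h + 1
    y0c, y1c = max(y0, 0), min(y1, ny)
    x0c, x1c = max(x0, 0), min(x1, nx)
    if y0c >= y1c or x0c >= x1c:
        return None
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    st = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    s = st.sum()
    if s <= 0:
        return None
    return slice(y0c, y1c), slice(x0c, x1c), st / s


def simulate_dataset(spec: SimulationSpec):
    """Render the 4D stack and its ground truth.

    Per reflection the deviation from the Bragg condition is a linear ramp
    across the field (zero on the contour locus); disc intensity is
    ``strength * dose * exp(-s^2/2)`` with the band width set per
    reflection; the direct beam carries the residual so the expected
    per-pattern total equals the dose exactly.  Counts are Poisson, seeded.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.scan_shape
    dy, dx = spec.detector_shape
    step = spec.scan_step
    dose = expected_counts(spec)
    bc = ((dx - 1) / 2.0, (dy - 1) / 2.0)

    xs = np.arange(nx) * step
    ys = np.arange(ny) * step
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])

    line = spec.line
    if line is not None:
        far = (np.asarray(line.side_of(pts)).reshape(ny, nx) > 0)
        u_hat = (line.points[-1] - line.points[0])
        u_hat = u_hat / np.hypot(*u_hat)  # stored-order direction
        u_az = line.u_azimuth
        length = line.length
    else:
        far = np.zeros((ny, nx), dtype=bool)
        u_hat = np.array([1.0, 0.0])
        u_az = None
        length = 0.0

    art_rows = np.zeros((ny, nx), dtype=bool)
    if spec.artifact_row is not None:
        art_rows[int(spec.artifact_row):, :] = True
    delta_art = spec.artifact_shift_px * step * unit_from_azimuth(35.0)

    expected = np.zeros((ny, nx, dy, dx), dtype=np.float32)
    total_frac = np.zeros((ny, nx))
    gt_reflections = []
    for refl in spec.reflections:
        kx, ky_up = refl.k
        phi_det = float(azimuth_math(kx, ky_up))
        phi_scan = float(wrap_360(phi_det + spec.rotation_offset))
        # the deviation gradient is parallel to g only for pure spherical
        # bending; generic slowly-varying curvature skews the contour
        # orientation per reflection
        skew = float(rng.uniform(-spec.curvature_skew_deg,
                                 spec.curvature_skew_deg))
        g_hat = unit_from_azimuth(phi_scan + skew)  # across-band unit
        f_nm = float(model_f(phi_scan, spec.A_true, spec.B_true, spec.C_true)) \
            if (line is not None and spec.A_true > 0) else 0.0
        if line is not None:
            anchor = line.point_at(float(rng.uniform(0.38, 0.62)) * length)
        else:
            anchor = np.array([xs.mean(), ys.mean()]) + rng.uniform(
                -0.2, 0.2, size=2) * min(xs.max(), ys.max())

        r_eval = pts.astype(float).copy()
        if line is not None and f_nm != 0.0:
            r_eval[far.ravel()] -= f_nm * u_hat
        twisted = False
        if (line is not None and spec.handedness != 0
                and ang_sep_mod180(phi_scan, u_az) <= 20.0):
            twisted = True
            pivot = anchor + f_nm * u_hat
            rot = rotation_matrix_storage(-spec.handedness * spec.twist_deg)
            fr = far.ravel()
            r_eval[fr] = (r_eval[fr] - pivot) @ rot.T + pivot
        d_perp = (r_eval - anchor) @ g_hat
        d_perp = d_perp.reshape(ny, nx)
        d_perp = d_perp + (delta_art @ g_hat) * art_rows
        inten = refl.strength * np.exp(-d_perp**2 / (2 * refl.width_nm**2))
        total_frac += inten

        disc_center = (bc[0] + kx / spec.detector_cal,
                       bc[1] - ky_up / spec.detector_cal)
        stamp = _gauss_stamp((dy, dx), disc_center, spec.sigma_disc_px)
        if stamp is not None:
            sy, sx, st = stamp
            expected[:, :, sy, sx] += (dose * inten)[:, :, None, None] \
                * st.astype(np.float32)
        crossing_angle = None
        if line is not None:
            contour_az = wrap_180(phi_scan + skew + 90.0)
            crossing_angle = float(ang_sep_mod180(contour_az, u_az))
        gt_reflections.append({
            "k": [float(kx), float(ky_up)],
            "hkl": list(refl.hkl) if refl.hkl else None,
            "phi_detector": phi_det,
            "phi_scan": phi_scan,
            "f_nm": f_nm,
            "curvature_skew_deg": skew,
            "anchor_nm": [float(anchor[0]), float(anchor[1])],
            "width_nm": refl.width_nm,
            "strength": refl.strength,
            "crossing_angle_deg": crossing_angle,
            "twisted": twisted,
        })

    if total_frac.max() >= 1.0:
        raise ValueError("reflection strengths exceed the dose budget")
    stamp0 = _gauss_stamp((dy, dx), bc, 2.0 * spec.sigma_disc_px)
    sy, sx, st = stamp0
    expected[:, :, sy, sx] += (dose * (1.0 - total_frac)
                               )[:, :, None, None] * st.astype(np.float32)

    counts = rng.poisson(expected).astype(np.uint32)
    ds = Dataset4D(
        counts,
        scan_step=step,
        detector_cal=spec.detector_cal,
        rotation_offset=spec.rotation_offset,
        beam_center=None,
        geometry=spec.geometry,
        flags=[f"synthetic seed={spec.seed}"],
    )
    gt = GroundTruth(
        seed=spec.seed,
        A_true=spec.A_true,
        B_true=spec.B_true,
        C_true=spec.C_true if spec.A_true > 0 else None,
        b_azimuth=(float(wrap_180(spec.C_true))
                   if (line is not None and spec.A_true > 0) else None),
        u_azimuth=u_az,
        handedness={1: "right", -1: "left", 0: "none"}[spec.handedness],
        dose=dose,
        artifact_rows=[int(spec.artifact_row)]
        if spec.artifact_row is not None else [],
        line_points_nm=line.points.tolist() if line is not None else [],
        positive_sense=line.positive_sense if line is not None else 1,
        reflections=gt_reflections,
    )
    return ds, gt


FIXTURE_KINDS = ("null", "edge", "screw", "mixed", "artifact", "lowdose")


def standard_spec(
    seed: int = 0,
    n_reflections: int = 10,
    A_true: float = 12.0,
    B_true: float = 2.5,
    C_true: float = 60.0,
    u_azimuth: float = 20.0,
    handedness: int = 1,
    dose: float | None = None,
    artifact_row: int | None = None,
    scan_shape=(64, 64),
    rotation_offset: float = 0.0,
) -> SimulationSpec:
    """The reference study conditions: a straight line through the field
    centre along ``u_azimuth``, ``n_reflections`` azimuths over [0, 180)
    (with slots forced exactly at C and C+90 for invisibility checks) plus
    a Friedel partner for the reflection nearest the line direction."""
    rng = np.random.default_rng(seed)
    ny, nx = scan_shape
    step = 4.0
    centre = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0]) * step
    half_len = 0.75 * min(nx, ny) * step
    u = unit_from_azimuth(u_azimuth)
    line = DislocationLine(np.array([centre - half_len * u,
                                     centre + half_len * u]))

    phis = np.linspace(0.0, 180.0, n_reflections, endpoint=False)
    phis = wrap_180(phis + rng.uniform(-4.0, 4.0, size=n_reflections))
    phis[int(np.argmin(ang_sep_mod180(phis, C_true)))] = wrap_180(C_true)
    phis[int(np.argmin(ang_sep_mod180(phis, C_true + 90.0)))] = \
        wrap_180(C_true + 90.0)
    mags = np.array([0.25, 0.33, 0.41, 0.49])[np.arange(n_reflections) % 4]

    det_phis = wrap_360(phis - rotation_offset)
    refl = [Reflection(k=(m * np.cos(np.radians(p)),
                          m * np.sin(np.radians(p))))
            for m, p in zip(mags, det_phis)]
    # Friedel partner of the reflection nearest u (for handedness analysis)
    i_near = int(np.argmin(ang_sep_mod180(phis, u_azimuth)))
    kx, ky = refl[i_near].k
    refl.append(Reflection(k=(-kx, -ky)))

    return SimulationSpec(
        scan_shape=scan_shape,
        scan_step=step,
        rotation_offset=rotation_offset,
        reflections=refl,
        line=line,
        A_true=A_true,
        B_true=B_true,
        C_true=C_true,
        handedness=handedness,
        dose=dose,
        artifact_row=artifact_row,
        seed=seed,
    )


def fixture_spec(kind: str, seed: int = 0) -> SimulationSpec:
    """Named fixture conditions used throughout the test gallery."""
    u = 20.0
    if kind == "null":
        return standard_spec(seed, A_true=0.0, handedness=0, u_azimuth=u)
    if kind == "edge":
        return standard_spec(seed, C_true=u + 90.0, handedness=0, u_azimuth=u)
    if kind == "screw":
        return standard_spec(seed, C_true=u, handedness=1, u_azimuth=u)
    if kind == "mixed":
        return standard_spec(seed, C_true=u + 45.0, handedness=1, u_azimuth=u)
    if kind == "artifact":
        return standard_spec(seed, C_true=u + 45.0, handedness=1,
                             u_azimuth=u, artifact_row=54)
    if kind == "lowdose":
        # fluence-equivalent of ~5 e-/A^2 instead of the standard ~8.8
        lo = electrons_per_pattern(AcquisitionGeometry()) * 5.0 / 8.8
        return standard_spec(seed, C_true=u + 45.0, handedness=1,
                             u_azimuth=u, dose=lo)
    raise ValueError(f"unknown fixture kind {kind!r}; use one of "
                     f"{FIXTURE_KINDS}")


def make_fixture_suite(out_dir, base_seed: int = 0):
    """Write the documented fixture gallery with ground-truth sidecars.

    Deterministic given seeds: repeated runs produce byte-identical
    ground-truth JSON.  Returns the list of written dataset paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, kind in enumerate(FIXTURE_KINDS):
        spec = fixture_spec(kind, seed=base_seed + i)
        ds, gt = simulate_dataset(spec)
        h5 = out_dir / f"{kind}.h5"
        save_dataset(ds, h5)
        (out_dir / f"{kind}.truth.json").write_text(gt.to_json() + "\n")
        written.append(h5)
    return written
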