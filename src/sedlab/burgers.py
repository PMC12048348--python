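"""Azimuthal displacement model and Burgers-vector assignment.

The bend-contour displacement of an in-plane dislocation varies with the
diffraction-vector azimuth phi as::

    f(phi) = A * arctan(B * cos^2(phi - C))

with amplitude ``A`` (nm, set by the effective curvature), shape ``B``
(dimensionless) and phase ``C`` (deg).  ``f`` has period 180 deg, its
maximum ``A*arctan(B)`` at ``phi = C`` (the Burgers-vector azimuth) and
zeros at ``phi = C +/- 90`` (the g.B = 0 invisibility azimuths).  Fitting
``|displacement|`` versus phi therefore recovers the projected Burgers
direction up to the intrinsic 180 deg ambiguity; the twist sense of the
contours at the line (Cherns-Preston construction) resolves the screw
handedness, and integer bookkeeping ``g.B = n`` connects indexed
reflections to lattice Burgers vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import least_squares

from ._geometry import (ang_sep_mod180, azimuth_deg, signed_axial_delta,
                        wrap_180)
from .contours import DislocationLine, side_branch_fit, trace_contour
from .errors import (FitRefusedError, GeometryError, NoResolvableDistortion,
                     TraceError)

__all__ = [
    "model_f",
    "BurgersFit",
    "fit_displacement_model",
    "burgers_azimuth",
    "InvisibilityResult",
    "invisibility_set",
    "CharacterCall",
    "classify_character",
    "screw_handedness",
    "gb_integer",
]


def model_f(phi, A, B, C):
    """Azimuthal contour-displacement law ``A*arctan(B*cos^2(phi-C))``.

    All angles in degrees; vectorised over ``phi``.
    """
    c = np.cos(np.radians(np.asarray(phi, dtype=float) - C))
    return A * np.arctan(B * c * c)


@dataclass
class BurgersFit:
    """Result of the weighted azimuthal fit.

    ``status`` is ``"ok"`` or ``"no_resolvable_distortion"`` (all measured
    displacements consistent with zero; ``phase_C`` is then None).
    """

    amp_A: float
    shape_B: float
    phase_C: float | None
    ci: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None
    rms: float = np.nan
    status: str = "ok"
    ci_method: str = "residual-bootstrap"
    n_points: int = 0

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _span_deg(phi):
    """Azimuthal span mod 180: 180 minus the largest empty gap."""
    p = np.sort(np.mod(np.asarray(phi, dtype=float), 180.0))
    if len(p) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([p, [p[0] + 180.0]]))
    return 180.0 - float(gaps.max())


def _residual_factory(phi, d, w):
    def resid(theta):
        a, b, c = theta
        return (model_f(phi, a, b, c) - d) * w
    return resid


def fit_displacement_model(
    profile,
    n_boot: int = 199,
    seed: int = 0,
    zero_sigma: float = 2.0,
) -> BurgersFit:
    """Weighted nonlinear least squares of ``|displacement|`` versus azimuth.

    Requires >= 4 usable crossings spanning >= 60 deg of azimuth.  Weights
    are ``1/uncertainty^2``; initialisation is ``A0 = max|d|``, ``B0 = 1``
    with a multistart over ``C0 = phi_at_max + {0, 45, 90, 135}`` deg, the
    best-chi-square start winning.  When every displacement is within
    ``zero_sigma`` uncertainties of zero the profile carries no resolvable
    distortion and no fit is attempted.  95% confidence intervals come from
    a seeded residual bootstrap (method recorded on the result).
    """
    phi = profile.phi
    d = np.abs(profile.displacement)
    sig = np.clip(profile.uncertainty, 1e-9, None)
    n = len(phi)
    if n < 4 or _span_deg(phi) < 60.0:
        raise FitRefusedError(
            f"under-constrained profile: {n} usable points spanning "
            f"{_span_deg(phi):.0f} deg (need >= 4 over >= 60 deg)")
    # no resolvable distortion: every point individually consistent with
    # zero, or collectively so (mean squared z of |d| near its null value)
    if np.all(d <= zero_sigma * sig) or np.mean((d / sig) ** 2) <= zero_sigma**2:
        return BurgersFit(amp_A=0.0, shape_B=0.0, phase_C=None,
                          status="no_resolvable_distortion", n_points=n)

    imax = int(np.argmax(d))
    model = lmfit.Model(model_f, independent_vars=["phi"])
    best = None
    for dc in (0.0, 45.0, 90.0, 135.0):
        params = model.make_params(
            A=dict(value=max(d.max(), 1e-6), min=0.0),
            B=dict(value=1.0, min=1e-6),
            C=dict(value=float(phi[imax]) + dc),
        )
        try:
            res = model.fit(d, params, phi=phi, weights=1.0 / sig,
                            method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitRefusedError("all fit starts failed")

    a_hat = float(best.params["A"].value)
    b_hat = float(best.params["B"].value)
    c_hat = float(wrap_180(best.params["C"].value))
    if a_hat * np.arctan(b_hat) <= zero_sigma * float(np.median(sig)):
        # the fitted lobe amplitude never rises above the noise floor
        return BurgersFit(amp_A=0.0, shape_B=0.0, phase_C=None,
                          status="no_resolvable_distortion", n_points=n)
    fhat = model_f(phi, a_hat, b_hat, c_hat)
    resid = d - fhat
    rms = float(np.sqrt(np.mean(resid**2)))

    # seeded residual bootstrap for the confidence intervals; residuals of
    # a p-parameter fit under-represent the noise variance by (n-p)/n, so
    # they are rescaled before resampling (leverage correction)
    rng = np.random.default_rng(seed)
    z = (resid / sig) * np.sqrt(n / max(n - 3, 1))
    draws = np.empty((n_boot, 3))
    ok = 0
    for b in range(n_boot):
        dstar = fhat + sig * rng.choice(z, size=n, replace=True)
        try:
            sol = least_squares(
                _residual_factory(phi, dstar, 1.0 / sig),
                x0=[a_hat, b_hat, c_hat],
                bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            )
        except Exception:
            continue
        draws[ok] = sol.x
        ok += 1
    ci = {}
    if ok >= 20:
        from scipy import stats

        # small-sample inflation: bootstrap quantiles estimate the scale
        # from n points, so widen by t_{n-3}/z as a Student correction;
        # the phase interval is symmetrized (C errors are symmetric and
        # equal-tailed percentile intervals of an axial quantity
        # under-cover)
        tfac = float(stats.t.ppf(0.975, max(n - 3, 2)) / 1.959964)
        dr = draws[:ok]
        lo_a, hi_a = np.percentile(dr[:, 0], [2.5, 97.5])
        lo_b, hi_b = np.percentile(dr[:, 1], [2.5, 97.5])
        dc = signed_axial_delta(c_hat, dr[:, 2])
        lo_c, hi_c = np.percentile(dc, [2.5, 97.5])
        half_c = tfac * max(hi_c, -lo_c)
        ci = {"A": (float(a_hat - tfac * (a_hat - lo_a)),
                    float(a_hat + tfac * (hi_a - a_hat))),
              "B": (float(max(b_hat - tfac * (b_hat - lo_b), 0.0)),
                    float(b_hat + tfac * (hi_b - b_hat))),
              "C": (float(c_hat - half_c), float(c_hat + half_c))}
    return BurgersFit(amp_A=a_hat, shape_B=b_hat, phase_C=c_hat, ci=ci,
                      residuals=resid, rms=rms, status="ok",
                      ci_method="residual-bootstrap", n_points=n)


def burgers_azimuth(fit: BurgersFit, rotation_offset: float = 0.0) -> float:
    """Burgers-vector azimuth ``(C + rotation_offset) mod 180`` in degrees.

    Profile azimuths are already rotation-corrected, so the offset is only
    for any *additional* frame change.  The 180 deg ambiguity is intrinsic.
    """
    if not fit.ok or fit.phase_C is None:
        raise NoResolvableDistortion(
            "no resolvable distortion: Burgers azimuth undefined")
    return float(wrap_180(fit.phase_C + rotation_offset))


@dataclass
class InvisibilityResult:
    """g-vectors consistent with the g.B = 0 invisibility criterion."""

    gvectors: list
    note: str = ""


def invisibility_set(
    profile,
    fit: BurgersFit,
    zero_tol: float = 2.0,
    angle_tol: float = 10.0,
) -> InvisibilityResult:
    """g-vectors whose displacement is zero within ``zero_tol`` uncertainties
    *and* whose azimuth lies within ``angle_tol`` of ``C +/- 90``."""
    if not fit.ok:
        raise NoResolvableDistortion("fit carries no resolvable distortion")
    target = wrap_180(fit.phase_C + 90.0)
    near, invisible = [], []
    for c in profile.usable:
        if ang_sep_mod180(c.g.phi, target) <= angle_tol:
            near.append(c)
            if abs(c.displacement) <= zero_tol * c.uncertainty:
                invisible.append(c.g)
    note = "" if near else (
        "unconstrained invisibility: no usable g within "
        f"{angle_tol:g} deg of C+/-90")
    return InvisibilityResult(gvectors=invisible, note=note)


@dataclass
class CharacterCall:
    """Dislocation character from the angle between B and the line u."""

    angle_Bu: float
    label: str  # edge | screw | mixed | undetermined
    handedness: str = "undetermined"  # left | right | undetermined
    edge_component_azimuth: float | None = None


def classify_character(
    b_azimuth: float | None,
    line,
    screw_tol: float = 15.0,
    edge_tol: float = 15.0,
) -> CharacterCall:
    """Classify edge/screw/mixed from the acute angle between the Burgers
    azimuth and the line direction (B || u -> screw, B perp u -> edge).

    ``line`` may be a :class:`DislocationLine` or a plain azimuth in deg.
    """
    if b_azimuth is None:
        return CharacterCall(angle_Bu=np.nan, label="undetermined")
    u_az = line.u_azimuth if isinstance(line, DislocationLine) else float(line)
    angle = float(ang_sep_mod180(b_azimuth, u_az))
    if angle <= screw_tol:
        label = "screw"
    elif angle >= 90.0 - edge_tol:
        label = "edge"
    else:
        label = "mixed"
    edge_az = None if label == "screw" else float(wrap_180(u_az + 90.0))
    return CharacterCall(angle_Bu=angle, label=label,
                         edge_component_azimuth=edge_az)


def classify_segments(b_azimuth, line: DislocationLine, **kw):
    """Per-segment character calls along a curved dislocation line."""
    out = []
    for d in line.segment_directions():
        from ._geometry import azimuth_deg
        out.append(classify_character(b_azimuth,
                                      float(wrap_180(azimuth_deg(d[0], d[1]))),
                                      **kw))
    return out


def screw_handedness(
    vdf_pair,
    line: DislocationLine,
    seeds_fn=None,
    align_tol: float = 20.0,
    noise_floor_deg: float = 2.0,
    smoothing: float | None = None,
    excluded_rows=(),
) -> str:
    """Handedness of the screw component from the contour twist at the line.

    Expects the two VDFs of a Friedel pair with g within ``align_tol`` of
    the line direction (the screw-component azimuth).  For each VDF the
    centerline direction of the contour segment on either side of the line
    is fitted; the signed rotation from near-side to far-side direction
    (y-up frame, axial) is the twist.  A consistent positive twist across
    the pair is reported ``"right"``, negative ``"left"``; disagreement or a
    twist below ``noise_floor_deg`` is ``"undetermined"``.
    """
    from .contours import (_axis_direction, _axis_intersect,
                           _branch_selection, auto_seeds)
    from ._geometry import cross_z_math
    u_az = line.u_azimuth
    for v in vdf_pair:
        sep = float(ang_sep_mod180(v.g.phi, u_az))
        if sep > align_tol:
            raise ValueError(
                f"g at phi={v.g.phi:.1f} deg is {sep:.1f} deg from the line "
                f"direction; handedness needs g within {align_tol:g} deg of u")
    calls = []
    for v in vdf_pair:
        try:
            seeds = seeds_fn(v) if seeds_fn else auto_seeds(v, line)
            traces = {}
            for s in seeds:
                sd = float(line.side_of(s))
                traces[sd] = trace_contour(v, s, smoothing,
                                           side_gate=(line, sd),
                                           excluded_rows=excluded_rows)
            width_px = float(np.median(np.concatenate(
                [t.widths_px for t in traces.values()])))
            sigma = (smoothing / v.scan_step) if smoothing else 2.0
            standoff = (max(2.0, 0.25 * width_px) + 1.0 * sigma) * v.scan_step
            geo = {}
            for sd, tr in traces.items():
                sel, _ = _branch_selection(tr, line, sd, standoff,
                                           barrier_rows=tuple(excluded_rows))
                mean, axis = _axis_direction(sel)
                pt, _ = _axis_intersect(mean, axis, line)
                # orient the branch direction away from the line
                t_away = axis if (mean - pt) @ axis > 0 else -axis
                geo[sd] = (pt, t_away)
        except (TraceError, GeometryError):
            continue
        if set(geo) != {1.0, -1.0}:
            continue
        twist = float(signed_axial_delta(
            azimuth_deg(*geo[-1.0][1]), azimuth_deg(*geo[1.0][1])))
        if abs(twist) < noise_floor_deg:
            calls.append(0.0)
            continue
        d = line.arclength_of(geo[1.0][0]) - line.arclength_of(geo[-1.0][0])
        if d == 0.0:
            calls.append(0.0)
            continue
        # chirality invariant: sign(displacement) * sign(t_near x t_far).
        # Mirror-odd (the cross product flips, the displacement does not),
        # rotation-even, and independent of which side is called "near"
        # (both factors flip together).  With the generator's convention a
        # right-handed screw twist gives a negative invariant.
        chi = np.sign(d) * np.sign(cross_z_math(geo[-1.0][1], geo[1.0][1]))
        calls.append(float(chi))
    if not calls or any(c == 0.0 for c in calls):
        return "undetermined"
    if len(set(calls)) > 1:
        return "undetermined"
    return "right" if calls[0] < 0 else "left"


def gb_integer(g_hkl, b_uvw) -> int:
    """Integer ``g . B = h*u + k*v + l*w`` (zero is the invisibility case)."""
    h, k, l = (int(x) for x in g_hkl)  # noqa: E741
    u, v, w = (int(x) for x in b_uvw)
    return h * u + k * v + l * w
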