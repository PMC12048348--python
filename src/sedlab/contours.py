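"""Bend-contour centerline tracing and displacement metrology.

A bend contour in a VDF image is the bright band where the locally curved
crystal meets the exact Bragg condition for that g-vector.  Where the band
crosses a dislocation line it is broken and displaced; the displacement is
measured as the distance *along the dislocation line* between the middles
of the two contour segments.  "Middle" is estimated per perpendicular cut
as the intensity centroid over the full-width-half-maximum band, which also
yields a contour width and a Poisson standard error per cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._geometry import (ang_sep_mod180, azimuth_deg, cross_z_math,
                        unit_from_azimuth, wrap_180)
from .discs import VDFImage
from .errors import EmptyProfileError, GeometryError, TraceError

__all__ = [
    "DislocationLine",
    "ContourTrace",
    "ContourCrossing",
    "DisplacementProfile",
    "trace_contour",
    "measure_displacement",
    "detect_uniform_shift",
    "build_profile",
    "auto_seeds",
]


@dataclass
class DislocationLine:
    """An in-plane dislocation line as an ordered scan-frame polyline (nm).

    ``points`` is ``(N, 2)`` with columns ``(x, y)`` in storage orientation
    (y down); azimuths are reported y-up like everywhere else.
    ``positive_sense`` (+1/-1) picks the direction along the stored order in
    which displacements are counted positive; the *side* labelling used for
    near/far bookkeeping follows the stored point order only, so flipping
    ``positive_sense`` negates measured displacements without relabelling
    sides.
    """

    points: np.ndarray
    positive_sense: int = 1

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 2:
            raise ValueError("polyline must be (N>=2, 2)")
        if np.any(np.all(np.diff(p, axis=0) == 0, axis=1)):
            raise ValueError("consecutive polyline points must be distinct")
        if self.positive_sense not in (-1, 1):
            raise ValueError("positive_sense must be +1 or -1")
        self.points = p

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def segment_directions(self) -> np.ndarray:
        d = np.diff(self.points, axis=0)
        return d / np.hypot(d[:, 0], d[:, 1])[:, None]

    @property
    def direction(self) -> np.ndarray:
        """Overall unit direction including ``positive_sense``."""
        d = self.points[-1] - self.points[0]
        return self.positive_sense * d / np.hypot(*d)

    @property
    def u_azimuth(self) -> float:
        """Axial line direction in degrees (y-up frame, mod 180)."""
        d = self.points[-1] - self.points[0]
        return float(wrap_180(azimuth_deg(d[0], d[1])))

    def point_at(self, s: float) -> np.ndarray:
        """Point at arclength ``s`` from the first stored point."""
        segs = np.diff(self.points, axis=0)
        lens = np.hypot(segs[:, 0], segs[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum[1:], s, side="right"))
        i = min(i, len(segs) - 1)
        t = (s - cum[i]) / lens[i]
        return self.points[i] + t * segs[i]

    def side_of(self, pts) -> np.ndarray:
        """Sign (+1/0/-1) of the side of each point w.r.t. the stored order.

        Computed against the nearest segment; +1 is the y-up mathematical
        left of the stored direction.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        segs = np.diff(self.points, axis=0)
        lens2 = np.sum(segs**2, axis=1)
        best_d2 = np.full(len(pts), np.inf)
        side = np.zeros(len(pts))
        for a, seg, l2 in zip(self.points[:-1], segs, lens2):
            t = np.clip(((pts - a) @ seg) / l2, 0.0, 1.0)
            proj = a + t[:, None] * seg
            d2 = np.sum((pts - proj) ** 2, axis=1)
            better = d2 < best_d2
            if better.any():
                cz = cross_z_math(np.broadcast_to(seg, pts.shape), pts - a)
                side[better] = np.sign(cz[better])
                best_d2[better] = d2[better]
        return side if side.size > 1 else side[0]

    def arclength_of(self, pt) -> float:
        """Signed arclength parameter of the projection of ``pt``.

        Measured from the first stored point along ``positive_sense``.
        """
        pt = np.asarray(pt, dtype=float)
        segs = np.diff(self.points, axis=0)
        lens = np.hypot(segs[:, 0], segs[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        best, s_best = np.inf, 0.0
        for i, (a, seg, ln) in enumerate(zip(self.points[:-1], segs, lens)):
            t = float(np.clip((pt - a) @ seg / ln**2, 0.0, 1.0))
            proj = a + t * seg
            d = float(np.hypot(*(pt - proj)))
            if d < best:
                best, s_best = d, cum[i] + t * ln
        s = s_best if self.positive_sense > 0 else self.length - s_best
        return float(s)


@dataclass
class ContourTrace:
    """A traced bend-contour centerline in scan-pixel coordinates."""

    points_px: np.ndarray
    widths_px: np.ndarray
    se_px: np.ndarray
    complete: bool = True
    scan_step: float = 1.0

    @property
    def points_nm(self) -> np.ndarray:
        return self.points_px * self.scan_step


@dataclass
class ContourCrossing:
    """One bend-contour displacement measurement at a dislocation line."""

    g: object
    displacement: float = np.nan  # nm, signed along positive_sense
    uncertainty: float = np.nan  # nm
    usable: bool = True
    contour_width: float = np.nan  # nm
    reason: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class DisplacementProfile:
    """Per-g displacement measurements versus azimuth."""

    crossings: list
    phi_convention: str = "detector frame, rotation-corrected, y-up"

    @property
    def usable(self):
        return [c for c in self.crossings if c.usable]

    @property
    def phi(self):
        return np.array([c.g.phi for c in self.usable])

    @property
    def displacement(self):
        return np.array([c.displacement for c in self.usable])

    @property
    def uncertainty(self):
        return np.array([c.uncertainty for c in self.usable])


def _orientation_field(sm, sigma):
    """Across-band orientation (radians, storage frame) from the structure
    tensor of the smoothed image."""
    gy = ndimage.gaussian_filter(sm, sigma, order=(1, 0))
    gx = ndimage.gaussian_filter(sm, sigma, order=(0, 1))
    jxx = ndimage.gaussian_filter(gx * gx, 2 * sigma)
    jyy = ndimage.gaussian_filter(gy * gy, 2 * sigma)
    jxy = ndimage.gaussian_filter(gx * gy, 2 * sigma)
    return jxx, jyy, jxy


def _across_dir(jxx, jyy, jxy, pt):
    """Unit vector across the band at a (col,row) float point."""
    coords = [[pt[1]], [pt[0]]]
    xx = ndimage.map_coordinates(jxx, coords, order=1)[0]
    yy = ndimage.map_coordinates(jyy, coords, order=1)[0]
    xy = ndimage.map_coordinates(jxy, coords, order=1)[0]
    theta = 0.5 * np.arctan2(2 * xy, xx - yy)
    return np.array([np.cos(theta), np.sin(theta)])  # (x, y_down)


def _sample(img, pts, order=1):
    return ndimage.map_coordinates(img, [pts[:, 1], pts[:, 0]], order=order,
                                   mode="constant", cval=0.0)


def _recenter_cut(sm, raw, pt, across, half, bg, thr, gate=None):
    """Half-maximum-band centroid of one perpendicular cut.

    Weights are ``max(profile - half_level, 0)``, which vanish continuously
    at the band edges (no quantisation jitter as the band slides across the
    sample grid).  Cuts whose band is clipped by the image border, the cut
    window or a side gate are rejected (None), as are cuts with no signal
    above threshold.  ``gate(points_px) -> bool`` marks samples that may
    contribute (used to keep cuts on one side of a dislocation line).
    """
    offs = np.arange(-half, half + 1, dtype=float)
    pts = pt[None, :] + offs[:, None] * across[None, :]
    ny, nx = sm.shape
    ok = ((pts[:, 0] >= 0) & (pts[:, 0] <= nx - 1)
          & (pts[:, 1] >= 0) & (pts[:, 1] <= ny - 1))
    if gate is not None:
        ok &= gate(pts)
    if ok.sum() < 5:
        return None
    prof = _sample(sm, pts)
    prof = np.where(ok, prof, 0.0)
    imax = int(np.argmax(prof))
    if prof[imax] <= thr:
        return None
    half_level = bg + 0.5 * (prof[imax] - bg)
    w = np.clip(prof - half_level, 0.0, None)
    if w[0] > 0 or w[-1] > 0:
        return None  # band clipped by the cut window
    pos = np.flatnonzero(w > 0)
    lo, hi = int(pos[0]), int(pos[-1])
    if (~ok[max(lo - 1, 0):hi + 2]).any():
        return None  # band clipped by the border or the side gate
    ws = w.sum()
    if ws <= 0:
        return None
    # weights vanish continuously at the band edges, so the centroid is free
    # of support-quantisation jitter as the band slides across the grid
    m = float((offs * w).sum() / ws)
    band = w > 0
    # refine on the raw counts with a symmetric soft window (mean shift):
    # unbiased for a symmetric band, and immune to the one-sided bias the
    # smoothing kernel acquires near a mask or image boundary
    raw_prof = np.clip(_sample(raw, pts), 0.0, None)
    raw_prof[~ok] = 0.0
    sw = max(1.5, 0.35 * band.sum())
    for _ in range(4):
        g = np.exp(-0.5 * ((offs - m) / sw) ** 2)
        wr = raw_prof * g
        tot = wr.sum()
        if tot <= 0:
            break
        m = float((offs * wr).sum() / tot)
    counts = raw_prof[band]
    tot = counts.sum()
    if tot > 0:
        var = float((counts * (offs[band] - m) ** 2).sum()) / tot**2
        se = np.sqrt(max(var, 1e-6))
    else:
        se = float(band.sum())
    centre = pt + m * across
    width = float(band.sum())
    return centre, width, se


def trace_contour(
    vdf: VDFImage,
    seed_point,
    smoothing: float | None = None,
    max_miss: int = 3,
    excluded_rows=(),
    side_gate=None,
) -> ContourTrace:
    """Trace the ridge of a bend contour from a seed point.

    ``seed_point`` is ``(x, y)`` in nm (scan frame); ``smoothing`` is the
    Gaussian pre-smoothing length in nm (default two scan pixels).  The
    centerline is marched one pixel at a time in both directions along the
    local band orientation, re-centred at every step on the FWHM-band
    intensity centroid of the perpendicular cut.  Tracing stops at the image
    border, or flags the trace partial when the ridge intensity stays below
    background for more than ``max_miss`` consecutive cuts.

    ``side_gate = (line, side)`` restricts every cut to samples on one side
    of a dislocation line; cuts whose half-maximum band would be clipped by
    the gate are dropped, so the kept centerline points belong to one
    contour segment only.
    """
    step = vdf.scan_step
    img = np.asarray(vdf.image, dtype=float)
    sigma = (smoothing / step) if smoothing else 2.0
    if side_gate is not None:
        # normalized masked convolution: smoothing must not mix intensity
        # across the dislocation line, or near-junction centroids inherit
        # the other segment's displacement
        gline, gside = side_gate
        nyg, nxg = img.shape
        yy, xx = np.mgrid[:nyg, :nxg]
        gpts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float) * step
        smask = (np.asarray(gline.side_of(gpts)).reshape(nyg, nxg)
                 == gside).astype(float)
        den = ndimage.gaussian_filter(smask, sigma)
        sm = ndimage.gaussian_filter(img * smask, sigma) \
            / np.maximum(den, 1e-6)
    else:
        sm = ndimage.gaussian_filter(img, sigma)
    bg = float(np.median(sm))
    noise = 1.4826 * float(np.median(np.abs(sm - bg)))
    thr = bg + 2.0 * noise
    seed = np.asarray(seed_point, dtype=float) / step
    ny, nx = img.shape
    if not (0 <= seed[0] <= nx - 1 and 0 <= seed[1] <= ny - 1):
        raise TraceError("seed point outside the image")
    if _sample(sm, seed[None, :])[0] <= thr:
        raise TraceError("seed point lies on background")

    jxx, jyy, jxy = _orientation_field(sm, max(sigma, 1.0))
    half = max(6, int(4 * sigma) + 4)
    excluded = set(int(r) for r in excluded_rows)

    gate = None
    if side_gate is not None:
        gline, gside = side_gate

        def gate(pts_px):
            return np.asarray(gline.side_of(pts_px * step)) == gside

    first = _recenter_cut(sm, img, seed, _across_dir(jxx, jyy, jxy, seed),
                          half, bg, thr, gate)
    if first is None:
        raise TraceError("no ridge at the seed point")

    complete = True
    branches = []
    across0 = _across_dir(jxx, jyy, jxy, seed)
    for sgn in (1.0, -1.0):
        pts, widths, ses = [], [], []
        cur = np.array(first[0])
        prev_along = sgn * np.array([-across0[1], across0[0]])
        miss = 0
        for _ in range(4 * max(ny, nx)):
            across = _across_dir(jxx, jyy, jxy, cur)
            along = np.array([-across[1], across[0]])
            # structure-tensor orientation is axial: keep march continuity
            if along @ prev_along < 0:
                along = -along
            prev_along = along
            nxt = cur + along
            if not (1 <= nxt[0] <= nx - 2 and 1 <= nxt[1] <= ny - 2):
                break
            res = _recenter_cut(sm, img, nxt, _across_dir(jxx, jyy, jxy, nxt),
                                half, bg, thr, gate)
            if res is None:
                miss += 1
                cur = nxt
                if miss > max_miss:
                    complete = False
                    break
                continue
            miss = 0
            cur = np.array(res[0])
            if int(round(cur[1])) in excluded:
                continue
            pts.append(res[0])
            widths.append(res[1])
            ses.append(res[2])
        branches.append((pts, widths, ses))

    fwd, bwd = branches
    pts = list(reversed(bwd[0])) + [first[0]] + fwd[0]
    widths = list(reversed(bwd[1])) + [first[1]] + fwd[1]
    ses = list(reversed(bwd[2])) + [first[2]] + fwd[2]
    if len(pts) < 3:
        raise TraceError("ridge lost immediately; contour too short to trace")
    return ContourTrace(np.asarray(pts), np.asarray(widths), np.asarray(ses),
                        complete=complete, scan_step=step)


def _dist_to_polyline(pts, line: DislocationLine):
    """Perpendicular distance (nm) of each point from the line polyline."""
    return _project_to_polyline(pts, line)[0]


def _project_to_polyline(pts, line: DislocationLine):
    """Distance (nm) and nearest point on the polyline for each point."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    dist = np.full(len(pts), np.inf)
    nearest = np.zeros_like(pts)
    for a, b in zip(line.points[:-1], line.points[1:]):
        seg = b - a
        l2 = seg @ seg
        t = np.clip(((pts - a) @ seg) / l2, 0.0, 1.0)
        proj = a + t[:, None] * seg
        d = np.hypot(*(pts - proj).T)
        better = d < dist
        dist[better] = d[better]
        nearest[better] = proj[better]
    return dist, nearest


def _branch_selection(trace, line, side, standoff_nm, n_fit=24,
                      barrier_rows=()):
    """Clean centerline points of one contour segment near the junction.

    Keeps trace points on the requested side, beyond the standoff, not
    separated from their line projection by a flagged reorientation row
    (``barrier_rows``), sorted by distance to the line, at most ``n_fit``.
    Returns ``(points_nm, se_meas_nm)``.
    """
    pts = trace.points_nm
    sides = np.asarray(line.side_of(pts))
    dist, nearest = _project_to_polyline(pts, line)
    keep = (sides == side) & (dist >= standoff_nm)
    if barrier_rows:
        # a flagged reorientation row between a point and its projection on
        # the line means the point sits in a rigidly shifted regime
        rows = trace.points_px[:, 1]
        proj_rows = nearest[:, 1] / trace.scan_step
        for b in barrier_rows:
            lo = np.minimum(rows, proj_rows)
            hi = np.maximum(rows, proj_rows)
            keep &= ~((lo <= b) & (b <= hi))
    if keep.sum() < 6:
        raise GeometryError(
            f"too few centerline points on side {side:+.0f} of the line"
            + (" clear of flagged reorientation rows" if barrier_rows else ""))
    idx = np.flatnonzero(keep)
    idx = idx[np.argsort(dist[idx])][:n_fit]
    se_meas = float(np.median(trace.se_px[idx])) * trace.scan_step
    return pts[idx], se_meas


def _axis_direction(sel):
    """Principal axis (total least squares) of a point cloud."""
    mean = sel.mean(axis=0)
    _, _, vt = np.linalg.svd(sel - mean)
    return mean, vt[0]


def _axis_intersect(mean, v, line):
    """Intersection of the infinite line (mean, v) with the polyline;
    returns ``(point, extrapolation_distance)``."""
    best = None
    for a, b in zip(line.points[:-1], line.points[1:]):
        seg = b - a
        den = v[0] * seg[1] - v[1] * seg[0]
        if den == 0:
            continue
        qp = a - mean
        t = (qp[0] * seg[1] - qp[1] * seg[0]) / den
        uu = (qp[0] * v[1] - qp[1] * v[0]) / den
        if -1e-9 <= uu <= 1 + 1e-9:
            pt = mean + t * v
            if best is None or abs(t) < best[0]:
                best = (abs(t), pt)
    if best is None:
        raise GeometryError(
            "extrapolated centerline does not intersect the dislocation line")
    return best[1], best[0]


def _crossing_se(sel, mean, v, se_meas, d_ext, sigma_dir=None,
                 corr_cuts=3.0):
    """Standard error of the extrapolated crossing perpendicular to the band:
    point scatter about the axis plus the axis-direction error amplified by
    the extrapolation lever arm.

    Successive cuts share intensity through the detection smoothing, so
    their centroid errors are correlated over ~``corr_cuts`` cuts; the
    direction variance is inflated accordingly (the linear component of a
    correlated drift is absorbed by the fitted axis and invisible in its
    residuals, so the naive formula underestimates it).
    """
    n = len(sel)
    perp = np.array([-v[1], v[0]])
    resid = (sel - mean) @ perp
    sigma_perp = max(float(resid.std(ddof=1)) if n > 2 else se_meas, se_meas)
    if sigma_dir is None:
        ss_t = float((((sel - mean) @ v) ** 2).sum())
        sigma_dir = sigma_perp * np.sqrt(corr_cuts / max(ss_t, 1e-9))
    return float(np.sqrt(sigma_perp**2 * corr_cuts / n
                         + (d_ext * sigma_dir) ** 2))


def side_branch_fit(
    trace: ContourTrace,
    line: DislocationLine,
    side: float,
    standoff_nm: float,
    n_fit: int = 24,
    barrier_rows=(),
):
    """Extrapolate one contour segment's centerline to the dislocation line.

    Cuts blended by the other segment near the junction are excluded: only
    trace points on the requested ``side`` of the line (stored-order
    convention) and at least ``standoff_nm`` away are kept.  A principal-axis
    (total least squares) line through the ``n_fit`` kept points nearest the
    junction is intersected with the line polyline.

    ``barrier_rows`` (scan rows flagged as mid-scan reorientation jumps)
    truncate the usable points: contour positions beyond such a row belong
    to a rigidly shifted regime and would bias the fit.

    Returns ``(crossing_point_nm, axial_azimuth_deg, se_nm)``.
    """
    sel, se_meas = _branch_selection(trace, line, side, standoff_nm, n_fit,
                                     barrier_rows)
    mean, v = _axis_direction(sel)
    az = float(wrap_180(azimuth_deg(v[0], v[1])))
    pt, d_ext = _axis_intersect(mean, v, line)
    se = _crossing_se(sel, mean, v, se_meas, d_ext)
    return pt, az, se


def measure_displacement(
    vdf: VDFImage,
    line: DislocationLine,
    seeds,
    smoothing: float | None = None,
    min_crossing_deg: float = 15.0,
    width_flag_factor: float = 5.0,
    excluded_rows=(),
) -> ContourCrossing:
    """Measure the bend-contour displacement across a dislocation line.

    ``seeds`` are two scan-frame points (nm), one on the contour segment on
    each side of the line.  The two centerlines are traced, intersected with
    the line, and the displacement is the signed arclength between the two
    intersections along ``positive_sense`` (positive when the far-side
    segment - the mathematical-left side of the stored point order - sits
    further along the positive sense).  Uncertainty combines the per-side
    FWHM-centroid standard errors in quadrature, inflated by the crossing
    angle.  Crossings shallower than ``min_crossing_deg`` or with contours
    broader than ``width_flag_factor`` times the median width are flagged
    unusable.
    """
    s1, s2 = (np.asarray(s, dtype=float) for s in seeds)
    sd1, sd2 = line.side_of(s1), line.side_of(s2)
    if sd1 == sd2 or 0 in (sd1, sd2):
        raise ValueError("seeds must lie on opposite sides of the line")
    g = vdf.g
    step = vdf.scan_step
    u_az = line.u_azimuth
    try:
        traces = {sd: trace_contour(vdf, s, smoothing,
                                    excluded_rows=excluded_rows,
                                    side_gate=(line, sd))
                  for sd, s in ((sd1, s1), (sd2, s2))}
    except TraceError as exc:
        return ContourCrossing(g=g, usable=False, reason=f"trace failed: {exc}")

    width_px = float(np.median(np.concatenate(
        [t.widths_px for t in traces.values()])))
    # cut centroids are refined on raw counts (no smoothing-kernel bias),
    # so the standoff only needs to clear partial-band cuts near the line
    sigma_px = (smoothing / step) if smoothing else 2.0
    standoff = (max(2.0, 0.25 * width_px) + 1.0 * sigma_px) * step
    s_vals, se_along, angles, azs = {}, {}, {}, {}
    for sd, tr in traces.items():
        try:
            sel, se_meas = _branch_selection(
                tr, line, sd, standoff, barrier_rows=tuple(excluded_rows))
        except GeometryError as exc:
            return ContourCrossing(g=g, usable=False, reason=str(exc))
        mean, v = _axis_direction(sel)
        pt, d_ext = _axis_intersect(mean, v, line)
        se = _crossing_se(sel, mean, v, se_meas, d_ext)
        az = float(wrap_180(azimuth_deg(v[0], v[1])))
        angle = float(ang_sep_mod180(az, u_az))
        angles[sd] = angle
        azs[sd] = az
        s_vals[sd] = line.arclength_of(pt)
        se_along[sd] = se / max(np.sin(np.radians(angle)), 1e-3)

    displacement = float(s_vals[1.0] - s_vals[-1.0])
    uncertainty = float(np.hypot(*se_along.values()))
    uncertainty = max(uncertainty, 0.05 * step)
    width = width_px * step

    crossing = ContourCrossing(
        g=g, displacement=displacement, uncertainty=uncertainty,
        contour_width=width,
        meta={"crossing_angles_deg": dict(angles),
              "branch_azimuths_deg": dict(azs),
              "complete": all(t.complete for t in traces.values())})
    if min(angles.values()) < min_crossing_deg:
        crossing.usable = False
        crossing.reason = (f"crossing angle {min(angles.values()):.1f} deg < "
                           f"{min_crossing_deg} deg: distance along the line "
                           "is ill-conditioned")
    return crossing


def _row_shift(a, b):
    """Sub-pixel lag of 1D profile b relative to a (None if featureless)."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    c = np.correlate(b, a, mode="full")
    i = int(np.argmax(c))
    if c[i] <= 0:
        return None
    d = 0.0
    if 0 < i < len(c) - 1:
        den = c[i - 1] - 2 * c[i] + c[i + 1]
        if den != 0:
            d = float(np.clip(0.5 * (c[i - 1] - c[i + 1]) / den, -1, 1))
    return i + d - (len(a) - 1)


def detect_uniform_shift(
    vdfs: list,
    jump_px: float = 1.5,
    fraction: float = 0.9,
    min_structure: float = 0.15,
    resid_tol_px: float = 1.0,
) -> list[int]:
    """Flag scan rows where contours jump together in all VDFs.

    A mid-scan reorientation of the sample displaces the whole contour
    pattern by one rigid vector ``delta``: the contour of reflection g
    shifts across its band by ``delta . g_hat``.  For every pair of
    consecutive rows the apparent x-shift of each VDF's row profile is
    measured by 1D cross-correlation and converted to an across-band shift;
    a single ``delta`` is then fitted by least squares over the VDFs.  A row
    is flagged when the fitted ``|delta|`` exceeds ``jump_px`` and at least
    ``fraction`` of the valid VDFs are consistent with it (within
    ``resid_tol_px``).  A dislocation displaces only its own g - a rigid
    ``delta`` fit over many VDFs then stays small - so single-g jumps are
    never flagged.

    Near-horizontal contours (|cos phi| small) carry no row-profile shift
    information and are excluded from both the fit and the head count.
    """
    if len(vdfs) < 3:
        raise ValueError("need at least 3 VDF images to separate a uniform "
                         "shift from single-g dislocation contrast")
    ny = vdfs[0].image.shape[0]
    sms, gvec = [], []
    for v in vdfs:
        sms.append(ndimage.gaussian_filter1d(
            np.asarray(v.image, dtype=float), 1.5, axis=1))
        # storage-frame g direction (x component = cos phi, y-up convention)
        gvec.append(unit_from_azimuth(v.g.phi))
    flagged = []
    for y in range(1, ny):
        ghats, s_obs = [], []
        for sm, ghat in zip(sms, gvec):
            if abs(ghat[0]) < 0.2:
                continue  # row correlation blind to this band
            a, b = sm[y - 1], sm[y]
            ref = sm.std()
            if min(a.std(), b.std()) < min_structure * ref:
                continue
            # a contour exiting the frame leaves a clipped, unusable bump
            if min(a.argmax(), b.argmax()) < 3 \
                    or max(a.argmax(), b.argmax()) > len(a) - 4:
                continue
            dx = _row_shift(a, b)
            if dx is None:
                continue
            ghats.append(ghat)
            s_obs.append(dx * ghat[0])  # across-band shift in px
        if len(s_obs) < max(3, int(np.ceil(0.6 * len(vdfs)))):
            continue  # too few informative witnesses for a global claim
        G = np.asarray(ghats)
        s = np.asarray(s_obs)
        delta, *_ = np.linalg.lstsq(G, s, rcond=None)
        if np.hypot(*delta) < jump_px:
            continue
        resid = np.abs(G @ delta - s)
        tol = np.maximum(resid_tol_px, 0.3 * np.abs(G @ delta))
        if np.mean(resid <= tol) >= fraction:
            flagged.append(int(y))
    return flagged


def build_profile(crossings: list) -> DisplacementProfile:
    """Assemble a displacement profile, keeping unusable crossings as QC
    metadata and rejecting duplicate g-vectors."""
    seen = []
    for c in crossings:
        key = tuple(np.round(np.asarray(c.g.k, dtype=float), 9))
        if key in seen:
            raise ValueError(f"duplicate g-vector in profile: k={key}")
        seen.append(key)
    if not any(c.usable for c in crossings):
        raise EmptyProfileError("no usable bend-contour crossings")
    return DisplacementProfile(crossings=list(crossings))


def export_profile_csv(profile: DisplacementProfile, path) -> None:
    """Write the displacement profile (hkl or k, phi, displacement,
    uncertainty, usable) as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["hkl", "k_x_invA", "k_y_invA", "phi_deg",
                    "displacement_nm", "uncertainty_nm", "usable", "reason"])
        for c in profile.crossings:
            g = c.g
            w.writerow([" ".join(map(str, g.hkl)) if g.hkl else "",
                        f"{g.k[0]:.6f}", f"{g.k[1]:.6f}", f"{g.phi:.4f}",
                        "" if np.isnan(c.displacement)
                        else f"{c.displacement:.4f}",
                        "" if np.isnan(c.uncertainty)
                        else f"{c.uncertainty:.4f}",
                        int(c.usable), c.reason])


def auto_seeds(vdf: VDFImage, line: DislocationLine, margin_px: int = 4,
               standoff_px: float = 4.0):
    """Suggest one seed per side of the line: the brightest smoothed VDF
    pixel on each side, away from the line and the image border."""
    img = ndimage.gaussian_filter(np.asarray(vdf.image, dtype=float), 2.0)
    ny, nx = img.shape
    step = vdf.scan_step
    yy, xx = np.mgrid[:ny, :nx]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float) * step
    sides = np.asarray(line.side_of(pts)).reshape(ny, nx)
    # distance from the line, in px
    dist = np.full((ny, nx), np.inf)
    for a, b in zip(line.points[:-1], line.points[1:]):
        seg = b - a
        l2 = seg @ seg
        t = np.clip(((pts - a) @ seg) / l2, 0, 1)
        proj = a + t[:, None] * seg
        d = np.hypot(*(pts - proj).T).reshape(ny, nx) / step
        dist = np.minimum(dist, d)
    border = np.zeros((ny, nx), dtype=bool)
    border[margin_px:-margin_px, margin_px:-margin_px] = True
    # border distance, for preferring seeds whose cut windows stay in-frame
    bdist = np.minimum.reduce([yy, xx, ny - 1 - yy, nx - 1 - xx])
    out = []
    for sd in (-1.0, 1.0):
        mask = (sides == sd) & (dist > standoff_px) & border
        if not mask.any():
            raise TraceError(f"no candidate seed on side {sd:+.0f}")
        sel = np.where(mask, img, -np.inf)
        # along a noise-free ridge many pixels tie at the maximum; among the
        # near-maximal ones take the one clearest of both the border and the
        # line, so its cut window stays valid
        near_max = sel >= 0.95 * sel.max()
        score = np.where(near_max, np.minimum(bdist, dist), -1.0)
        iy, ix = np.unravel_index(np.argmax(score), score.shape)
        out.append(np.array([ix, iy], dtype=float) * step)
    return tuple(out)
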