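"""Unit-cell arithmetic: metric tensors, d-spacings, zone-axis projections,
azimuth-to-[uvw] matching, a geometry-only indexing assist, and dislocation
density bookkeeping.

All reciprocal-space arithmetic goes through the direct metric tensor G and
its inverse G* (no structure factors anywhere: kinematic intensities are not
needed for bend-contour metrology, so absent reflections simply fail to
match).  A zone axis [uvw] defines a viewing plane; a shared orthonormal
2D basis of that plane (e1 along the projection of the lowest-index in-zone
g) makes crystal azimuths commensurable with calibrated detector azimuths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from ._geometry import ang_sep_mod180, azimuth_math, wrap_180, wrap_360
from .contours import DislocationLine

__all__ = [
    "UnitCell",
    "ZoneAxis",
    "P_TERPHENYL",
    "d_spacing",
    "zone_g_list",
    "zone_basis",
    "project_direction",
    "match_burgers",
    "index_assist",
    "assign_slip_system",
    "dislocation_density",
    "out_of_plane_bound",
    "cell_from_cif",
    "coprime_directions",
]


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    label: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180) deg")
        if not self.volume > 0:
            raise ValueError("cell volume must be real and positive")

    @property
    def metric(self) -> np.ndarray:
        """Direct metric tensor G (A^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        return np.array([
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ])

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def volume(self) -> float:
        det = np.linalg.det(self.metric)
        return float(np.sqrt(det)) if det > 0 else -1.0

    @property
    def direct_matrix(self) -> np.ndarray:
        """Rows are the direct basis vectors a, b, c in Cartesian A
        (a along x, b in the x-y plane)."""
        return np.linalg.cholesky(self.metric)

    def direction_cartesian(self, uvw) -> np.ndarray:
        return np.asarray(uvw, dtype=float) @ self.direct_matrix

    def g_cartesian(self, hkl) -> np.ndarray:
        """Reciprocal vector g_hkl in Cartesian 1/A."""
        recip = np.linalg.inv(self.direct_matrix).T
        return np.asarray(hkl, dtype=float) @ recip


# p-terphenyl, monoclinic P2_1/a; cell constants transcribed from the
# published single-crystal structure (CCDC entry 1269381)
P_TERPHENYL = UnitCell(8.106, 5.613, 13.613, 90.0, 92.02, 90.0,
                       label="p-terphenyl P2_1/a, CCDC 1269381")


@dataclass(frozen=True)
class ZoneAxis:
    """A beam-parallel lattice direction [uvw], coprime integers."""

    uvw: tuple

    def __post_init__(self):
        u = tuple(int(x) for x in self.uvw)
        if u == (0, 0, 0):
            raise ValueError("zone axis cannot be [000]")
        g = math.gcd(math.gcd(abs(u[0]), abs(u[1])), abs(u[2]))
        object.__setattr__(self, "uvw", tuple(x // g for x in u))

    def __iter__(self):
        return iter(self.uvw)


def d_spacing(cell: UnitCell, hkl) -> float:
    """Interplanar spacing ``1/sqrt(h^T G* h)`` in Angstrom."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("hkl must not be (0,0,0)")
    return float(1.0 / np.sqrt(h @ cell.reciprocal_metric @ h))


def _canonical_sign(hkl):
    for x in hkl:
        if x != 0:
            return tuple(hkl) if x > 0 else tuple(-v for v in hkl)
    return tuple(hkl)


def zone_basis(cell: UnitCell, zone: ZoneAxis, gmax: float = 1.0):
    """Shared orthonormal 2D basis (e1, e2, beam) of the zone plane.

    e1 lies along the lowest-index in-zone reciprocal vector (canonical
    sign: first nonzero index positive), e2 = beam x e1, so azimuths of
    reciprocal vectors and projected real directions are directly
    comparable.
    """
    beam = cell.direction_cartesian(list(zone))
    beam = beam / np.linalg.norm(beam)
    best = None
    mmax = max(2, int(math.ceil(gmax * max(cell.a, cell.b, cell.c))) + 1)
    for hkl in product(range(-mmax, mmax + 1), repeat=3):
        if hkl == (0, 0, 0):
            continue
        if sum(h * u for h, u in zip(hkl, zone)) != 0:
            continue
        key = (sum(abs(x) for x in hkl), _canonical_sign(hkl))
        if best is None or key < best[0]:
            best = (key, _canonical_sign(hkl))
    g1 = cell.g_cartesian(best[1])
    e1 = g1 - (g1 @ beam) * beam
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(beam, e1)
    return e1, e2, beam


def zone_g_list(cell: UnitCell, zone: ZoneAxis, gmax: float):
    """All in-zone reflections with ``|g| <= gmax`` and their 2D coordinates.

    Returns a list of ``(hkl, k2)`` with ``k2 = (g.e1, g.e2)`` in 1/A in the
    shared zone-plane basis.  Geometry only; no structure factors.
    """
    if not gmax > 0:
        raise ValueError("gmax must be positive")
    e1, e2, beam = zone_basis(cell, zone, gmax)
    mmax = int(math.ceil(gmax * max(cell.a, cell.b, cell.c))) + 1
    out = []
    for hkl in product(range(-mmax, mmax + 1), repeat=3):
        if hkl == (0, 0, 0):
            continue
        if sum(h * u for h, u in zip(hkl, zone)) != 0:
            continue
        g = cell.g_cartesian(hkl)
        if np.linalg.norm(g) > gmax + 1e-12:
            continue
        out.append((tuple(hkl), np.array([g @ e1, g @ e2])))
    out.sort(key=lambda t: (round(float(np.hypot(*t[1])), 9), t[0]))
    return out


def project_direction(cell: UnitCell, zone: ZoneAxis, uvw) -> float:
    """Azimuth (deg) of the real-space direction [uvw] projected onto the
    zone plane, in the same 2D basis as :func:`zone_g_list`."""
    e1, e2, beam = zone_basis(cell, zone)
    v = cell.direction_cartesian(uvw)
    vp = v - (v @ beam) * beam
    if np.linalg.norm(vp) < 1e-9 * np.linalg.norm(v):
        raise ValueError(f"direction {tuple(uvw)} is parallel to the zone axis")
    return float(wrap_360(azimuth_math(vp @ e1, vp @ e2)))


def coprime_directions(max_index: int = 2):
    """All coprime integer directions with |indices| <= max_index,
    one per antiparallel pair (canonical sign)."""
    seen = set()
    for uvw in product(range(-max_index, max_index + 1), repeat=3):
        if uvw == (0, 0, 0):
            continue
        g = math.gcd(math.gcd(abs(uvw[0]), abs(uvw[1])), abs(uvw[2]))
        c = _canonical_sign(tuple(x // g for x in uvw))
        seen.add(c)
    return sorted(seen)


@dataclass
class BurgersMatch:
    uvw: tuple
    projected_azimuth: float
    mismatch_deg: float


def match_burgers(
    fitted_azimuth: float,
    cell: UnitCell,
    zone: ZoneAxis,
    candidates=None,
    tol: float = 3.0,
):
    """Rank candidate lattice directions by projected-azimuth mismatch.

    Returns ``(matches_within_tol, best_near_miss)``; ties are broken by
    lower index sum then shorter real-space length.  The 180 deg azimuth
    ambiguity is folded out (axial comparison).
    """
    if candidates is None:
        candidates = coprime_directions(2)
    if not len(candidates):
        raise ValueError("candidate list is empty")
    ranked = []
    for uvw in candidates:
        try:
            az = project_direction(cell, zone, uvw)
        except ValueError:
            continue
        mis = float(ang_sep_mod180(az, fitted_azimuth))
        length = float(np.linalg.norm(cell.direction_cartesian(uvw)))
        ranked.append((mis, sum(abs(i) for i in uvw), length,
                       BurgersMatch(tuple(int(i) for i in uvw), az, mis)))
    ranked.sort(key=lambda t: t[:3])
    matches = [r[3] for r in ranked if r[0] <= tol]
    best = ranked[0][3] if ranked else None
    return matches, best


def index_assist(
    gvectors,
    cell: UnitCell,
    zones,
    mag_tol: float = 0.03,
    angle_tol: float = 4.0,
    score_floor: float = 0.6,
):
    """Rank candidate zone axes against observed g-vectors.

    Scoring is rotation invariant: for every candidate in-plane rotation
    that aligns one observed g with one simulated g of compatible magnitude,
    the fraction of observed g-vectors matched in both magnitude
    (``mag_tol`` 1/A) and azimuth (``angle_tol`` deg) is computed; a zone's
    score is its best rotation's fraction.  Returns a list of
    ``(ZoneAxis, score, rotation_deg, {gvector_index: hkl})`` sorted by
    descending score, or ``"unindexed"`` when nothing reaches
    ``score_floor``.
    """
    if len(gvectors) < 3:
        raise ValueError("need >= 3 g-vectors to index")
    obs_az = np.array([g.phi for g in gvectors])
    obs_mag = np.array([g.magnitude for g in gvectors])
    span = np.ptp(np.mod(obs_az, 180.0))
    if span < 1e-6:
        raise ValueError("g-vectors are collinear")
    results = []
    for z in zones:
        zone = z if isinstance(z, ZoneAxis) else ZoneAxis(tuple(z))
        sim = zone_g_list(cell, zone, gmax=float(obs_mag.max()) * 1.15)
        if not sim:
            continue
        sim_az = np.array([azimuth_math(k[0], k[1]) for _, k in sim])
        sim_mag = np.array([float(np.hypot(*k)) for _, k in sim])
        best = (0.0, 0.0, {})
        for i in range(len(gvectors)):
            for j in range(len(sim)):
                if abs(obs_mag[i] - sim_mag[j]) > mag_tol:
                    continue
                rot = wrap_360(obs_az[i] - sim_az[j])
                assigned = {}
                for ii in range(len(gvectors)):
                    da = np.abs(np.mod(sim_az + rot - obs_az[ii] + 180.0,
                                       360.0) - 180.0)
                    ok = (np.abs(sim_mag - obs_mag[ii]) <= mag_tol) \
                        & (da <= angle_tol)
                    if ok.any():
                        jj = int(np.argmin(np.where(ok, da, np.inf)))
                        assigned[ii] = sim[jj][0]
                frac = len(assigned) / len(gvectors)
                if frac > best[0]:
                    best = (frac, float(rot), assigned)
        results.append((zone, best[0], best[1], best[2]))
    results.sort(key=lambda t: -t[1])
    if not results or results[0][1] < score_floor:
        return "unindexed"
    return results


def assign_slip_system(
    b_uvw,
    line: DislocationLine,
    zone: ZoneAxis,
    cell: UnitCell,
    orientation_offset: float = 0.0,
    line_candidates=None,
    max_plane_index: int = 3,
    tol: float = 10.0,
):
    """Identify the operative slip system [uvw](hkl).

    The observed line azimuth (scan frame) is converted into the zone-plane
    basis with ``orientation_offset`` (the in-plane rotation found by
    indexing, crystal -> scan) and matched to a low-index lattice direction;
    the slip plane is the lattice plane containing both the Burgers vector
    and that line direction, ``(hkl) = b x u`` reduced to coprime integers.
    A pure-screw geometry (b || u) leaves the plane undetermined.
    """
    b = tuple(int(x) for x in b_uvw)
    u_az_crystal = wrap_180(line.u_azimuth - orientation_offset)
    matches, best = match_burgers(u_az_crystal, cell, zone,
                                  candidates=line_candidates, tol=tol)
    if not matches:
        return {"b": b, "plane": None,
                "label": f"[{b[0]}{b[1]}{b[2]}], plane undetermined",
                "reason": "line direction matches no low-index [uvw]"}
    u3 = matches[0].uvw
    n = np.cross(np.array(b), np.array(u3)).astype(int)
    if not n.any():
        return {"b": b, "plane": None, "u": u3,
                "label": f"[{b[0]}{b[1]}{b[2]}], plane undetermined",
                "reason": "pure screw geometry (b || u)"}
    g = math.gcd(math.gcd(abs(int(n[0])), abs(int(n[1]))), abs(int(n[2])))
    plane = _canonical_sign(tuple(int(x) // g for x in n))
    if max(abs(x) for x in plane) > max_plane_index:
        return {"b": b, "plane": None, "u": u3,
                "label": f"[{b[0]}{b[1]}{b[2]}], plane undetermined",
                "reason": f"no common plane with index <= {max_plane_index}"}
    label = (f"[{b[0]}{b[1]}{b[2]}]"
             f"({plane[0]}{plane[1]}{plane[2]})")
    return {"b": b, "plane": plane, "u": u3, "label": label, "reason": ""}


def dislocation_density(lines, area_um2: float, thickness_nm) -> tuple:
    """Dislocation density rho = (line length)/(area * thickness) in 1/cm^2.

    ``thickness_nm`` is a ``(t_min, t_max)`` range; the density is reported
    as ``(rho_at_t_max, rho_at_t_min)``, i.e. (low, high).
    """
    if not area_um2 > 0:
        raise ValueError("area must be positive")
    t_lo, t_hi = (float(t) for t in np.sort(np.atleast_1d(thickness_nm)))
    if not t_lo > 0:
        raise ValueError("thickness bounds must be positive")
    total_nm = float(sum(ln.length for ln in lines))
    if total_nm == 0:
        return (0.0, 0.0)
    l_cm = total_nm * 1e-7
    a_cm2 = area_um2 * 1e-8
    return (l_cm / (a_cm2 * t_hi * 1e-7), l_cm / (a_cm2 * t_lo * 1e-7))


def out_of_plane_bound(length_um: float, thickness_nm: float) -> float:
    """Maximum inclination (deg) of a line of projected length ``length_um``
    confined to a film of ``thickness_nm``: ``arctan(t / L)``."""
    if not (length_um > 0 and thickness_nm > 0):
        raise ValueError("length and thickness must be positive")
    return float(np.degrees(np.arctan(thickness_nm / (length_um * 1e3))))


def cell_from_cif(path, label: str | None = None) -> UnitCell:
    """Read cell constants (only) from a CIF file via gemmi."""
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    def val(tag):
        raw = block.find_value(tag)
        if raw is None:
            raise ValueError(f"{path}: missing {tag}")
        return float(gemmi.cif.as_number(raw))
    return UnitCell(
        a=val("_cell_length_a"), b=val("_cell_length_b"),
        c=val("_cell_length_c"),
        alpha=val("_cell_angle_alpha"), beta=val("_cell_angle_beta"),
        gamma=val("_cell_angle_gamma"),
        label=label or block.name,
    )
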