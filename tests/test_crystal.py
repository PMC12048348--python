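import itertools

import gemmi
import numpy as np
import pytest

from sedlab._geometry import ang_sep_mod180, unit_from_azimuth
from sedlab.contours import DislocationLine
from sedlab.crystal import (P_TERPHENYL, UnitCell, ZoneAxis,
                            assign_slip_system, cell_from_cif,
                            coprime_directions, d_spacing,
                            dislocation_density, index_assist, match_burgers,
                            out_of_plane_bound, project_direction,
                            zone_g_list)
from sedlab.discs import GVector

MONO = UnitCell(8.0, 5.6, 13.6, 90.0, 92.0, 90.0, label="monoclinic test")
ORTHO = UnitCell(7.0, 5.0, 10.0, label="orthorhombic test")
TRICLINIC = UnitCell(6.1, 7.3, 8.9, 82.0, 95.0, 104.0)


# ------------------------------------------------------------ d-spacings

def test_p_terphenyl_reference_spacings():
    """Printed d-spacings for the benchmark monoclinic crystal."""
    assert round(d_spacing(P_TERPHENYL, (2, 1, 0)), 2) == 3.28
    assert round(d_spacing(P_TERPHENYL, (2, 0, 0)), 2) == 4.05


def test_d_spacing_cubic_closed_form():
    cubic = UnitCell(1.0, 1.0, 1.0)
    assert d_spacing(cubic, (1, 0, 0)) == pytest.approx(1.0, abs=1e-12)
    assert d_spacing(cubic, (1, 1, 0)) == pytest.approx(1 / np.sqrt(2))


def test_d_spacing_orthorhombic_closed_form():
    for hkl in [(1, 0, 0), (0, 2, 1), (3, 1, 2)]:
        h, k, l = hkl  # noqa: E741
        expect = 1.0 / np.sqrt(h**2 / 7.0**2 + k**2 / 5.0**2
                               + l**2 / 10.0**2)
        assert d_spacing(ORTHO, hkl) == pytest.approx(expect, abs=1e-12)


@pytest.mark.parametrize("cell", [P_TERPHENYL, MONO, TRICLINIC])
def test_d_spacing_matches_gemmi(cell):
    """Independent cross-check against gemmi's unit-cell arithmetic."""
    gc = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta,
                        cell.gamma)
    for hkl in [(1, 0, 0), (0, 1, 0), (2, 1, 0), (1, -1, 3), (-2, 3, 1)]:
        assert d_spacing(cell, hkl) == pytest.approx(
            gc.calculate_d(hkl), rel=1e-9)


def test_d_spacing_rejects_zero_hkl():
    with pytest.raises(ValueError):
        d_spacing(MONO, (0, 0, 0))


# ------------------------------------------------------------ zone lists

def test_zone_g_list_cubic_001():
    cubic = UnitCell(1.0, 1.0, 1.0)
    out = zone_g_list(cubic, ZoneAxis((0, 0, 1)), gmax=1.45)
    hkls = {h for h, _ in out}
    assert hkls == {(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0)}
    k100 = dict(out)[(1, 0, 0)]
    k010 = dict(out)[(0, 1, 0)]
    assert abs(k100 @ k010) < 1e-12  # right angles


def test_zone_g_list_satisfies_zone_law():
    for cell, zone in [(MONO, (0, 0, 1)), (TRICLINIC, (1, 4, 1)),
                       (ORTHO, (1, 1, 0))]:
        for hkl, _ in zone_g_list(cell, ZoneAxis(zone), gmax=0.8):
            assert sum(h * u for h, u in zip(hkl, zone)) == 0


def test_zone_g_list_matches_brute_force_oracle():
    """Independent enumeration with gemmi magnitudes gives the same set."""
    gmax = 0.6
    zone = (0, 0, 1)
    gc = gemmi.UnitCell(MONO.a, MONO.b, MONO.c, MONO.alpha, MONO.beta,
                        MONO.gamma)
    expect = set()
    for hkl in itertools.product(range(-10, 11), repeat=3):
        if hkl == (0, 0, 0) or hkl[2] != 0:
            continue
        if 1.0 / gc.calculate_d(hkl) <= gmax:
            expect.add(hkl)
    got = {h for h, _ in zone_g_list(MONO, ZoneAxis(zone), gmax)}
    assert got == expect
    for hkl, k2 in zone_g_list(MONO, ZoneAxis(zone), gmax):
        assert np.hypot(*k2) == pytest.approx(1.0 / gc.calculate_d(hkl),
                                              rel=1e-9)


# ------------------------------------------------------------ projections

def test_project_direction_orthorhombic():
    az100 = project_direction(ORTHO, ZoneAxis((0, 0, 1)), (1, 0, 0))
    az010 = project_direction(ORTHO, ZoneAxis((0, 0, 1)), (0, 1, 0))
    assert ang_sep_mod180(az100, az010) == pytest.approx(90.0, abs=1e-9)


def test_project_direction_rejects_parallel():
    with pytest.raises(ValueError):
        project_direction(ORTHO, ZoneAxis((0, 0, 1)), (0, 0, 2))


def test_project_direction_matrix_oracle():
    """Numeric 3D projection with an independently built orthogonalization
    matrix agrees to 1e-9."""
    cell, zone, uvw = MONO, ZoneAxis((0, 0, 1)), (1, 2, 0)
    gc = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta,
                        cell.gamma)
    om = np.array(gc.orth.mat.tolist())  # columns are a, b, c
    beam = om @ np.array(list(zone), dtype=float)
    beam /= np.linalg.norm(beam)
    v = om @ np.array(uvw, dtype=float)
    vp = v - (v @ beam) * beam
    # reference azimuth measured against the same e1 the package uses
    from sedlab.crystal import zone_basis
    e1, e2, _ = zone_basis(cell, zone)
    # map package basis into gemmi frame via shared reciprocal vector
    got = project_direction(cell, zone, uvw)
    # angles between projected [100] and [120] must agree in any frame
    v2 = om @ np.array([1.0, 0.0, 0.0])
    v2p = v2 - (v2 @ beam) * beam
    expect_sep = np.degrees(np.arccos(
        np.clip(vp @ v2p / np.linalg.norm(vp) / np.linalg.norm(v2p), -1, 1)))
    got_sep = ang_sep_mod180(got, project_direction(cell, zone, (1, 0, 0)))
    assert got_sep == pytest.approx(min(expect_sep, 180 - expect_sep),
                                    abs=1e-9)


def test_zone_basis_shared_between_g_and_directions():
    """g azimuths and projected real directions are commensurable: in an
    orthorhombic cell [100] projects along g_100 exactly."""
    az_dir = project_direction(ORTHO, ZoneAxis((0, 0, 1)), (1, 0, 0))
    g = dict(zone_g_list(ORTHO, ZoneAxis((0, 0, 1)), 0.2))[(1, 0, 0)]
    az_g = np.degrees(np.arctan2(g[1], g[0])) % 360
    assert ang_sep_mod180(az_dir, az_g) == pytest.approx(0.0, abs=1e-9)


# ------------------------------------------------------------ matching

def test_match_burgers_ranks_planted_direction():
    az010 = project_direction(MONO, ZoneAxis((0, 0, 1)), (0, 1, 0))
    matches, best = match_burgers(az010 + 1.0, MONO, ZoneAxis((0, 0, 1)))
    assert matches[0].uvw == (0, 1, 0)
    assert matches[0].mismatch_deg == pytest.approx(1.0, abs=1e-6)


def test_match_burgers_unmatched_carries_near_miss():
    az010 = project_direction(ORTHO, ZoneAxis((0, 0, 1)), (0, 1, 0))
    matches, best = match_burgers(az010 + 20.0, ORTHO, ZoneAxis((0, 0, 1)),
                                  candidates=[(0, 1, 0)], tol=3.0)
    assert matches == []
    assert best.uvw == (0, 1, 0)
    assert best.mismatch_deg == pytest.approx(20.0, abs=1e-6)


def test_match_burgers_axial_invariance():
    az = 61.0
    m1, _ = match_burgers(az, MONO, ZoneAxis((0, 0, 1)))
    m2, _ = match_burgers(az + 180.0, MONO, ZoneAxis((0, 0, 1)))
    assert [m.uvw for m in m1] == [m.uvw for m in m2]


# ------------------------------------------------------------ indexing

def _observed(cell, zone, rot_deg, gmax=0.45):
    out = []
    for hkl, k2 in zone_g_list(cell, zone, gmax):
        az = np.degrees(np.arctan2(k2[1], k2[0])) + rot_deg
        mag = np.hypot(*k2)
        out.append(GVector(
            k=mag * np.array([np.cos(np.radians(az)),
                              np.sin(np.radians(az))]),
            phi=float(az % 360), hkl=None))
    return out


def test_index_assist_identifies_zone_and_hkl():
    zones = [ZoneAxis(z) for z in [(0, 0, 1), (0, 1, 0), (1, 0, 0),
                                   (1, 1, 0)]]
    obs = _observed(MONO, ZoneAxis((0, 0, 1)), rot_deg=0.0)
    res = index_assist(obs, MONO, zones)
    assert res != "unindexed"
    zone, score, rot, assigned = res[0]
    assert zone.uvw == (0, 0, 1)
    assert score == 1.0
    for i, hkl in assigned.items():
        assert sum(h * u for h, u in zip(hkl, zone.uvw)) == 0
        assert abs(1 / d_spacing(MONO, hkl) - obs[i].magnitude) < 0.03


def test_index_assist_rotation_invariant():
    zones = [ZoneAxis(z) for z in [(0, 0, 1), (0, 1, 0), (1, 1, 0)]]
    res = index_assist(_observed(MONO, ZoneAxis((0, 0, 1)), 25.0),
                       MONO, zones)
    assert res != "unindexed"
    assert res[0][0].uvw == (0, 0, 1)
    assert res[0][1] == 1.0


def test_index_assist_rejects_wrong_cell():
    other = UnitCell(11.3, 9.7, 17.1, 90, 90, 90)
    obs = _observed(other, ZoneAxis((0, 0, 1)), 0.0, gmax=0.3)
    res = index_assist(obs, MONO, [ZoneAxis((0, 0, 1)),
                                   ZoneAxis((0, 1, 0))])
    assert res == "unindexed"


# ------------------------------------------------------------ slip system

def _line_along(az):
    u = unit_from_azimuth(az)
    return DislocationLine(np.array([[0.0, 0.0], 400 * u]))


def test_slip_system_reference_case():
    """b=[010], line in the a-b plane of a monoclinic [001] zone ->
    [010](001)."""
    az100 = project_direction(MONO, ZoneAxis((0, 0, 1)), (1, 0, 0))
    out = assign_slip_system((0, 1, 0), _line_along(az100), ZoneAxis((0, 0, 1)),
                             MONO)
    assert out["plane"] == (0, 0, 1)
    assert out["label"] == "[010](001)"


def test_slip_system_pure_screw_undetermined():
    az010 = project_direction(MONO, ZoneAxis((0, 0, 1)), (0, 1, 0))
    out = assign_slip_system((0, 1, 0), _line_along(az010),
                             ZoneAxis((0, 0, 1)), MONO)
    assert out["plane"] is None
    assert "undetermined" in out["label"]


def test_slip_system_orthorhombic_planted():
    az = project_direction(ORTHO, ZoneAxis((0, 0, 1)), (1, 0, 0))
    out = assign_slip_system((0, 1, 0), _line_along(az), ZoneAxis((0, 0, 1)),
                             ORTHO)
    assert out["b"] == (0, 1, 0)
    assert out["u"] == (1, 0, 0)
    assert out["plane"] == (0, 0, 1)


# ------------------------------------------------------------ density

def test_dislocation_density_unit_conversion():
    """10 um of line in 25 um^2 at 100 nm thickness -> 4e8 cm^-2."""
    line = DislocationLine(np.array([[0.0, 0.0], [10000.0, 0.0]]))
    low, high = dislocation_density([line], 25.0, (100.0, 100.0))
    assert low == pytest.approx(4e8, rel=1e-9)


def test_dislocation_density_thickness_ratio():
    line = DislocationLine(np.array([[0.0, 0.0], [5000.0, 0.0]]))
    low, high = dislocation_density([line], 25.0, (10.0, 100.0))
    assert high / low == pytest.approx(10.0, rel=1e-12)


def test_dislocation_density_empty():
    assert dislocation_density([], 25.0, (10.0, 100.0)) == (0.0, 0.0)


def test_out_of_plane_bound():
    assert out_of_plane_bound(2.0, 100.0) == pytest.approx(2.862, abs=0.01)
    assert out_of_plane_bound(2.0, 100.0) < 3.0
    assert out_of_plane_bound(2.0, 10.0) == pytest.approx(0.286, abs=0.01)
    assert out_of_plane_bound(2.0, 1e-9) == pytest.approx(0.0, abs=1e-6)


# ------------------------------------------------------------ cells

def test_cell_from_cif(tmp_path):
    cif = tmp_path / "cell.cif"
    cif.write_text("""data_test
_cell_length_a 8.106
_cell_length_b 5.613
_cell_length_c 13.613
_cell_angle_alpha 90.0
_cell_angle_beta 92.02
_cell_angle_gamma 90.0
""")
    cell = cell_from_cif(cif)
    assert cell.a == 8.106
    assert round(d_spacing(cell, (2, 1, 0)), 2) == 3.28


def test_unit_cell_validation():
    with pytest.raises(ValueError):
        UnitCell(-1.0, 5.0, 5.0)
    with pytest.raises(ValueError):
        UnitCell(5.0, 5.0, 5.0, 190.0, 90.0, 90.0)
    with pytest.raises(ValueError):
        ZoneAxis((0, 0, 0))
    assert ZoneAxis((2, 4, 2)).uvw == (1, 2, 1)


def test_coprime_directions_cover_paper_cases():
    dirs = coprime_directions(2)
    for d in [(0, 1, 0), (1, 0, 0), (1, 0, 2)]:
        assert d in dirs
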