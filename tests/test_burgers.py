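import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import contour_scene
from sedlab._geometry import ang_sep_mod180, unit_from_azimuth
from sedlab.burgers import (burgers_azimuth, classify_character,
                            fit_displacement_model, gb_integer,
                            invisibility_set, model_f, screw_handedness)
from sedlab.contours import (ContourCrossing, DislocationLine, auto_seeds,
                             build_profile)
from sedlab.discs import GVector
from sedlab.errors import FitRefusedError, NoResolvableDistortion


# ------------------------------------------------------------ model

def test_model_maximum_and_zero():
    assert model_f(40.0, 10.0, 1.0, 40.0) == pytest.approx(10 * np.pi / 4)
    assert model_f(130.0, 10.0, 1.0, 40.0) == pytest.approx(0.0, abs=1e-12)


@given(st.floats(0, 360), st.floats(0, 180), st.floats(0.1, 50),
       st.floats(0.01, 20))
def test_model_symmetry_and_period(phi0, c, a, b):
    """f is even about C and has period 180 degrees."""
    assert model_f(c + phi0, a, b, c) == pytest.approx(
        model_f(c - phi0, a, b, c), rel=1e-9, abs=1e-9)
    assert model_f(phi0, a, b, c) == pytest.approx(
        model_f(phi0 + 180.0, a, b, c), rel=1e-9, abs=1e-9)


# ------------------------------------------------------------ fitting

def _profile(phis, values, sigma=1.0):
    cs = []
    for p, v in zip(phis, values):
        g = GVector(k=0.3 * np.array([np.cos(np.radians(p)),
                                      np.sin(np.radians(p))]), phi=float(p))
        cs.append(ContourCrossing(g=g, displacement=float(v),
                                  uncertainty=sigma))
    return build_profile(cs)


def test_fit_recovers_noise_free_parameters():
    """Noise-free samples of (A=12, B=2.5, C=40) reproduce the parameters
    to better than 1e-6 relative."""
    phis = np.linspace(0.0, 165.0, 12)
    prof = _profile(phis, model_f(phis, 12.0, 2.5, 40.0))
    fit = fit_displacement_model(prof, n_boot=0)
    assert fit.ok
    assert fit.amp_A == pytest.approx(12.0, rel=1e-6)
    assert fit.shape_B == pytest.approx(2.5, rel=1e-6)
    assert fit.phase_C == pytest.approx(40.0, rel=1e-6)


def test_fit_seeded_noise_recovery_and_ci():
    """5% Gaussian noise, 16 azimuths: C within 2 degrees and inside the
    95% bootstrap interval."""
    rng = np.random.default_rng(1234)
    phis = np.linspace(0.0, 168.75, 16)
    truth = model_f(phis, 12.0, 2.5, 40.0)
    sigma = 0.05 * truth.max()
    prof = _profile(phis, truth + rng.normal(0, sigma, len(phis)),
                    sigma=sigma)
    fit = fit_displacement_model(prof, seed=7)
    assert fit.ok
    assert ang_sep_mod180(fit.phase_C, 40.0) < 2.0
    lo, hi = fit.ci["C"]
    assert lo <= 40.0 <= hi


def test_fit_refuses_underconstrained_profiles():
    phis = [0.0, 10.0, 20.0]
    with pytest.raises(FitRefusedError):
        fit_displacement_model(_profile(phis, [1, 2, 3]))
    phis4 = [0.0, 10.0, 20.0, 30.0]  # span < 60 deg
    with pytest.raises(FitRefusedError):
        fit_displacement_model(_profile(phis4, [1, 2, 3, 2]))


def test_fit_all_zero_profile_reports_no_distortion():
    phis = np.linspace(0.0, 165.0, 12)
    rng = np.random.default_rng(0)
    prof = _profile(phis, rng.normal(0, 0.3, len(phis)), sigma=0.5)
    fit = fit_displacement_model(prof, n_boot=0)
    assert fit.status == "no_resolvable_distortion"
    assert fit.phase_C is None
    with pytest.raises(NoResolvableDistortion):
        burgers_azimuth(fit)


def test_fit_azimuth_shift_equivariance():
    """Rotating all azimuths by delta shifts C by delta and nothing else."""
    phis = np.linspace(0.0, 165.0, 12)
    base = fit_displacement_model(
        _profile(phis, model_f(phis, 9.0, 1.8, 50.0)), n_boot=0)
    for delta in (17.0, 60.0, 123.0):
        shifted = fit_displacement_model(
            _profile((phis + delta) % 360,
                     model_f(phis, 9.0, 1.8, 50.0)), n_boot=0)
        assert shifted.phase_C == pytest.approx((50.0 + delta) % 180,
                                                abs=1e-6)
        assert shifted.amp_A == pytest.approx(base.amp_A, rel=1e-7)
        assert shifted.shape_B == pytest.approx(base.shape_B, rel=1e-6)


def test_parameter_recovery_across_noise_levels():
    """Median |C error| < 2 degrees at 5% noise over seeded profiles of
    8-24 points."""
    errors = {0.02: [], 0.05: [], 0.10: []}
    for i in range(60):
        rng = np.random.default_rng(1000 + i)
        n = int(rng.integers(8, 25))
        noise = [0.02, 0.05, 0.10][i % 3]
        c_true = float(rng.uniform(0, 180))
        phis = np.sort(rng.uniform(0, 360, n))
        truth = model_f(phis, 12.0, 2.5, c_true)
        sigma = noise * truth.max()
        prof = _profile(phis, truth + rng.normal(0, sigma, n), sigma=sigma)
        fit = fit_displacement_model(prof, n_boot=0)
        if fit.ok:
            errors[noise].append(float(ang_sep_mod180(fit.phase_C, c_true)))
    assert np.median(errors[0.05]) < 2.0
    assert np.median(errors[0.02]) <= np.median(errors[0.10])


# ------------------------------------------------------------ azimuth

def test_burgers_azimuth_modular():
    from sedlab.burgers import BurgersFit
    fit = BurgersFit(amp_A=1.0, shape_B=1.0, phase_C=40.0)
    assert burgers_azimuth(fit) == 40.0
    fit170 = BurgersFit(amp_A=1.0, shape_B=1.0, phase_C=170.0)
    assert burgers_azimuth(fit170, rotation_offset=20.0) == pytest.approx(10.0)


def test_invisibility_set_selects_zero_azimuths():
    phis = np.linspace(0.0, 165.0, 12)
    vals = model_f(phis, 12.0, 2.5, 40.0)
    prof = _profile(phis, vals, sigma=0.3)
    fit = fit_displacement_model(prof, n_boot=0)
    res = invisibility_set(prof, fit, zero_tol=2.0, angle_tol=10.0)
    assert res.gvectors  # g near C+90=130 with ~zero displacement
    for g in res.gvectors:
        assert ang_sep_mod180(g.phi, 130.0) <= 10.0
    assert all(ang_sep_mod180(g.phi, 40.0) > 10.0 for g in res.gvectors)


def test_invisibility_unconstrained_note():
    phis = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 170.0])
    vals = model_f(phis, 12.0, 2.5, 40.0)
    prof = _profile(phis, vals, sigma=0.3)
    fit = fit_displacement_model(prof, n_boot=0)
    res = invisibility_set(prof, fit, angle_tol=5.0)
    assert res.gvectors == []
    assert "unconstrained" in res.note


def test_invisibility_consistent_with_burgers_azimuth():
    phis = np.linspace(0.0, 170.0, 14)
    prof = _profile(phis, model_f(phis, 12.0, 2.5, 63.0), sigma=0.3)
    fit = fit_displacement_model(prof, n_boot=0)
    target = (burgers_azimuth(fit) + 90.0) % 180
    for g in invisibility_set(prof, fit).gvectors:
        assert ang_sep_mod180(g.phi, target) <= 10.0


# ------------------------------------------------------------ character

@pytest.mark.parametrize("angle,label", [(0.0, "screw"), (90.0, "edge"),
                                         (45.0, "mixed"), (10.0, "screw"),
                                         (80.0, "edge")])
def test_classify_character_labels(angle, label):
    call = classify_character(20.0 + angle, 20.0)
    assert call.label == label
    assert call.angle_Bu == pytest.approx(angle)


def test_classify_character_flip_symmetry():
    for b, u in [(30.0, 75.0), (150.0, 10.0)]:
        a = classify_character(b, u)
        assert classify_character(b + 180.0, u).label == a.label
        assert classify_character(b, u + 180.0).label == a.label


def test_classify_character_undetermined():
    assert classify_character(None, 20.0).label == "undetermined"


# ------------------------------------------------------------ handedness

def _twist_pair(twist_deg, u_az=20.0, mirror=False, noise=None):
    ln = DislocationLine(np.array(
        [np.array([126.0, 126.0]) - 190 * unit_from_azimuth(u_az),
         np.array([126.0, 126.0]) + 190 * unit_from_azimuth(u_az)]))
    pair = []
    for phi in (u_az + 2.0, u_az + 182.0):
        v, _ = contour_scene(phi=phi, f=10.0, line=ln,
                             twist_deg=twist_deg, noise_seed=noise)
        if mirror:
            # a mirror flips the scan image AND the diffraction vector
            img = v.image[:, ::-1].copy()
            from sedlab.discs import VDFImage
            g = GVector(k=np.array([-v.g.k[0], v.g.k[1]]),
                        phi=(180.0 - v.g.phi) % 360)
            v = VDFImage(img, g, v.aperture_radius, v.scan_step)
        pair.append(v)
    if mirror:
        ln = DislocationLine(np.array(
            [[252.0 - ln.points[0][0], ln.points[0][1]],
             [252.0 - ln.points[1][0], ln.points[1][1]]]))
    return pair, ln


def test_screw_handedness_recovers_planted_twist():
    pair, ln = _twist_pair(+10.0)
    assert screw_handedness(pair, ln) == "right"
    pair, ln = _twist_pair(-10.0)
    assert screw_handedness(pair, ln) == "left"


def test_screw_handedness_mirror_parity():
    pair, ln = _twist_pair(+10.0, mirror=True)
    assert screw_handedness(pair, ln) == "left"


def test_screw_handedness_zero_twist_undetermined():
    pair, ln = _twist_pair(0.0)
    assert screw_handedness(pair, ln) == "undetermined"


def test_screw_handedness_requires_g_near_u():
    pair, ln = _twist_pair(10.0)
    pair[0].g.phi = 75.0
    with pytest.raises(ValueError):
        screw_handedness(pair, ln)


# ------------------------------------------------------------ g.B

@pytest.mark.parametrize("g,b,n", [((2, 1, 0), (0, 1, 0), 1),
                                   ((2, 0, 0), (0, 1, 0), 0),
                                   ((1, 4, 1), (1, 0, 2), 3)])
def test_gb_integer(g, b, n):
    assert gb_integer(g, b) == n
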