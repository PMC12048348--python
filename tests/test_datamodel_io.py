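import numpy as np
import pytest
import yaml

from conftest import gaussian_disc, make_tiny_dataset
from sedlab.datamodel import Calibration, Dataset4D
from sedlab.errors import CenteringError, DataError, FormatError
from sedlab.io import load_dataset, save_dataset
from sedlab.optics import AcquisitionGeometry
from sedlab.preprocess import (adf_image, bin_patterns, center_and_correct,
                               mean_pattern, sqrt_display)


# ---------------------------------------------------------------- container

def test_h5_round_trip(tmp_path):
    ds = make_tiny_dataset(scan=(8, 9), det=(16, 17), scan_step=4.0,
                           detector_cal=0.012, rotation_offset=12.5,
                           beam_center=(8.0, 7.5), flags=["demo"])
    path = save_dataset(ds, tmp_path / "d.h5")
    back = load_dataset(path)
    np.testing.assert_array_equal(back.counts, ds.counts)
    assert back.scan_step == ds.scan_step
    assert back.detector_cal == ds.detector_cal
    assert back.rotation_offset == ds.rotation_offset
    assert back.beam_center == ds.beam_center
    assert back.flags == ds.flags
    assert back.geometry == ds.geometry


def test_raw_array_with_sidecar(tmp_path):
    counts = np.ones((8, 8, 16, 16))
    np.save(tmp_path / "raw.npy", counts)
    (tmp_path / "raw.yaml").write_text(yaml.safe_dump(
        {"scan_step_nm": 2.0, "detector_cal_invA": 0.01,
         "acquisition": {"kv": 200.0, "alpha_mrad": 0.8,
                         "current_pa": 1.0, "dwell_ms": 1.0}}))
    ds = load_dataset(tmp_path / "raw.npy")
    assert ds.scan_step == 2.0
    assert ds.geometry == AcquisitionGeometry(200.0, 0.8, 1.0, 1.0)


def test_missing_calibration_flagged(tmp_path):
    np.save(tmp_path / "raw.npy", np.ones((8, 8, 16, 16)))
    ds = load_dataset(tmp_path / "raw.npy")
    assert ds.detector_cal == 1.0
    assert "uncalibrated-detector" in ds.flags


def test_asymmetric_shapes_preserved(tmp_path):
    """Scan and detector dims (incl. odd detector sizes) survive a round
    trip untouched."""
    ds = make_tiny_dataset(scan=(16, 12), det=(33, 33))
    back = load_dataset(save_dataset(ds, tmp_path / "d.h5"))
    assert back.counts.shape == (16, 12, 33, 33)


def test_missing_signal_is_format_error(tmp_path):
    import h5py
    with h5py.File(tmp_path / "empty.h5", "w") as f:
        f.attrs["format"] = "sedlab-4d"
    with pytest.raises(FormatError):
        load_dataset(tmp_path / "empty.h5")


def test_non_finite_counts_rejected(tmp_path):
    counts = np.ones((8, 8, 16, 16))
    counts[0, 0, 0, 0] = np.nan
    np.save(tmp_path / "bad.npy", counts)
    with pytest.raises(DataError):
        load_dataset(tmp_path / "bad.npy")


def test_dataset_validation():
    with pytest.raises(DataError):
        Dataset4D(np.ones((4, 8, 8, 8)) * -1.0)
    with pytest.raises(DataError):
        Dataset4D(np.ones((4, 4, 8, 8)))  # dims >= 8
    with pytest.raises(DataError):
        Dataset4D(np.ones((8, 8, 8, 8)), beam_center=(20.0, 2.0))


def test_calibration_requires_invertible_affine():
    with pytest.raises(ValueError):
        Calibration(np.zeros((2, 2, 2)), affine=np.zeros((2, 2)))


# ---------------------------------------------------------------- centering

def test_centering_identity_case():
    ds = make_tiny_dataset()
    out, calib = center_and_correct(ds)
    assert np.abs(calib.center_shift_map).max() < 0.05
    np.testing.assert_allclose(out.counts, ds.counts, atol=0.5)


def test_centering_recovers_injected_shift():
    ds = make_tiny_dataset(det=(48, 48))
    # inject a known sub-pixel translation into every pattern
    ny, nx = ds.detector_shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    phase = np.exp(-2j * np.pi * (ky * (-2.1) + kx * 3.4))
    shifted = np.fft.ifft2(np.fft.fft2(ds.counts) * phase).real.clip(0)
    out, calib = center_and_correct(Dataset4D(shifted, geometry=ds.geometry))
    np.testing.assert_allclose(calib.center_shift_map[..., 0], -3.4, atol=0.1)
    np.testing.assert_allclose(calib.center_shift_map[..., 1], 2.1, atol=0.1)


def test_centering_idempotent():
    ds = make_tiny_dataset(det=(48, 48))
    once, _ = center_and_correct(ds)
    _, calib2 = center_and_correct(once)
    assert np.abs(calib2.center_shift_map).max() < 0.05


def test_centering_failure_lists_positions():
    ds = make_tiny_dataset(beam=200.0)
    counts = ds.counts.copy()
    counts[2, 3] = 0.0  # no beam at one position
    with pytest.raises(CenteringError) as err:
        center_and_correct(ds.replace_counts(counts))
    assert (2, 3) in err.value.positions


def test_affine_correction_restores_circular_ring():
    """A ring stretched by diag(1.1, 1) regains radial std < 0.2 px after
    correcting with the inverse stretch."""
    ny = nx = 64
    y, x = np.mgrid[:ny, :nx]
    cx = cy = (nx - 1) / 2.0
    r0 = 18.0
    distort = np.diag([1.1, 1.0])  # k_meas = distort @ k_true
    xd = (x - cx) / 1.1
    ring = np.exp(-((np.hypot(xd, y - cy) - r0) ** 2) / 2.0) * 100.0
    beam = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / 8.0) * 300.0
    counts = np.broadcast_to(ring + beam, (8, 8, ny, nx)).copy()
    ds = Dataset4D(counts)
    out, _ = center_and_correct(ds, reference_disc_radius=2.0,
                                affine=np.linalg.inv(distort))

    def sector_radius_std(pat):
        """Brute-force radial profile: ring-radius centroid per 10-degree
        azimuthal sector, spread across sectors."""
        yy, xx = np.mgrid[:ny, :nx]
        rr = np.hypot(xx - cx, yy - cy)
        th = np.arctan2(yy - cy, xx - cx)
        sel = np.abs(rr - r0) < 5
        w = np.clip(pat - np.median(pat), 0, None)
        radii = []
        for t0 in np.arange(-np.pi, np.pi, np.pi / 18):
            m = sel & (th >= t0) & (th < t0 + np.pi / 18)
            if w[m].sum() > 0:
                radii.append((rr[m] * w[m]).sum() / w[m].sum())
        return float(np.std(radii))

    assert sector_radius_std(out.counts[0, 0]) < 0.2
    # without the correction the stretched ring fails the same bound
    out2, _ = center_and_correct(ds, reference_disc_radius=2.0)
    assert sector_radius_std(out2.counts[0, 0]) > 0.2


# ---------------------------------------------------------------- binning

def test_bin_factor_one_is_identity():
    ds = make_tiny_dataset()
    out = bin_patterns(ds, 1)
    np.testing.assert_array_equal(out.counts, ds.counts)


def test_bin_uniform_blocks():
    ds = Dataset4D(np.ones((8, 8, 16, 16)))
    out = bin_patterns(ds, 2)
    assert out.counts.shape == (8, 8, 8, 8)
    np.testing.assert_array_equal(out.counts, 4.0)
    assert out.detector_cal == 2.0


def test_bin_conserves_counts_over_retained_region():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(8, 8, 17, 18))
    ds = Dataset4D(counts)
    out = bin_patterns(ds, 2)
    expected = counts[:, :, :16, :18].sum(axis=(2, 3))
    np.testing.assert_array_equal(out.counts.sum(axis=(2, 3)), expected)


def test_bin_rejects_bad_factor():
    ds = make_tiny_dataset()
    with pytest.raises(ValueError):
        bin_patterns(ds, 0)


# ---------------------------------------------------------------- ADF/mean

def _brute_force_adf(ds, r_in, r_out):
    ny_s, nx_s = ds.scan_shape
    bx, by = ds.center
    out = np.zeros((ny_s, nx_s))
    for iy in range(ny_s):
        for ix in range(nx_s):
            pat = ds.counts[iy, ix]
            for py in range(pat.shape[0]):
                for px in range(pat.shape[1]):
                    r = np.hypot(py - by, px - bx) * ds.detector_cal
                    if r_in <= r <= r_out:
                        out[iy, ix] += pat[py, px]
    return out


def test_adf_equals_brute_force_oracle():
    rng = np.random.default_rng(3)
    ds = Dataset4D(rng.integers(0, 20, size=(8, 8, 16, 16)),
                   detector_cal=0.05)
    got = adf_image(ds, 0.12, 0.35)
    np.testing.assert_array_equal(got, _brute_force_adf(ds, 0.12, 0.35))


def test_adf_uniform_pattern_counts_annulus_pixels():
    ds = Dataset4D(np.full((8, 8, 16, 16), 3.0), detector_cal=0.05)
    bx, by = ds.center
    y, x = np.mgrid[:16, :16]
    n_pix = (((np.hypot(y - by, x - bx) * 0.05) >= 0.12)
             & ((np.hypot(y - by, x - bx) * 0.05) <= 0.35)).sum()
    np.testing.assert_allclose(adf_image(ds, 0.12, 0.35), 3.0 * n_pix)


def test_adf_excludes_inside_inner_radius():
    counts = np.zeros((8, 8, 32, 32))
    ds0 = Dataset4D(counts.copy(), detector_cal=0.05)
    bx, by = ds0.center
    # a bright pixel at |k| ~ 0.05 1/A, one pixel from centre
    counts[:, :, int(by), int(bx) + 1] = 100.0
    ds = Dataset4D(counts, detector_cal=0.05)
    np.testing.assert_array_equal(adf_image(ds, 0.12, 0.7), 0.0)


def test_adf_warns_when_annulus_truncated():
    ds = make_tiny_dataset(detector_cal=0.01)
    with pytest.warns(UserWarning, match="truncated"):
        adf_image(ds, 0.05, 1.0)


def test_mean_pattern_semantics():
    rng = np.random.default_rng(1)
    counts = rng.random((8, 8, 16, 16))
    ds = Dataset4D(counts + 0.01)
    mask = np.zeros((8, 8), dtype=bool)
    mask[2, 3] = True
    np.testing.assert_allclose(mean_pattern(ds, mask), ds.counts[2, 3])
    mask[5, 1] = True
    np.testing.assert_allclose(
        mean_pattern(ds, mask), (ds.counts[2, 3] + ds.counts[5, 1]) / 2.0)
    np.testing.assert_allclose(mean_pattern(ds),
                               ds.counts.mean(axis=(0, 1)))
    with pytest.raises(ValueError):
        mean_pattern(ds, np.zeros((8, 8), dtype=bool))


def test_sqrt_display_clips_negative():
    np.testing.assert_allclose(sqrt_display(np.array([-1.0, 4.0])),
                               [0.0, 2.0])
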