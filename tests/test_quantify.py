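"""Sensitivity correction, calibration, dilation, GTM and PV correction."""

import numpy as np
import pytest

from dyno17 import (
    MaskSet,
    TimeSeries4D,
    Volume,
    build_gtm,
    calibrate_concentration,
    dilate_mask,
    pv_correct_series,
    region_mean_series,
    sensitivity_correct,
)
from dyno17.core import GridMismatchError
from dyno17.quantify import NATURAL_ABUNDANCE_H2O17_MMOL_L

from oracles import dilate_bfs, gaussian_blur_explicit

VOX = (7.5, 7.5, 7.5)


def _series(data):
    return TimeSeries4D(data, VOX, 1.0, t_a_min=10, t_b_min=21)


# --- sensitivity correction -------------------------------------------------


def test_unit_map_is_identity():
    data = np.random.default_rng(0).uniform(1, 2, size=(4, 4, 4, 3))
    out = sensitivity_correct(_series(data), Volume(np.ones((4, 4, 4)), VOX))
    assert np.array_equal(out.data, data)


def test_sine_mode_flip_angle_ratio():
    # actual 30 deg vs nominal 60 deg -> divide by sin30/sin60, i.e. x sqrt(3)
    data = np.ones((2, 2, 2, 1))
    fmap = Volume(np.full((2, 2, 2), 30.0), VOX)
    out = sensitivity_correct(_series(data), fmap, mode="sine", nominal_flip_deg=60)
    assert out.data.flat[0] == pytest.approx(1.7320508, abs=1e-6)


def test_nonpositive_map_voxels_become_invalid():
    data = np.ones((2, 2, 2, 2))
    m = np.ones((2, 2, 2))
    m[0, 0, 0] = 0.0
    out = sensitivity_correct(_series(data), Volume(m, VOX))
    assert np.isnan(out.data[0, 0, 0]).all()
    assert np.isfinite(out.data[1, 1, 1]).all()


def test_all_invalid_map_rejected():
    with pytest.raises(ValueError, match="invalid everywhere"):
        sensitivity_correct(_series(np.ones((2, 2, 2, 1))),
                            Volume(np.zeros((2, 2, 2)), VOX))


def test_grid_mismatch_rejected():
    with pytest.raises(GridMismatchError):
        sensitivity_correct(_series(np.ones((2, 2, 2, 1))),
                            Volume(np.ones((3, 3, 3)), VOX))


def test_phantom_bias_field_inverted_exactly(clean_spec):
    """Dividing by the stored sensitivity field recovers the unbiased
    phantom voxel values in the noise-free case."""
    from dyno17 import PhantomSpec, build_label_volume, render_timeseries

    spec = PhantomSpec(psf_fwhm_mm=0.0, bias_amplitude=0.25, noise_cv=0.0, seed=4)
    labels, masks = build_label_volume(spec)
    biased, truth = render_timeseries(labels, masks, spec)
    corrected = sensitivity_correct(biased, truth.sensitivity)
    clean = PhantomSpec(psf_fwhm_mm=0.0, bias_amplitude=0.0, noise_cv=0.0, seed=4)
    unbiased, _ = render_timeseries(labels, masks, clean)
    assert np.allclose(corrected.data, unbiased.data, rtol=1e-12)


# --- concentration calibration ----------------------------------------------


def test_reference_signal_maps_to_reference_concentration():
    out = calibrate_concentration(_series(np.full((2, 2, 2, 1), 100.0)), ref_signal=100.0)
    assert np.allclose(out.data, NATURAL_ABUNDANCE_H2O17_MMOL_L)
    assert NATURAL_ABUNDANCE_H2O17_MMOL_L == pytest.approx(55.35 * 3.7e-4 * 1000, abs=0.005)


def test_zero_signal_maps_to_zero():
    out = calibrate_concentration(_series(np.zeros((2, 2, 2, 1))), ref_signal=50.0)
    assert np.all(out.data == 0.0)


def test_nonpositive_reference_rejected():
    with pytest.raises(ValueError):
        calibrate_concentration(_series(np.ones((2, 2, 2, 1))), ref_signal=0.0)


# --- mask dilation ------------------------------------------------------------


def test_single_voxel_dilation_counts():
    mask = np.zeros((9, 9, 9), dtype=bool)
    mask[4, 4, 4] = True
    assert dilate_mask(mask, 1).sum() == 7  # voxel + 6 face neighbours
    assert dilate_mask(mask, 2).sum() == 25  # L1 ball of radius 2


@pytest.mark.parametrize("iterations", [0, 1, 2, 3])
def test_dilation_matches_lattice_bfs(iterations):
    rng = np.random.default_rng(3)
    mask = rng.random((8, 8, 8)) > 0.9
    expected = dilate_bfs(mask, iterations)
    assert np.array_equal(dilate_mask(mask, iterations), expected)


def test_dilation_contains_input_and_handles_empty():
    mask = np.zeros((5, 5, 5), dtype=bool)
    assert not dilate_mask(mask, 2).any()
    mask[2, 2, 2] = True
    out = dilate_mask(mask, 2)
    assert out[mask].all()
    with pytest.raises(ValueError):
        dilate_mask(mask, -1)


# --- geometric transfer matrix ------------------------------------------------


def _half_space_masks(n=12):
    a = np.zeros((n, n, n), dtype=bool)
    b = np.zeros((n, n, n), dtype=bool)
    a[: n // 2] = True
    b[n // 2:] = True
    return MaskSet({"A": a, "B": b}, VOX)


def test_delta_psf_gives_identity_gtm():
    gtm = build_gtm(_half_space_masks(), psf_fwhm_mm=0.0)
    assert np.allclose(gtm.matrix, np.eye(2))
    assert gtm.condition_number == pytest.approx(1.0)


def test_gtm_rows_match_explicit_convolution_oracle():
    masks = _half_space_masks()
    fwhm = 11.25
    gtm = build_gtm(masks, fwhm)
    for i, ni in enumerate(("A", "B")):
        for j, nj in enumerate(("A", "B")):
            spread = gaussian_blur_explicit(masks[nj].astype(float), fwhm, VOX)
            assert gtm.matrix[i, j] == pytest.approx(spread[masks[ni]].mean(), abs=1e-6)


def test_gtm_rows_sum_to_one_with_background():
    # compartments + background tile the support, and blur preserves mass
    n = 14
    a = np.zeros((n, n, n), dtype=bool)
    b = np.zeros((n, n, n), dtype=bool)
    a[4:7, 4:10, 4:10] = True
    b[7:10, 4:10, 4:10] = True
    gtm = build_gtm(MaskSet({"A": a, "B": b}, VOX), psf_fwhm_mm=9.0)
    sums = gtm.matrix.sum(axis=1) + gtm.background
    assert np.allclose(sums, 1.0, atol=1e-6)


def test_overlapping_or_empty_compartments_rejected():
    n = 8
    a = np.zeros((n, n, n), dtype=bool)
    a[:5] = True
    b = np.zeros((n, n, n), dtype=bool)
    b[4:] = True  # overlaps a
    with pytest.raises(ValueError, match="mutually exclusive"):
        build_gtm(MaskSet({"A": a, "B": b}, VOX), 0.0)
    with pytest.raises(ValueError, match="empty"):
        build_gtm(MaskSet({"A": a, "B": np.zeros_like(b)}, VOX), 0.0)


def test_near_singular_gtm_rejected():
    with pytest.raises(ValueError, match="singular"):
        build_gtm(_half_space_masks(), psf_fwhm_mm=30.0, max_condition=1.2)


# --- PV correction ------------------------------------------------------------


def test_identity_gtm_reduces_to_regional_means():
    rng = np.random.default_rng(8)
    data = rng.uniform(1, 3, size=(12, 12, 12, 5))
    masks = _half_space_masks()
    series = _series(data)
    gtm = build_gtm(masks, 0.0)
    curves = pv_correct_series(series, masks, gtm)
    for name in ("A", "B"):
        plain = region_mean_series(series, masks[name])
        assert np.allclose(curves[name].values, plain.values)


def test_two_compartment_phantom_recovered_exactly():
    """Blurring mixes the 10/20 plateau values; the GTM solve unmixes them
    while plain regional means stay biased."""
    masks = _half_space_masks(16)
    truth = {"A": 10.0, "B": 20.0}
    img = np.zeros((16, 16, 16))
    for name, value in truth.items():
        img[masks[name]] = value
    from dyno17 import apply_psf

    blurred = apply_psf(img, 11.25, VOX)
    series = _series(blurred[..., None])
    gtm = build_gtm(masks, 11.25)
    curves = pv_correct_series(series, masks, gtm)
    for name, value in truth.items():
        assert curves[name].values[0] == pytest.approx(value, abs=1e-6)
        plain = blurred[masks[name]].mean()
        assert abs(plain - value) > 0.1  # the uncorrected mean is visibly biased


def test_end_to_end_phantom_pv_recovery(blurred_phantom):
    """Noiseless blurred phantom: PV-corrected compartment curves equal the
    ground-truth curves to numerical precision."""
    from dyno17 import roi_compartments

    spec, _, masks, series, truth = blurred_phantom
    comps = roi_compartments(masks)
    gtm = build_gtm(comps, spec.psf_fwhm_mm, spec.voxel_size_mm, dilate_iterations=2)
    curves = pv_correct_series(series, comps, gtm)
    for name in ("GM_S_left", "GM_C_right", "WM_N_left", "CSF_N_right"):
        expected = truth.region_curves[name].values
        rel = np.abs(curves[name].values - expected) / expected
        assert rel.max() < 1e-6
        plain = series.data[comps[name], :].mean(axis=0)
        assert np.max(np.abs(plain - expected) / expected) > 1e-3


def test_pv_correction_amplifies_noise_in_small_rois(noisy_phantom):
    """Small stimulated-patch compartments end up noisier than the large
    non-stimulated compartments after PV correction."""
    from dyno17 import roi_compartments

    spec, _, masks, series, _ = noisy_phantom
    comps = roi_compartments(masks)
    gtm = build_gtm(comps, psf_fwhm_mm=0.0)
    curves = pv_correct_series(series, comps, gtm)
    var_small = np.var(curves["GM_S_left"].values[:10])
    var_large = np.var(curves["GM_N_right"].values[:10])
    assert var_small > var_large
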