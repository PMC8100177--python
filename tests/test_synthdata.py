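"""Generator: cohort sampling, phantom rendering, quality degradation."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import truncnorm

from rnflgray.errors import ConfigurationError, GeometryError
from rnflgray.quality import QCAL_MAX
from rnflgray.quantify import compute_imageq
from rnflgray.sectors import column_sectors
from rnflgray.synthdata import (
    CovariateSpec,
    GenerativeParams,
    cohort_to_frame,
    degrade_quality,
    render_bscan,
    sample_cohort,
    thickness_profile_um,
)


# ------------------------------------------------------------------ sampling

def test_empty_cohort(default_params):
    assert sample_cohort(default_params, 0) == []


def test_negative_n_rejected(default_params):
    with pytest.raises(ValueError):
        sample_cohort(default_params, -1)


def test_determinism(default_params):
    a = sample_cohort(default_params, 20)
    b = sample_cohort(default_params, 20)
    for ta, tb in zip(a, b):
        assert ta.age == tb.age and ta.avg_gray_true == tb.avg_gray_true
        np.testing.assert_array_equal(ta.sector_gray_true, tb.sector_gray_true)


def test_cohort_moments_match_truncated_normal_expectations(default_params):
    """With n = 5000, every covariate's sample mean must sit within 3 SE
    of its truncated-normal expectation (truncation shifts the mean away
    from the parent normal's, so the correction matters)."""
    n = 5000
    cohort = sample_cohort(default_params, n)
    df = cohort_to_frame(cohort)
    for name in ("age", "se", "bcva", "al", "iop", "vf_md", "rpe_gray", "imageq"):
        spec = default_params.covariates[name]
        m, v = spec.moments()
        se = np.sqrt(v / n)
        assert abs(df[name].mean() - m) < 3 * se, name
    # binary covariates
    p = default_params.male_fraction
    assert abs(df["sex"].mean() - p) < 3 * np.sqrt(p * (1 - p) / n)
    # the grayscale model target
    assert abs(df["true_avg_gray"].mean() - default_params.mean_gray) < 3 * (
        default_params.total_gray_sd / np.sqrt(n)
    )


def test_truncation_bounds_respected(default_params):
    df = cohort_to_frame(sample_cohort(default_params, 2000))
    for name in ("age", "al", "imageq"):
        spec = default_params.covariates[name]
        assert df[name].min() >= spec.lo and df[name].max() <= spec.hi


def test_age_truncated_mean_uses_correction():
    """Sanity-check the analytic moments against scipy's truncnorm."""
    spec = CovariateSpec(44.63, 16.43, 18.0, 80.0)
    a = (18.0 - 44.63) / 16.43
    b = (80.0 - 44.63) / 16.43
    m, v = truncnorm(a, b, loc=44.63, scale=16.43).stats(moments="mv")
    assert spec.moments() == pytest.approx((float(m), float(v)))


def test_linear_model_fidelity_noise_free():
    """With the residual budget driven to zero, regressing the true
    grayscale on the effect covariates returns the configured slopes to
    numerical precision."""
    base = GenerativeParams(seed=3)
    explained_sd = np.sqrt(base.explained_gray_variance())
    params = dataclasses.replace(base, total_gray_sd=float(explained_sd))
    assert params.residual_gray_sd() == pytest.approx(0.0, abs=1e-7)
    df = cohort_to_frame(sample_cohort(params, 400))
    X = np.column_stack(
        [np.ones(len(df))] + [df[k].to_numpy() for k in params.effects]
    )
    beta, *_ = np.linalg.lstsq(X, df["true_avg_gray"].to_numpy(), rcond=None)
    for j, (name, slope) in enumerate(params.effects.items(), start=1):
        assert beta[j] == pytest.approx(slope, abs=1e-8), name
    assert beta[0] == pytest.approx(params.intercept(), abs=1e-6)


def test_variance_budget_overflow_raises():
    with pytest.raises(ConfigurationError, match="variance budget"):
        GenerativeParams(total_gray_sd=1.0)


def test_invalid_covariate_spec():
    with pytest.raises(ConfigurationError):
        CovariateSpec(mean=10.0, sd=-1.0, lo=0.0, hi=20.0)
    with pytest.raises(ConfigurationError):
        CovariateSpec(mean=30.0, sd=1.0, lo=0.0, hi=20.0)


def test_sector_offsets_out_of_range_rejected():
    with pytest.raises(ConfigurationError):
        GenerativeParams(
            sector_gray_offsets={
                "T": 0, "IT": 0, "IN": 0, "N": 200.0, "SN": 0, "ST": 0
            }
        )


# ------------------------------------------------------------------ rendering

def test_rendered_image_has_device_geometry(speckled_eye):
    _, image, _ = speckled_eye
    assert image.n_columns == 1024
    assert image.pixels.dtype == np.uint8
    assert image.scan_diameter == pytest.approx(3.46)


def test_ground_truth_boundary_ordering(speckled_eye):
    _, image, gt = speckled_eye
    assert np.all(gt.ilm <= gt.rnfl_post)
    assert np.all(gt.rnfl_post <= gt.rpe_inner)
    assert np.all(gt.rpe_inner <= gt.rpe_outer)
    assert np.all(gt.rpe_outer < image.n_rows)


def test_ground_truth_reflectivity_matches_sector_truth(speckled_eye):
    """Averaging the recorded per-column reflectivity over a sector's
    columns must reproduce the sector grayscale truth exactly."""
    truth, image, gt = speckled_eye
    sec = column_sectors(image.n_columns, truth.laterality)
    for k in range(6):
        cols = sec == k
        assert np.mean(gt.rnfl_refl[cols]) == pytest.approx(
            truth.sector_gray_true[k], abs=1e-6
        )


def test_thickness_profile_sector_means_exact(small_cohort):
    truth = small_cohort[2]
    prof = thickness_profile_um(truth.sector_thickness_true)
    sec = column_sectors(prof.shape[0], "OD")
    for k in range(6):
        assert prof[sec == k].mean() == pytest.approx(
            truth.sector_thickness_true[k], abs=1e-9
        )
    # smooth enough for the DP transition bound (circular wrap included)
    jumps = np.abs(np.diff(np.r_[prof, prof[0]])) / 5.0  # px at 5 um/px
    assert jumps.max() < 3.0


def test_noise_free_sector_pixel_means_match_truth(noise_free_eye):
    """Without speckle the in-band pixel mean per sector equals the
    sector grayscale truth to within 8-bit quantisation."""
    truth, image, gt = noise_free_eye
    sec = column_sectors(image.n_columns, truth.laterality)
    rows = np.arange(image.n_rows)[:, None]
    band = (rows >= np.ceil(gt.ilm)) & (rows < np.ceil(gt.rnfl_post))
    for k in range(6):
        mask = band & (sec == k)[None, :]
        assert image.pixels[mask].mean() == pytest.approx(
            truth.sector_gray_true[k], abs=0.5
        )


def test_speckled_sector_mean_within_monte_carlo_band(speckled_eye):
    """Speckle is unit-mean, so in-band pixel means stay centred on the
    reflectivity truth; the tolerance comes from an independent
    brute-force Monte-Carlo of the speckle law (gamma draws -> quantise
    -> clip), not from the renderer."""
    truth, image, gt = speckled_eye
    rows = np.arange(image.n_rows)[:, None]
    band = (rows >= np.ceil(gt.ilm)) & (rows < np.ceil(gt.rnfl_post))
    refl = np.broadcast_to(gt.rnfl_refl, image.pixels.shape)[band]
    observed = image.pixels[band].mean() - refl.mean()

    mc = np.random.default_rng(123)
    shape = 60.0
    reps = np.empty(200)
    for i in range(reps.size):
        sim = np.clip(np.rint(refl * mc.gamma(shape, 1 / shape, refl.size)), 0, 255)
        reps[i] = sim.mean() - refl.mean()
    assert refl.size >= 10_000
    assert abs(observed - reps.mean()) < 3 * reps.std() + 3 * reps.std() / np.sqrt(200)


def test_os_eye_is_mirrored(noise_free_params):
    """Rendering the same truth as OD and OS gives anatomically
    mirrored pixels.  Because columns sample angles {360 c / N}, the
    mirror of the sampled circle is a horizontal flip followed by a
    one-column roll (angle -theta lands on column N - c, not N - 1 - c).
    """
    truth = sample_cohort(noise_free_params, 2)[0]
    od = dataclasses.replace(truth, laterality="OD")
    os_ = dataclasses.replace(truth, laterality="OS")
    img_od, gt_od = render_bscan(od, noise_free_params)
    img_os, gt_os = render_bscan(os_, noise_free_params)
    np.testing.assert_array_equal(
        img_os.pixels, np.roll(img_od.pixels[:, ::-1], 1, axis=1)
    )
    np.testing.assert_array_equal(gt_os.ilm, np.roll(gt_od.ilm[::-1], 1))


def test_render_geometry_error_when_frame_too_short(small_cohort, default_params):
    with pytest.raises(GeometryError):
        render_bscan(small_cohort[0], default_params, height=150)


# ------------------------------------------------------------------ degradation

def test_degrade_identity_at_calibration_max(speckled_eye):
    _, image, _ = speckled_eye
    out = degrade_quality(image, QCAL_MAX, np.random.default_rng(0))
    np.testing.assert_array_equal(out.pixels, image.pixels)


def test_degrade_monotone_in_quality(speckled_eye):
    _, image, _ = speckled_eye
    mad = {}
    for q in (45.0, 65.0):
        out = degrade_quality(image, q, np.random.default_rng(5))
        mad[q] = np.abs(
            out.pixels.astype(float) - image.pixels.astype(float)
        ).mean()
    assert mad[45.0] > mad[65.0] > 0.0


def test_degrade_outside_calibration_range(speckled_eye):
    _, image, _ = speckled_eye
    for bad in (39.9, 70.1):
        with pytest.raises(ValueError):
            degrade_quality(image, bad)


def test_degradation_calibration_loop(speckled_eye):
    """Degrading to knob 55 and re-measuring with the proxy must recover
    55 +/- 2 on average over 50 seeds."""
    _, image, _ = speckled_eye
    vals = [
        compute_imageq(degrade_quality(image, 55.0, np.random.default_rng(s)))
        for s in range(50)
    ]
    assert 53.0 <= np.mean(vals) <= 57.0
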