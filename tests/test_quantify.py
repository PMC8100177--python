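"""Quantification: band statistics, thickness, quality proxy, measure_eye."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from rnflgray.errors import MeasurementError, QCRefusalError
from rnflgray.image import BScanImage
from rnflgray.quantify import (
    compute_imageq,
    layer_grayscale,
    layer_pixel_count,
    layer_thickness,
    measure_eye,
)
from rnflgray.sectors import SECTOR_ORDER, column_sectors
from rnflgray.segmentation import LayerBoundaries, segment_boundaries
from rnflgray.synthdata import (
    degrade_quality,
    render_bscan,
    sample_cohort,
)


def _toy_image():
    """Small random image with fractional hand-written boundaries."""
    rng = np.random.default_rng(99)
    px = rng.integers(0, 256, size=(8, 64)).astype(np.uint8)
    upper = np.linspace(1.2, 2.8, 64)
    lower = np.linspace(4.9, 6.4, 64)
    return BScanImage(px, axial_scale=5.0), upper, lower


def _brute_force_band(px, upper, lower):
    """Independent per-pixel loop implementing the half-open ceil band."""
    vals, per_col = [], {}
    for c in range(px.shape[1]):
        lo = int(np.ceil(upper[c]))
        hi = int(np.ceil(lower[c]))
        col_vals = [float(px[r, c]) for r in range(lo, hi)]
        vals.extend(col_vals)
        if col_vals:
            per_col[c] = np.mean(col_vals)
    return vals, per_col


# ------------------------------------------------------------------ oracles

def test_layer_grayscale_matches_pixel_loop_oracle():
    image, upper, lower = _toy_image()
    vals, per_col = _brute_force_band(image.pixels, upper, lower)
    got = layer_grayscale(image, upper, lower)
    assert got == pytest.approx(np.sum(vals) / len(vals), abs=1e-12)
    got_cw = layer_grayscale(image, upper, lower, column_weighted=True)
    assert got_cw == pytest.approx(np.mean(list(per_col.values())), abs=1e-12)
    assert layer_pixel_count(image, upper, lower) == len(vals)


def test_layer_grayscale_constant_band():
    px = np.full((10, 64), 100, dtype=np.uint8)
    assert layer_grayscale(BScanImage(px), np.full(64, 2.0), np.full(64, 7.0)) == 100.0


def test_layer_grayscale_pixel_weighting():
    """Two columns with band heights 1 and 3: the pixel-weighted mean
    weights the taller column three times as much."""
    px = np.zeros((6, 64), dtype=np.uint8)
    px[1, 0] = 100
    px[1:4, 1] = 200
    upper = np.full(64, 1.0)
    lower = np.r_[2.0, 4.0, np.full(62, 1.0)]
    got = layer_grayscale(BScanImage(px), upper, lower, columns=np.array([0, 1]))
    assert got == pytest.approx((100 + 3 * 200) / 4)
    got_cw = layer_grayscale(
        BScanImage(px), upper, lower, columns=np.array([0, 1]), column_weighted=True
    )
    assert got_cw == pytest.approx((100 + 200) / 2)


def test_layer_grayscale_empty_band_raises():
    px = np.full((10, 64), 50, dtype=np.uint8)
    with pytest.raises(MeasurementError):
        layer_grayscale(BScanImage(px), np.full(64, 3.0), np.full(64, 3.0))


def test_layer_thickness_examples():
    upper = np.full(64, 10.0)
    assert layer_thickness(upper, upper + 20.0, 5.0) == pytest.approx(100.0)
    assert layer_thickness(upper, upper, 5.0) == 0.0
    with pytest.raises(ValueError):
        layer_thickness(upper, upper - 1.0, 5.0)


def test_thickness_recovered_within_5um_per_sector(speckled_eye):
    """Against the ground-truth sidecar, segmented sector thickness must
    land within one pixel (5 um) of the generative truth."""
    truth, image, gt = speckled_eye
    b = segment_boundaries(image)
    sec = column_sectors(image.n_columns, truth.laterality)
    for k in range(6):
        cols = np.flatnonzero(sec == k)
        got = layer_thickness(b.ilm, b.rnfl_post, image.axial_scale, cols)
        assert got == pytest.approx(truth.sector_thickness_true[k], abs=5.0)


# ------------------------------------------------------------------ closure

def test_weighted_mean_closure(speckled_eye):
    """gray_mean must equal the pixel-count-weighted mean of the sector
    grays, and thick_mean the column-count-weighted sector mean."""
    truth, image, _ = speckled_eye
    b = segment_boundaries(image)
    m = measure_eye(image, b)
    sec = column_sectors(image.n_columns, truth.laterality)
    counts = np.array([
        layer_pixel_count(image, b.ilm, b.rnfl_post, np.flatnonzero(sec == k))
        for k in range(6)
    ])
    grays = np.array([m.gray_sectors[s] for s in SECTOR_ORDER])
    assert m.gray_mean == pytest.approx(
        float((grays * counts).sum() / counts.sum()), abs=1e-9
    )
    col_counts = np.bincount(sec, minlength=6)
    thicks = np.array([m.thick_sectors[s] for s in SECTOR_ORDER])
    assert m.thick_mean == pytest.approx(
        float((thicks * col_counts).sum() / col_counts.sum()), abs=1e-9
    )


def test_range_preservation(speckled_eye):
    _, image, _ = speckled_eye
    b = segment_boundaries(image)
    m = measure_eye(image, b)
    lo, hi = float(image.pixels.min()), float(image.pixels.max())
    for v in [m.gray_mean, m.rpe_gray, *m.gray_sectors.values()]:
        assert lo <= v <= hi


# ------------------------------------------------------------------ laterality

def test_laterality_invariance(noise_free_params):
    """Measuring an OS rendering must equal measuring the OD rendering
    of the same truth, sector for sector, exactly (the two frames hold
    the same set of A-scans)."""
    truth = sample_cohort(noise_free_params, 2)[0]
    results = {}
    for lat in ("OD", "OS"):
        t = dataclasses.replace(truth, laterality=lat)
        image, gt = render_bscan(t, noise_free_params)
        b = LayerBoundaries(
            ilm=gt.ilm, rnfl_post=gt.rnfl_post,
            rpe_inner=gt.rpe_inner, rpe_outer=gt.rpe_outer,
        )
        results[lat] = measure_eye(image, b)
    for s in SECTOR_ORDER:
        assert results["OD"].gray_sectors[s] == results["OS"].gray_sectors[s]
        assert results["OD"].thick_sectors[s] == results["OS"].thick_sectors[s]
    assert results["OD"].gray_mean == results["OS"].gray_mean


# ------------------------------------------------------------------ imageq proxy

def test_imageq_noise_free_at_ceiling(noise_free_eye):
    _, image, _ = noise_free_eye
    assert compute_imageq(image) >= 65.0


def test_imageq_pure_noise_below_gate():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 256, size=(480, 1024)).astype(np.uint8)
    assert compute_imageq(BScanImage(px)) < 45.0


def test_imageq_monotone_in_knob(speckled_eye):
    """Spearman correlation between degradation knob and proxy must be
    a perfect 1.0 across the five calibration levels, every seed."""
    _, image, _ = speckled_eye
    levels = np.array([45.0, 50.0, 55.0, 60.0, 65.0])
    for seed in range(20):
        proxies = [
            compute_imageq(degrade_quality(image, q, np.random.default_rng(seed)))
            for q in levels
        ]
        rho, _ = spearmanr(levels, proxies)
        assert rho == pytest.approx(1.0)


# ------------------------------------------------------------------ measure_eye

def test_equal_sector_truth_gives_equal_sector_grays(noise_free_params):
    """With all sector offsets zero, all six measured sector grays equal
    the overall mean (up to quantisation of a shared reflectivity)."""
    params = dataclasses.replace(
        noise_free_params,
        sector_gray_offsets={s: 0.0 for s in SECTOR_ORDER},
    )
    truth = sample_cohort(params, 1)[0]
    image, gt = render_bscan(truth, params)
    b = LayerBoundaries(
        ilm=gt.ilm, rnfl_post=gt.rnfl_post,
        rpe_inner=gt.rpe_inner, rpe_outer=gt.rpe_outer,
    )
    m = measure_eye(image, b)
    vals = list(m.gray_sectors.values())
    assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)


def test_nasal_depression_detected(speckled_eye):
    """The generative nasal offset is negative, so the nasal sector must
    come out lowest of the six."""
    truth, image, _ = speckled_eye
    b = segment_boundaries(image)
    m = measure_eye(image, b)
    assert min(m.gray_sectors, key=m.gray_sectors.get) == "N"


def test_qc_refusal_and_override(speckled_eye):
    _, image, gt = speckled_eye
    bad = LayerBoundaries(
        ilm=np.full(image.n_columns, 20.0),
        rnfl_post=np.full(image.n_columns, 40.0),
        rpe_inner=gt.rpe_inner, rpe_outer=gt.rpe_outer,
    )
    with pytest.raises(QCRefusalError):
        measure_eye(image, bad)
    m = measure_eye(image, bad, override_qc=True)
    assert m.qc is not None and m.qc.misidentification


def test_device_quality_value_takes_precedence(speckled_eye):
    _, image, _ = speckled_eye
    b = segment_boundaries(image)
    tagged = dataclasses.replace(image, quality_factor=58.5)
    assert measure_eye(tagged, b).imageq == 58.5
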