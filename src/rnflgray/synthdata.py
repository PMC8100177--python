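"""Synthetic peripapillary cohorts and circular-scan B-scan phantoms.

This module is the study-condition generator for the whole package: it
draws covariate profiles of healthy adult eyes, assigns each eye a true
average pRNFL grayscale value through a linear determinant model (older
age, longer axial length, lower RPE reflectivity and lower scan quality
all lower the value), and renders every eye as an 8-bit circular-scan
B-scan with exact ground-truth layer boundaries and reflectivities.

Model summary
-------------
* Covariates are independent truncated normals (plus Bernoulli sex),
  with default moments matching a normative adult cohort: age
  44.63 +/- 16.43 y on [18, 80], axial length 23.73 +/- 1.13 mm, scan
  quality 55.4 +/- 4.35 on [45, 65], and so on.
* avg_gray_true = intercept + sum_j beta_j x_j + eps.  The intercept is
  solved so the cohort mean equals ``mean_gray`` (default 164.82), and
  Var(eps) is solved so the cohort SD equals ``total_gray_sd`` (default
  5.69); a configuration whose effects already explain more variance
  than that budget is rejected.
* Sector grayscale truths are the eye average plus fixed sector offsets
  (nasal lowest); sector thickness truths are the normative sector
  profile scaled per eye by a truncated-normal average thickness.
* Rendering: four-layer geometry (vitreous / pRNFL / inner retina / RPE)
  on a 1024-column, 5 um-per-pixel frame; the pRNFL thickness profile is
  a circularly smoothed sector-step plus a double-hump (superior and
  inferior bumps) ripple, mean-corrected per sector so sector means are
  exact; pixel intensities are layer reflectivities times unit-mean
  gamma speckle, quantised to 8 bits.  OS eyes are mirrored.

Seeding: one master seed in the params; every stochastic stage of eye i
uses ``numpy.random.SeedSequence([master_seed, stream, subject_id])``
with stream 1 = cohort sampling (subject_id 0), 2 = speckle,
3 = quality degradation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .errors import ConfigurationError, GeometryError
from .image import (
    DEFAULT_AXIAL_SCALE_UM,
    DEFAULT_N_COLUMNS,
    BScanImage,
)
from .quality import QCAL_MAX, QCAL_MIN, noise_sd_for_imageq
from .sectors import SECTOR_ORDER, column_angle, column_sectors

STREAM_COHORT = 1
STREAM_SPECKLE = 2
STREAM_DEGRADE = 3

#: Names of the continuous covariates, in sampling order.
CONTINUOUS_COVARIATES = ("age", "se", "bcva", "al", "iop", "vf_md", "rpe_gray", "imageq")


@dataclass(frozen=True)
class CovariateSpec:
    """Truncated-normal covariate: mean/SD of the parent normal and hard
    truncation bounds."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"negative SD {self.sd}")
        if not self.lo <= self.mean <= self.hi:
            raise ConfigurationError(
                f"mean {self.mean} outside bounds [{self.lo}, {self.hi}]"
            )

    def _dist(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm(a, b, loc=self.mean, scale=self.sd)

    def moments(self) -> tuple[float, float]:
        """(mean, variance) of the truncated distribution."""
        if self.sd == 0:
            return self.mean, 0.0
        m, v = self._dist().stats(moments="mv")
        return float(m), float(v)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        return self._dist().rvs(size=n, random_state=rng)


def _default_covariates() -> dict[str, CovariateSpec]:
    return {
        "age": CovariateSpec(44.63, 16.43, 18.0, 80.0),
        "se": CovariateSpec(-0.78, 1.85, -6.0, 3.5),
        "bcva": CovariateSpec(0.006, 0.075, -0.2, 0.3),
        "al": CovariateSpec(23.73, 1.13, 20.7, 26.0),
        "iop": CovariateSpec(14.43, 2.87, 7.9, 21.0),
        "vf_md": CovariateSpec(-1.01, 1.37, -2.47, 2.75),
        "rpe_gray": CovariateSpec(170.0, 8.0, 140.0, 200.0),
        "imageq": CovariateSpec(55.4, 4.35, 45.0, 65.0),
    }


def _default_effects() -> dict[str, float]:
    # Gray levels per unit covariate for the average-grayscale model;
    # covariates absent here have a true effect of zero.
    return {"age": -0.053, "al": -0.664, "rpe_gray": 0.372, "imageq": 0.658}


def _default_gray_offsets() -> dict[str, float]:
    # Sector mean minus overall mean, gray levels (normative pattern:
    # nasal clearly lowest, inferior sectors slightly brightest).
    return {"T": 0.38, "IT": 0.79, "IN": 0.95, "N": -1.56, "SN": 0.27, "ST": 0.27}


def _default_sector_thickness() -> dict[str, float]:
    # Normative sector mean thickness in um (double-hump / ISNT pattern).
    return {"T": 84.77, "IT": 144.34, "IN": 123.74, "N": 79.59, "SN": 124.30, "ST": 132.32}


@dataclass(frozen=True)
class GenerativeParams:
    """Everything that defines a synthetic cohort and its rendering."""

    covariates: dict[str, CovariateSpec] = field(default_factory=_default_covariates)
    male_fraction: float = 0.494
    effects: dict[str, float] = field(default_factory=_default_effects)
    mean_gray: float = 164.82
    total_gray_sd: float = 5.69
    sector_gray_offsets: dict[str, float] = field(default_factory=_default_gray_offsets)
    thickness_mean: float = 106.68
    sector_thickness: dict[str, float] = field(default_factory=_default_sector_thickness)
    thickness_sd: float = 8.89
    thickness_bounds: tuple[float, float] = (60.0, 160.0)
    speckle_shape: float | None = 60.0
    background_refl: float = 25.0
    inner_retina_refl: float = 90.0
    retina_gap_um: float = 180.0
    rpe_band_um: float = 25.0
    ilm_row_um: float = 600.0
    ilm_wave_um: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(CONTINUOUS_COVARIATES) - set(self.covariates)
        if missing:
            raise ConfigurationError(f"missing covariate specs: {sorted(missing)}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        bad = set(self.effects) - set(CONTINUOUS_COVARIATES) - {"sex"}
        if bad:
            raise ConfigurationError(f"effects on unknown covariates: {sorted(bad)}")
        for label in SECTOR_ORDER:
            if label not in self.sector_gray_offsets:
                raise ConfigurationError(f"missing sector gray offset {label}")
            if label not in self.sector_thickness:
                raise ConfigurationError(f"missing sector thickness {label}")
            mean_s = self.mean_gray + self.sector_gray_offsets[label]
            if not 0.0 <= mean_s <= 255.0:
                raise ConfigurationError(
                    f"sector {label} mean grayscale {mean_s} outside [0, 255]"
                )
            if self.sector_thickness[label] <= 0:
                raise ConfigurationError(f"sector {label} thickness must be positive")
        if self.total_gray_sd < 0 or self.thickness_sd < 0:
            raise ConfigurationError("SDs must be non-negative")
        if self.speckle_shape is not None and not self.speckle_shape > 0:
            raise ConfigurationError("speckle_shape must be positive (or None)")
        # Fail fast on an impossible variance budget.
        self.residual_gray_sd()

    # -- linear-model bookkeeping -------------------------------------

    def covariate_moments(self, name: str) -> tuple[float, float]:
        if name == "sex":
            p = self.male_fraction
            return p, p * (1.0 - p)
        return self.covariates[name].moments()

    def explained_gray_variance(self) -> float:
        """Variance of the linear predictor under independent covariates."""
        return float(
            sum(b * b * self.covariate_moments(k)[1] for k, b in self.effects.items())
        )

    def residual_gray_sd(self) -> float:
        resid = self.total_gray_sd**2 - self.explained_gray_variance()
        if resid < -1e-9:
            raise ConfigurationError(
                "variance budget exhausted: total_gray_sd^2 = "
                f"{self.total_gray_sd**2:.3f} < explained variance "
                f"{self.explained_gray_variance():.3f}"
            )
        return float(np.sqrt(max(resid, 0.0)))

    def intercept(self) -> float:
        """Intercept solving cohort E[avg_gray_true] = mean_gray."""
        shift = sum(b * self.covariate_moments(k)[0] for k, b in self.effects.items())
        return float(self.mean_gray - shift)


@dataclass(frozen=True)
class SubjectTruth:
    """Generative truth for one eye of one subject."""

    subject_id: int
    age: float
    sex: int  # 0 female, 1 male
    se: float
    bcva: float
    al: float
    iop: float
    vf_md: float
    rpe_gray_true: float
    imageq_true: float
    avg_gray_true: float
    sector_gray_true: np.ndarray  # six values, SECTOR_ORDER
    sector_thickness_true: np.ndarray  # six values, um, SECTOR_ORDER
    laterality: str


@dataclass
class GroundTruth:
    """Exact rendered geometry and reflectivity, one value per column.

    Boundary positions live on the half-integer lattice between pixel
    rows: a boundary at r - 0.5 separates pixel row r - 1 from row r, and
    a layer's pixels are the rows in [ceil(upper), ceil(lower)).
    """

    ilm: np.ndarray
    rnfl_post: np.ndarray
    rpe_inner: np.ndarray
    rpe_outer: np.ndarray
    rnfl_refl: np.ndarray
    rpe_refl: np.ndarray

    def validate(self, n_rows: int) -> None:
        tr = [self.ilm, self.rnfl_post, self.rpe_inner, self.rpe_outer]
        for up, lo in zip(tr[:-1], tr[1:]):
            if not np.all(up <= lo):
                raise AssertionError("boundary ordering violated")
        if not np.all(tr[-1] < n_rows):
            raise AssertionError("boundaries exceed image height")
        for refl in (self.rnfl_refl, self.rpe_refl):
            if refl.min() < 0 or refl.max() > 255:
                raise AssertionError("reflectivity outside [0, 255]")

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in vars(self).items()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=float) for k, v in payload.items()})


# ---------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------

def _rng_for(params: GenerativeParams, stream: int, subject_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), int(stream), int(subject_id)])
    )


def sample_cohort(params: GenerativeParams, n: int) -> list[SubjectTruth]:
    """Draw ``n`` independent subjects (one eye each) from the model.

    Deterministic given ``params.seed``; raises on negative ``n``.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return []
    rng = _rng_for(params, STREAM_COHORT, 0)

    draws = {k: params.covariates[k].sample(n, rng) for k in CONTINUOUS_COVARIATES}
    sex = rng.binomial(1, params.male_fraction, size=n)
    laterality = np.where(rng.integers(0, 2, size=n) == 0, "OD", "OS")

    linpred = np.full(n, params.intercept())
    for name, beta in params.effects.items():
        x = sex if name == "sex" else draws[name]
        linpred = linpred + beta * x
    eps = rng.normal(0.0, params.residual_gray_sd(), size=n)
    avg_gray = np.clip(linpred + eps, 0.0, 255.0)

    offsets = np.array([params.sector_gray_offsets[s] for s in SECTOR_ORDER])
    sector_means = np.array([params.sector_thickness[s] for s in SECTOR_ORDER])
    lo, hi = params.thickness_bounds
    if params.thickness_sd > 0:
        thick_spec = CovariateSpec(params.thickness_mean, params.thickness_sd, lo, hi)
        eye_thickness = thick_spec.sample(n, rng)
    else:
        eye_thickness = np.full(n, params.thickness_mean)
    scale = eye_thickness / params.thickness_mean

    cohort = []
    for i in range(n):
        cohort.append(
            SubjectTruth(
                subject_id=i + 1,
                age=float(draws["age"][i]),
                sex=int(sex[i]),
                se=float(draws["se"][i]),
                bcva=float(draws["bcva"][i]),
                al=float(draws["al"][i]),
                iop=float(draws["iop"][i]),
                vf_md=float(draws["vf_md"][i]),
                rpe_gray_true=float(draws["rpe_gray"][i]),
                imageq_true=float(draws["imageq"][i]),
                avg_gray_true=float(avg_gray[i]),
                sector_gray_true=np.clip(avg_gray[i] + offsets, 0.0, 255.0),
                sector_thickness_true=sector_means * scale[i],
                laterality=str(laterality[i]),
            )
        )
    return cohort


TRUTH_CSV_COLUMNS = [
    "subject_id", "age", "sex", "se", "bcva", "al", "iop", "vf_md",
    "rpe_gray", "imageq", "laterality",
    "true_avg_gray",
    *[f"true_gray_{s}" for s in SECTOR_ORDER],
    "true_thick_mean",
    *[f"true_thick_{s}" for s in SECTOR_ORDER],
]


def cohort_to_frame(cohort: list[SubjectTruth]) -> pd.DataFrame:
    """Cohort table with the documented column layout (one row per eye)."""
    rows = []
    for t in cohort:
        row = {
            "subject_id": t.subject_id, "age": t.age, "sex": t.sex, "se": t.se,
            "bcva": t.bcva, "al": t.al, "iop": t.iop, "vf_md": t.vf_md,
            "rpe_gray": t.rpe_gray_true, "imageq": t.imageq_true,
            "laterality": t.laterality, "true_avg_gray": t.avg_gray_true,
        }
        for k, s in enumerate(SECTOR_ORDER):
            row[f"true_gray_{s}"] = t.sector_gray_true[k]
        widths = np.array([90.0, 45.0, 45.0, 90.0, 45.0, 45.0])  # SECTOR_ORDER spans
        row["true_thick_mean"] = float(
            np.sum(t.sector_thickness_true * widths) / 360.0
        )
        for k, s in enumerate(SECTOR_ORDER):
            row[f"true_thick_{s}"] = t.sector_thickness_true[k]
        rows.append(row)
    return pd.DataFrame(rows, columns=TRUTH_CSV_COLUMNS)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

def thickness_profile_um(
    sector_thickness: np.ndarray,
    n_columns: int = DEFAULT_N_COLUMNS,
    laterality: str = "OD",
    smooth_deg: float = 10.0,
    ripple_amp_um: float = 6.0,
    ripple_kappa: float = 2.0,
) -> np.ndarray:
    """Per-column pRNFL thickness (um) in the eye's own frame.

    A circularly smoothed step over the six sector targets carries the
    gross ISNT pattern; a two-bump von-Mises ripple centred on the
    superior (90 deg) and inferior (270 deg) meridians adds the classic
    double hump within sectors.  A final per-sector additive correction
    makes every sector's mean equal its target exactly, in the same
    column-to-angle frame quantification will use.
    """
    sec = column_sectors(n_columns, laterality)
    step = np.asarray(sector_thickness, dtype=float)[sec]
    sigma_cols = smooth_deg / 360.0 * n_columns
    prof = gaussian_filter1d(step, sigma=sigma_cols, mode="wrap")
    theta = np.deg2rad(column_angle(np.arange(n_columns), n_columns, laterality))
    ripple = np.exp(ripple_kappa * (np.cos(theta - np.pi / 2) - 1.0)) + np.exp(
        ripple_kappa * (np.cos(theta - 3 * np.pi / 2) - 1.0)
    )
    prof = prof + ripple_amp_um * (ripple - ripple.mean())
    # Drive sector means onto their targets with a *smoothed* correction
    # field, iterated to convergence: constant per-sector corrections
    # would leave multi-pixel steps at sector borders, which the layer
    # geometry (and the segmenter's smoothness bound) should not see.
    targets = np.asarray(sector_thickness, dtype=float)
    for _ in range(12):
        delta = np.empty(n_columns)
        for k in range(len(SECTOR_ORDER)):
            cols = sec == k
            delta[cols] = targets[k] - prof[cols].mean()
        prof = prof + gaussian_filter1d(delta, sigma=sigma_cols / 2.0, mode="wrap")
    for k in range(len(SECTOR_ORDER)):
        cols = sec == k
        prof[cols] += targets[k] - prof[cols].mean()
    return prof


def render_bscan(
    truth: SubjectTruth,
    params: GenerativeParams | None = None,
    height: int = 480,
    axial_scale: float = DEFAULT_AXIAL_SCALE_UM,
    n_columns: int = DEFAULT_N_COLUMNS,
    rng: np.random.Generator | None = None,
) -> tuple[BScanImage, GroundTruth]:
    """Render one eye as an 8-bit circular-scan B-scan plus ground truth.

    Geometry is laid out directly in the eye's own column-to-angle
    frame, so an OS scan is the anatomical mirror of the equivalent OD
    scan and the ground-truth sidecar's column c always describes the
    image's column c.
    """
    params = params or GenerativeParams()
    if rng is None:
        rng = _rng_for(params, STREAM_SPECKLE, truth.subject_id)

    prof_um = thickness_profile_um(
        truth.sector_thickness_true, n_columns, truth.laterality
    )
    t_px = np.maximum(np.rint(prof_um / axial_scale).astype(int), 1)

    theta = np.deg2rad(
        column_angle(np.arange(n_columns), n_columns, truth.laterality)
    )
    ilm_px = np.rint(
        (params.ilm_row_um + params.ilm_wave_um * np.sin(theta + 0.7)) / axial_scale
    ).astype(int)
    gap_px = max(int(round(params.retina_gap_um / axial_scale)), 1)
    rpe_px = max(int(round(params.rpe_band_um / axial_scale)), 1)

    b = ilm_px
    p = b + t_px
    ri = p + gap_px
    ro = ri + rpe_px
    if b.min() < 2 or ro.max() >= height - 1:
        raise GeometryError(
            f"layer stack spans rows [{b.min()}, {ro.max()}] which does not fit "
            f"a height-{height} frame with margin"
        )

    sec = column_sectors(n_columns, truth.laterality)
    rnfl_refl = np.asarray(truth.sector_gray_true, dtype=float)[sec]
    rpe_refl = np.full(n_columns, float(truth.rpe_gray_true))

    rows = np.arange(height)[:, None]
    img = np.full((height, n_columns), params.background_refl, dtype=np.float64)
    img = np.where((rows >= b) & (rows < p), rnfl_refl, img)
    img = np.where((rows >= p) & (rows < ri), params.inner_retina_refl, img)
    img = np.where((rows >= ri) & (rows < ro), rpe_refl, img)

    if params.speckle_shape is not None and np.isfinite(params.speckle_shape):
        shape = float(params.speckle_shape)
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        ilm=b - 0.5, rnfl_post=p - 0.5, rpe_inner=ri - 0.5, rpe_outer=ro - 0.5,
        rnfl_refl=rnfl_refl, rpe_refl=rpe_refl,
    )
    gt.validate(height)

    image = BScanImage(
        pixels=pixels,
        axial_scale=axial_scale,
        laterality=truth.laterality,
        quality_factor=None,
    )
    return image, gt


def degrade_quality(
    image: BScanImage,
    imageq: float,
    rng: np.random.Generator | None = None,
) -> BScanImage:
    """Degrade a scan to a target quality level.

    Injects zero-mean Gaussian background noise whose SD follows the
    calibrated quality law (see :mod:`rnflgray.quality`).  At the
    calibration ceiling the image is returned bit-identical.  The
    operator is mean-preserving on tissue by design, so layer grayscale
    truths remain well defined at every quality level.
    """
    sd = noise_sd_for_imageq(imageq)  # raises outside [QCAL_MIN, QCAL_MAX]
    if sd == 0.0:
        return replace(image, pixels=image.pixels.copy())
    if rng is None:
        rng = np.random.default_rng(0)
    noisy = image.pixels.astype(np.float64) + rng.normal(0.0, sd, image.pixels.shape)
    return replace(image, pixels=np.clip(np.rint(noisy), 0, 255).astype(np.uint8))


def degrade_rng(params: GenerativeParams, subject_id: int) -> np.random.Generator:
    """The per-eye RNG stream reserved for quality degradation."""
    return _rng_for(params, STREAM_DEGRADE, subject_id)


__all__ = [
    "CovariateSpec", "GenerativeParams", "SubjectTruth", "GroundTruth",
    "sample_cohort", "cohort_to_frame", "render_bscan", "degrade_quality",
    "degrade_rng", "thickness_profile_um", "TRUTH_CSV_COLUMNS",
    "QCAL_MIN", "QCAL_MAX",
]
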