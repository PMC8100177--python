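"""Layer-boundary detection on circular peripapillary B-scans.

Four boundaries are traced, in this detection order:

1. ILM            (vitreous -> pRNFL, dark-to-bright, strongest edge)
2. RPE outer      (RPE -> choroid/background, strongest bright-to-dark)
3. pRNFL posterior(pRNFL -> inner retina, bright-to-dark, between 1 and 2)
4. RPE inner      (inner retina -> RPE, dark-to-bright, between 3 and 2)

Each trace is the minimum-cost smooth path on a signed vertical-gradient
cost image, restricted to the band left admissible by the traces already
found, so the anatomical ordering ILM <= pRNFL-posterior <= RPE-inner <=
RPE-outer holds by construction.  Boundary positions live on the
half-integer lattice (a value r - 0.5 separates pixel rows r - 1 and r)
and are refined to sub-pixel precision by a quadratic fit of the
gradient peak.  The gradient is computed after a light anisotropic
Gaussian smoothing, wrapped horizontally because the scan is a closed
circle.

The device-era segmentation this mirrors was an unpublished ImageJ
plug-in; the dynamic-programming formulation here is this package's own
transparent, deterministic stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, median_filter

from ._dp import BIG, banded_min_cost_trace
from .errors import SegmentationFailure
from .image import BScanImage, column_cumsum

#: Default DP transition limit, rows per column.
DEFAULT_MAX_JUMP = 3
#: Minimum mean signed gradient (gray/px) along a trace for it to count
#: as a real edge rather than noise.
MIN_EDGE_STRENGTH = 6.0
#: Minimum admissible ILM -> RPE-outer separation, px.
MIN_ILM_TO_RPE = 10

# QC rule defaults
THICKNESS_BAND_UM = (30.0, 250.0)
ROUGHNESS_LIMIT_PX = 1.5
#: The pRNFL band must be at least this much brighter than the vitreous
#: (gray levels); a band statistically indistinguishable from background
#: is a misidentified band.
INTENSITY_MARGIN = 5.0


@dataclass
class LayerBoundaries:
    """Per-column boundary rows (fractional; half-integer convention:
    a layer's pixels are the rows in [ceil(upper), ceil(lower)))."""

    ilm: np.ndarray
    rnfl_post: np.ndarray
    rpe_inner: np.ndarray
    rpe_outer: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ilm", "rnfl_post", "rpe_inner", "rpe_outer"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        order = [self.ilm, self.rnfl_post, self.rpe_inner, self.rpe_outer]
        for up, lo in zip(order[:-1], order[1:]):
            if up.shape != lo.shape:
                raise ValueError("boundary traces must share one length")
            if not np.all(up <= lo):
                raise ValueError("boundary ordering violated")

    @property
    def n_columns(self) -> int:
        return self.ilm.shape[0]

    def traces(self) -> dict[str, np.ndarray]:
        return {
            "ilm": self.ilm,
            "rnfl_post": self.rnfl_post,
            "rpe_inner": self.rpe_inner,
            "rpe_outer": self.rpe_outer,
        }

    def mirrored(self) -> "LayerBoundaries":
        return LayerBoundaries(
            **{k: v[::-1].copy() for k, v in self.traces().items()}
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"column_index": np.arange(self.n_columns), **self.traces()})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LayerBoundaries":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            ilm=df["ilm"].to_numpy(),
            rnfl_post=df["rnfl_post"].to_numpy(),
            rpe_inner=df["rpe_inner"].to_numpy(),
            rpe_outer=df["rpe_outer"].to_numpy(),
        )


@dataclass
class QCReport:
    """Outcome of the automated boundary-misidentification screen."""

    misidentification: bool
    reasons: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "misidentification": bool(self.misidentification),
            "reasons": list(self.reasons),
            "scores": {k: float(v) for k, v in self.scores.items()},
        }


def denoise(image: BScanImage, kernel: int = 3) -> BScanImage:
    """Median-filtered copy; kernel 1 is the identity.  The kernel must
    be odd so the filter is centred and unbiased."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return BScanImage(
            pixels=image.pixels.copy(),
            axial_scale=image.axial_scale,
            scan_diameter=image.scan_diameter,
            laterality=image.laterality,
            quality_factor=image.quality_factor,
        )
    filtered = median_filter(image.pixels, size=kernel, mode="nearest")
    return BScanImage(
        pixels=filtered,
        axial_scale=image.axial_scale,
        scan_diameter=image.scan_diameter,
        laterality=image.laterality,
        quality_factor=image.quality_factor,
    )


def _signed_gradient(image: BScanImage, sigma_rows: float, sigma_cols: float) -> np.ndarray:
    """Smoothed vertical derivative d[r, c] = S[r, c] - S[r-1, c]; d[0]=0.

    Horizontal smoothing wraps (circular scan); both kernels are
    symmetric, so the gradient field mirrors exactly with the image.
    """
    smoothed = gaussian_filter(
        image.pixels.astype(np.float64),
        sigma=(sigma_rows, sigma_cols),
        mode=("nearest", "wrap"),
    )
    d = np.zeros_like(smoothed)
    d[1:, :] = smoothed[1:, :] - smoothed[:-1, :]
    return d


def _subpixel_offsets(signal: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Quadratic refinement of a per-column peak of `signal` at `rows`.

    Fits a parabola through the three samples around each peak; offsets
    are clipped to +/-0.5 and zeroed where the vertex is not a maximum.
    """
    H = signal.shape[0]
    cols = np.arange(signal.shape[1])
    r0 = np.clip(rows, 1, H - 2)
    gm = signal[r0 - 1, cols]
    g0 = signal[r0, cols]
    gp = signal[r0 + 1, cols]
    denom = gm - 2.0 * g0 + gp
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (gm - gp) / denom
    off = np.where((denom < -1e-12) & np.isfinite(off), off, 0.0)
    return np.clip(off, -0.5, 0.5)


def _trace_edge(
    grad: np.ndarray,
    polarity: int,
    lower_limit: np.ndarray,
    upper_limit: np.ndarray,
    max_jump: int,
    name: str,
) -> tuple[np.ndarray, np.ndarray]:
    """One DP boundary search.

    polarity +1 finds dark-to-bright (positive gradient) edges, -1
    bright-to-dark.  The admissible band per column is
    [lower_limit, upper_limit] inclusive, in integer edge rows.
    Returns (integer rows, fractional trace).
    """
    H, W = grad.shape
    signal = polarity * grad  # to be maximised
    if np.any(lower_limit > upper_limit):
        raise SegmentationFailure(f"empty admissible band for {name}")
    rows, best = banded_min_cost_trace(signal, lower_limit, upper_limit, max_jump)
    if best >= BIG:
        raise SegmentationFailure(f"no admissible path for {name}")
    strength = float(np.mean(signal[rows, np.arange(W)]))
    if strength < MIN_EDGE_STRENGTH:
        raise SegmentationFailure(
            f"{name} edge too weak (mean gradient {strength:.2f} gray/px, "
            f"need {MIN_EDGE_STRENGTH}); the image may be featureless"
        )
    frac = rows - 0.5 + _subpixel_offsets(signal, rows)
    return rows, frac


def segment_boundaries(
    image: BScanImage,
    max_jump: int = DEFAULT_MAX_JUMP,
    sigma_rows: float = 1.0,
    sigma_cols: float = 3.0,
) -> LayerBoundaries:
    """Detect ILM, pRNFL posterior boundary and the RPE band.

    Raises SegmentationFailure when no admissible, sufficiently strong
    edge exists (e.g. a constant or layer-free image); that is a hard
    failure, distinct from QC flagging of an implausible but traceable
    result.
    """
    H, W = image.pixels.shape
    grad = _signed_gradient(image, sigma_rows, sigma_cols)
    ones = np.ones(W, dtype=np.int64)

    # 1. ILM: strongest dark->bright edge anywhere with room below.
    ilm_r, ilm_f = _trace_edge(
        grad, +1, ones, ones * (H - 2 - MIN_ILM_TO_RPE), max_jump, "ilm"
    )
    # 2. RPE outer: strongest bright->dark edge well below the ILM.
    ro_r, ro_f = _trace_edge(
        grad, -1, ilm_r + MIN_ILM_TO_RPE, ones * (H - 2), max_jump, "rpe_outer"
    )
    # 3. pRNFL posterior: bright->dark between ILM and RPE outer.
    p_r, p_f = _trace_edge(grad, -1, ilm_r + 1, ro_r - 3, max_jump, "rnfl_post")
    # 4. RPE inner: dark->bright between pRNFL posterior and RPE outer.
    ri_r, ri_f = _trace_edge(grad, +1, p_r + 1, ro_r - 1, max_jump, "rpe_inner")

    # Sub-pixel refinement cannot cross the integer-band constraints by
    # more than half a pixel, but clamp pathological crossings anyway.
    ilm_f = np.minimum(ilm_f, p_f)
    ri_f = np.clip(ri_f, p_f, ro_f)
    return LayerBoundaries(ilm=ilm_f, rnfl_post=p_f, rpe_inner=ri_f, rpe_outer=ro_f)


def flag_misidentification(
    image: BScanImage,
    boundaries: LayerBoundaries,
    thickness_band_um: tuple[float, float] = THICKNESS_BAND_UM,
    roughness_limit_px: float = ROUGHNESS_LIMIT_PX,
    intensity_margin: float = INTENSITY_MARGIN,
) -> QCReport:
    """Automated proxy for the human boundary-misidentification screen.

    Deterministic rules; any firing rule flags the scan:

    * ``thickness_implausible`` - median pRNFL thickness outside the
      plausibility band (default 30-250 um);
    * ``trace_roughness`` - mean absolute second difference of any trace
      above the limit (default 1.5 px);
    * ``rnfl_darker_than_background`` - mean intensity inside the pRNFL
      band not clearly above the mean vitreous intensity (a band landing
      in vitreous or choroid).
    """
    reasons: list[str] = []
    scores: dict[str, float] = {}

    thick_px = boundaries.rnfl_post - boundaries.ilm
    med_um = float(np.median(thick_px) * image.axial_scale)
    scores["median_thickness_um"] = med_um
    if not thickness_band_um[0] <= med_um <= thickness_band_um[1]:
        reasons.append("thickness_implausible")

    rough = max(
        float(np.mean(np.abs(np.diff(tr, 2)))) for tr in boundaries.traces().values()
    )
    scores["max_roughness_px"] = rough
    if rough > roughness_limit_px:
        reasons.append("trace_roughness")

    S = column_cumsum(image.pixels)
    H = image.pixels.shape[0]
    up = np.clip(np.ceil(boundaries.ilm).astype(np.int64), 0, H)
    lo = np.clip(np.ceil(boundaries.rnfl_post).astype(np.int64), 0, H)
    cols = np.arange(image.n_columns)
    band_n = float((lo - up).sum())
    band_mean = float((S[lo, cols] - S[up, cols]).sum() / band_n) if band_n else 0.0
    bg_hi = np.clip(np.floor(boundaries.ilm).astype(np.int64) - 1, 0, H)
    bg_n = float(bg_hi.sum())
    bg_mean = float(S[bg_hi, cols].sum() / bg_n) if bg_n else 255.0
    scores["rnfl_mean_intensity"] = band_mean
    scores["background_mean_intensity"] = bg_mean
    if band_mean <= bg_mean + intensity_margin:
        reasons.append("rnfl_darker_than_background")

    return QCReport(misidentification=bool(reasons), reasons=reasons, scores=scores)
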