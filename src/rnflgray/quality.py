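"""Shared model of scan quality (the "ImageQ" proxy).

The device quality factor is proprietary, so this package defines its own
calibrated pair of operations:

* ``synthdata.degrade_quality`` injects zero-mean Gaussian background
  noise whose standard deviation grows exponentially as the quality knob
  ``q`` falls below the calibration ceiling ``QCAL_MAX`` (at which the
  image is returned untouched);
* ``quantify.compute_imageq`` inverts that law from the image alone via a
  signal-to-background contrast statistic: the log-ratio of a fixed
  nominal tissue-to-background contrast to the measured background
  spread.  Using a fixed contrast reference (rather than a per-image
  bright percentile) keeps the proxy independent of the eye's own tissue
  reflectivity, so quality and reflectivity remain separate covariates.

Noise is additive and zero-mean by design: in-layer mean grayscale is a
generative quantity in this package, so the degradation operator must not
shift layer means, only bury them in noise.  With

    lambda = (QCAL_MAX - q) / (QCAL_MAX - QCAL_MIN)
    sd_add = BG_NOISE_SD0 * sqrt(exp(2 * NOISE_DECAY * lambda) - 1)

the total background spread is BG_NOISE_SD0 * exp(NOISE_DECAY * lambda)
(speckle and injected noise add in variance), hence the log-contrast
statistic is affine in q and the proxy is a two-constant affine map,
fitted once on default synthetic scans and frozen below.
"""

from __future__ import annotations

import numpy as np

#: Calibration range of the quality knob / proxy.
QCAL_MIN = 40.0
QCAL_MAX = 70.0

#: Exponential growth rate of background noise over the full knob range.
NOISE_DECAY = 1.5

#: Background speckle SD of a default-rendered scan at maximum quality
#: (background reflectivity 25 at gamma speckle shape 60, after 8-bit
#: quantisation).  Anchors the noise-injection law.
BG_NOISE_SD0 = 3.24

#: Nominal tissue-to-background contrast (gray levels) used as the fixed
#: numerator of the contrast statistic.
CONTRAST_REF = 150.0

#: Floor on the measured background spread (quantisation scale) so the
#: statistic stays finite on noise-free images.
SPREAD_FLOOR = 0.05

#: Affine calibration q = IMAGEQ_CAL_A + IMAGEQ_CAL_B * s of the proxy on
#: the log-contrast statistic s, fitted by least squares on default
#: synthetic scans degraded over a 40..70 knob grid (see docs/methods.md).
IMAGEQ_CAL_A = -18.38
IMAGEQ_CAL_B = 20.69


def noise_sd_for_imageq(imageq: float) -> float:
    """Additive background-noise SD injected at quality ``imageq``."""
    if not QCAL_MIN <= imageq <= QCAL_MAX:
        raise ValueError(
            f"imageq {imageq} outside calibration range [{QCAL_MIN}, {QCAL_MAX}]"
        )
    lam = (QCAL_MAX - imageq) / (QCAL_MAX - QCAL_MIN)
    return float(BG_NOISE_SD0 * np.sqrt(np.expm1(2.0 * NOISE_DECAY * lam)))


def contrast_stat(pixels: np.ndarray) -> float:
    """Log signal-to-background contrast of a raster.

    Background spread is the standard deviation of the pixels at or
    below the image median: layers occupy a minority of rows, so the
    median sits inside the background distribution and the selected
    half-sample is background noise.  The numerator is the fixed
    nominal contrast, deliberately NOT a per-image bright percentile
    (see module docstring).
    """
    px = np.asarray(pixels, dtype=np.float64)
    med = np.median(px)
    spread = max(float(px[px <= med].std()), SPREAD_FLOOR)
    return float(np.log(CONTRAST_REF / spread))


def imageq_from_stat(stat: float) -> float:
    """Affine proxy map, clipped to [0, QCAL_MAX]."""
    q = IMAGEQ_CAL_A + IMAGEQ_CAL_B * stat
    return float(np.clip(q, 0.0, QCAL_MAX))
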