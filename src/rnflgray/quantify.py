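"""Sectoral pRNFL grayscale and thickness quantification.

Converts an image plus layer boundaries into the per-eye parameter set:
average and six-sector pRNFL grayscale values (mean 8-bit intensity of
the pixels between the ILM and the pRNFL posterior boundary), the
matching thicknesses in micrometres, the RPE grayscale reference and a
scan-quality proxy.

Conventions
-----------
* A layer's pixels in a column are the rows in [ceil(upper),
  ceil(lower)); a boundary row belongs to the layer below it, so
  adjacent layers never share a pixel.
* Grayscale averages are pixel-weighted by default: the grayscale value
  of a region is the plain mean of its pixels, which makes the overall
  mean the pixel-count-weighted mean of the sector values exactly.  A
  column-weighted dialect (each column's band mean counted once) is
  available for sensitivity analysis.
* The average is taken over the full 360-degree scan (all columns), not
  over the six sector values.
* OS scans are sectorised through the mirrored column-to-angle map, so
  "temporal" is anatomically temporal for both eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MeasurementError, QCRefusalError
from .image import BScanImage, column_cumsum
from .quality import contrast_stat, imageq_from_stat
from .sectors import (
    DEFAULT_SCHEME,
    SECTOR_ORDER,
    SectorScheme,
    column_angle,
    column_sectors,
)
from .segmentation import LayerBoundaries, QCReport, flag_misidentification

#: Measurement columns of the one-row-per-eye output table.
MEASUREMENT_COLUMNS = [
    "gray_mean", *[f"gray_{s}" for s in SECTOR_ORDER],
    "thick_mean", *[f"thick_{s}" for s in SECTOR_ORDER],
    "rpe_gray",
]


@dataclass
class PRNFLMeasurement:
    """Per-eye pRNFL parameter set (grayscale 0-255, thickness um)."""

    gray_mean: float
    gray_sectors: dict[str, float]
    thick_mean: float
    thick_sectors: dict[str, float]
    rpe_gray: float
    imageq: float
    qc: QCReport | None = None

    def to_row(self) -> dict[str, float]:
        row = {"gray_mean": self.gray_mean}
        row.update({f"gray_{s}": self.gray_sectors[s] for s in SECTOR_ORDER})
        row["thick_mean"] = self.thick_mean
        row.update({f"thick_{s}": self.thick_sectors[s] for s in SECTOR_ORDER})
        row["rpe_gray"] = self.rpe_gray
        row["imageq"] = self.imageq
        row["qc_pass"] = bool(self.qc is None or not self.qc.misidentification)
        return row


def sector_of_angle(angle: float, scheme: SectorScheme = DEFAULT_SCHEME) -> str:
    """Sector label of an angle in [0, 360) under the half-open scheme."""
    return scheme.sector_of_angle(angle)


def _band_rows(
    upper: np.ndarray, lower: np.ndarray, n_rows: int, columns: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Integer band [up, lo) per selected column under the half-open
    ceil convention."""
    up = np.ceil(np.asarray(upper, dtype=float)[columns]).astype(np.int64)
    lo = np.ceil(np.asarray(lower, dtype=float)[columns]).astype(np.int64)
    if np.any(up > lo):
        raise ValueError("upper boundary below lower boundary")
    return np.clip(up, 0, n_rows), np.clip(lo, 0, n_rows)


def _gray_from_cumsum(
    S: np.ndarray,
    upper: np.ndarray,
    lower: np.ndarray,
    columns: np.ndarray,
    column_weighted: bool,
) -> float:
    up, lo = _band_rows(upper, lower, S.shape[0] - 1, columns)
    sums = S[lo, columns] - S[up, columns]
    counts = (lo - up).astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise MeasurementError("empty pixel band: zero-thickness region")
    if not column_weighted:
        return float(sums.sum() / total)
    nonzero = counts > 0
    return float(np.mean(sums[nonzero] / counts[nonzero]))


def layer_grayscale(
    image: BScanImage,
    upper: np.ndarray,
    lower: np.ndarray,
    columns: np.ndarray | None = None,
    column_weighted: bool = False,
) -> float:
    """Mean 8-bit intensity of the pixels between two boundary traces.

    Pixel-weighted by default; ``column_weighted=True`` averages the
    per-column band means instead (the dialect switch).  Raises
    MeasurementError when the band holds no pixel on the selected
    columns (a zero-thickness region).
    """
    if columns is None:
        columns = np.arange(image.n_columns)
    columns = np.asarray(columns, dtype=np.int64)
    S = column_cumsum(image.pixels)
    return _gray_from_cumsum(S, upper, lower, columns, column_weighted)


def layer_pixel_count(
    image: BScanImage, upper: np.ndarray, lower: np.ndarray,
    columns: np.ndarray | None = None,
) -> int:
    """Number of pixels in the band over the selected columns."""
    if columns is None:
        columns = np.arange(image.n_columns)
    columns = np.asarray(columns, dtype=np.int64)
    up, lo = _band_rows(upper, lower, image.n_rows, columns)
    return int((lo - up).sum())


def layer_thickness(
    upper: np.ndarray,
    lower: np.ndarray,
    axial_scale: float,
    columns: np.ndarray | None = None,
) -> float:
    """Mean (lower - upper) over the selected columns, in micrometres."""
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if columns is None:
        columns = np.arange(upper.shape[0])
    columns = np.asarray(columns, dtype=int)
    diff = lower[columns] - upper[columns]
    if np.any(diff < 0):
        raise ValueError("negative band: lower boundary above upper")
    return float(diff.mean() * axial_scale)


def compute_imageq(image: BScanImage) -> float:
    """Scan-quality proxy on the device-like 40-70 scale.

    An affine map of the log signal-to-background contrast statistic
    (fixed nominal tissue contrast over the measured background spread),
    calibrated against the synthetic degradation law so the proxy
    reproduces the degradation knob; monotone in true quality.  See
    :mod:`rnflgray.quality`.
    """
    return imageq_from_stat(contrast_stat(image.pixels))


def measure_eye(
    image: BScanImage,
    boundaries: LayerBoundaries,
    scheme: SectorScheme = DEFAULT_SCHEME,
    qc: QCReport | None = None,
    override_qc: bool = False,
    column_weighted: bool = False,
) -> PRNFLMeasurement:
    """Full per-eye measurement.

    Runs the boundary-misidentification screen first (unless a report is
    supplied) and refuses to measure a flagged scan without an explicit
    override.  The device quality value on the image is used when
    present; otherwise the proxy is computed from the pixels.
    """
    if qc is None:
        qc = flag_misidentification(image, boundaries)
    if qc.misidentification and not override_qc:
        raise QCRefusalError(
            f"boundary misidentification flagged ({', '.join(qc.reasons)}); "
            "pass override_qc=True to measure anyway"
        )

    sectors = column_sectors(image.n_columns, image.laterality, scheme)
    S = column_cumsum(image.pixels)  # shared by all grayscale reads
    gray_sec: dict[str, float] = {}
    thick_sec: dict[str, float] = {}
    for k, label in enumerate(SECTOR_ORDER):
        cols = np.flatnonzero(sectors == k)
        gray_sec[label] = _gray_from_cumsum(
            S, boundaries.ilm, boundaries.rnfl_post, cols, column_weighted
        )
        thick_sec[label] = layer_thickness(
            boundaries.ilm, boundaries.rnfl_post, image.axial_scale, cols
        )

    all_cols = np.arange(image.n_columns)
    gray_mean = _gray_from_cumsum(
        S, boundaries.ilm, boundaries.rnfl_post, all_cols, column_weighted
    )
    thick_mean = layer_thickness(
        boundaries.ilm, boundaries.rnfl_post, image.axial_scale, None
    )
    rpe_gray = _gray_from_cumsum(
        S, boundaries.rpe_inner, boundaries.rpe_outer, all_cols, column_weighted
    )
    imageq = (
        float(image.quality_factor)
        if image.quality_factor is not None
        else compute_imageq(image)
    )
    return PRNFLMeasurement(
        gray_mean=gray_mean,
        gray_sectors=gray_sec,
        thick_mean=thick_mean,
        thick_sectors=thick_sec,
        rpe_gray=rpe_gray,
        imageq=imageq,
        qc=qc,
    )
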