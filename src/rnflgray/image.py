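"""The B-scan container and 8-bit image I/O.

A circular peripapillary scan is stored as a rows x columns uint8 raster
with row 0 on the vitreous side.  Columns are A-scans; the device this
package emulates samples 1024 A-scans on a 3.46 mm circle with a 5 um
axial pixel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

DEFAULT_N_COLUMNS = 1024
DEFAULT_AXIAL_SCALE_UM = 5.0
DEFAULT_SCAN_DIAMETER_MM = 3.46


@dataclass
class BScanImage:
    """One circular B-scan plus acquisition metadata.

    pixels : uint8 array, shape (rows, columns), 0 = black, 255 = white.
    axial_scale : axial size of one pixel in micrometres.
    scan_diameter : diameter of the scan circle in millimetres.
    laterality : "OD" or "OS".
    quality_factor : device-style quality value if known (else None and a
        proxy is computed from the pixels).
    """

    pixels: np.ndarray
    axial_scale: float = DEFAULT_AXIAL_SCALE_UM
    scan_diameter: float = DEFAULT_SCAN_DIAMETER_MM
    laterality: str = "OD"
    quality_factor: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if px.shape[1] < 64:
            raise ValueError("a B-scan needs at least 64 A-scan columns")
        if self.axial_scale <= 0:
            raise ValueError("axial_scale must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")
        self.pixels = px

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_columns(self) -> int:
        return self.pixels.shape[1]

    def mirrored(self) -> "BScanImage":
        """Horizontally mirrored copy with the opposite laterality label."""
        other = "OS" if self.laterality == "OD" else "OD"
        return replace(self, pixels=self.pixels[:, ::-1].copy(), laterality=other)


def column_cumsum(pixels: np.ndarray) -> np.ndarray:
    """(rows+1, cols) prefix sums down each column; exact for uint8 data
    in float64 (sums stay far below 2**53).  Shared by quantification
    and QC so band statistics are O(columns) after one pass."""
    H, W = pixels.shape
    S = np.zeros((H + 1, W), dtype=np.float64)
    np.cumsum(pixels, axis=0, out=S[1:])
    return S


def write_image(image: BScanImage, path: str | Path, jpeg_quality: int = 95) -> None:
    """Write the raster as 8-bit grayscale.

    PNG/TIFF are lossless and preferred; JPEG is accepted for parity with
    clinical export workflows but is lossy and will perturb grayscale
    statistics slightly.
    """
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        iio.imwrite(path, image.pixels, quality=jpeg_quality)
    else:
        iio.imwrite(path, image.pixels)


def read_image(
    path: str | Path,
    axial_scale: float = DEFAULT_AXIAL_SCALE_UM,
    laterality: str = "OD",
    quality_factor: float | None = None,
) -> BScanImage:
    """Read an 8-bit grayscale PNG/TIFF/JPEG as a BScanImage.

    RGB inputs are reduced to luma by channel averaging; 16-bit inputs are
    rescaled to 8 bits.
    """
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:
        px = px[..., :3].mean(axis=2)
    if px.dtype == np.uint16:
        px = (px / 257.0)
    px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return BScanImage(
        pixels=px,
        axial_scale=axial_scale,
        laterality=laterality,
        quality_factor=quality_factor,
    )
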