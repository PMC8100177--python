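"""Angular sector scheme of the circular peripapillary scan.

The 3.46 mm scan circle is unrolled into a B-scan whose columns are
A-scans ordered by angle.  Angles follow the ophthalmic convention used
for right eyes: 0 deg at the temporal horizontal meridian, increasing
through superior (90 deg), nasal (180 deg) and inferior (270 deg).  Left
eyes (OS) are mirrored into the same frame so "temporal" means the same
thing for both lateralities.

Six sectors partition the circle: temporal and nasal span 90 deg each,
the four oblique sectors span 45 deg each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical sector order used for all six-element vectors in this package.
SECTOR_ORDER: tuple[str, ...] = ("T", "IT", "IN", "N", "SN", "ST")

SECTOR_NAMES: dict[str, str] = {
    "T": "temporal",
    "IT": "inferior-temporal",
    "IN": "inferior-nasal",
    "N": "nasal",
    "SN": "superior-nasal",
    "ST": "superior-temporal",
}


@dataclass(frozen=True)
class SectorScheme:
    """Half-open angular intervals, in degrees, labelled by sector code.

    The temporal sector wraps through 0 deg and is stored as [315, 405)
    internally; membership tests reduce angles mod 360.
    """

    intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "T": (315.0, 405.0),   # wraps through 0
            "ST": (45.0, 90.0),
            "SN": (90.0, 135.0),
            "N": (135.0, 225.0),
            "IN": (225.0, 270.0),
            "IT": (270.0, 315.0),
        }
    )

    def __post_init__(self) -> None:
        spans = sum(hi - lo for lo, hi in self.intervals.values())
        if not np.isclose(spans, 360.0):
            raise ValueError("sector intervals must cover 360 degrees exactly")

    def sector_of_angle(self, angle: float) -> str:
        """Sector label for an angle in [0, 360); half-open intervals, so a
        boundary angle belongs to the sector it opens (45 deg -> ST)."""
        a = np.asarray(angle, dtype=float)
        if np.any(a < 0.0) or np.any(a >= 360.0):
            raise ValueError(f"angle must lie in [0, 360), got {angle}")
        for label, (lo, hi) in self.intervals.items():
            if lo <= float(a) < hi or lo <= float(a) + 360.0 < hi:
                return label
        raise AssertionError("unreachable: intervals cover the circle")

    def sector_indices(self, angles: np.ndarray) -> np.ndarray:
        """Vectorised sector assignment; returns indices into SECTOR_ORDER."""
        a = np.asarray(angles, dtype=float)
        if np.any(a < 0.0) or np.any(a >= 360.0):
            raise ValueError("angles must lie in [0, 360)")
        out = np.empty(a.shape, dtype=np.int8)
        out.fill(-1)
        for label, (lo, hi) in self.intervals.items():
            k = SECTOR_ORDER.index(label)
            hit = ((a >= lo) & (a < hi)) | ((a + 360.0 >= lo) & (a + 360.0 < hi))
            out[hit] = k
        assert np.all(out >= 0)
        return out


DEFAULT_SCHEME = SectorScheme()


def column_angle(column, n_columns: int, laterality: str = "OD"):
    """Angle (degrees, [0, 360)) of an A-scan column.

    For OD the first column sits on the temporal meridian and the angle
    grows linearly with column index.  For OS the acquired image is the
    mirror of the OD frame, so the mapping is reflected: angle =
    (360 - 360*c/N) mod 360, which keeps temporal at 0 deg for both eyes.
    """
    c = np.asarray(column)
    if np.any(c < 0) or np.any(c >= n_columns):
        raise ValueError(f"column out of range [0, {n_columns})")
    ang = 360.0 * c / float(n_columns)
    if laterality == "OS":
        ang = np.mod(360.0 - ang, 360.0)
    elif laterality != "OD":
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    if np.isscalar(column):
        return float(ang)
    return ang


def column_sectors(
    n_columns: int, laterality: str = "OD", scheme: SectorScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Sector index (into SECTOR_ORDER) for every column of a scan."""
    angles = column_angle(np.arange(n_columns), n_columns, laterality)
    return scheme.sector_indices(angles)
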