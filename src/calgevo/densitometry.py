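"""Gel densitometry: lane extraction, band quantification, normalization.

A gel is a 2-D grayscale intensity grid (rows = migration axis, columns =
lane axis). Lanes are equal-width vertical strips unless explicit boundaries
are given; each strip is collapsed to a 1-D migration profile by summing
across its width. A band is integrated over a fixed window shared by all
lanes, after subtracting a linear background interpolated between the median
intensities of small flanking regions on either side of the window. Each
time course is normalized to its own undigested t = 0 lane, yielding the
fraction of intact protein that downstream decay fitting consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DensitometryError",
    "GelImage",
    "LaneProfile",
    "BandQuantification",
    "extract_lanes",
    "quantify_band",
    "normalize_timecourse",
]


class DensitometryError(ValueError):
    pass


@dataclass
class GelImage:
    """2-D grayscale gel image with optional per-lane time labels (minutes)."""

    data: np.ndarray
    lane_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DensitometryError("gel image must be a 2-D grid")
        if not np.all(np.isfinite(self.data)):
            raise DensitometryError("gel image contains non-finite values")
        if np.any(self.data < 0):
            raise DensitometryError("gel image intensities must be >= 0")

    @classmethod
    def from_csv(cls, path, lane_times=None) -> "GelImage":
        return cls(np.loadtxt(path, delimiter=","), lane_times)

    @classmethod
    def from_tiff(cls, path, lane_times=None) -> "GelImage":
        return cls(tifffile.imread(str(path)).astype(float), lane_times)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.data, delimiter=",", fmt="%.6g")

    def to_tiff(self, path) -> None:
        scaled = self.data / max(self.data.max(), 1e-12) * 65535
        tifffile.imwrite(str(path), scaled.astype(np.uint16))

    def flag_saturated(self, saturation_level: float = 65535.0) -> int:
        """Count pixels at or above the detector saturation level (16-bit)."""
        return int(np.sum(self.data >= saturation_level))


@dataclass
class LaneProfile:
    """1-D intensity vs migration position for one lane."""

    intensity: np.ndarray
    time_min: float | None = None
    lane: int | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < 10:
            raise DensitometryError("lane profile needs >= 10 positions")


@dataclass
class BandQuantification:
    """Integrated band intensities per lane, normalized to a reference lane."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def extract_lanes(
    image: GelImage,
    n_lanes: int,
    boundaries: list[int] | None = None,
) -> list[LaneProfile]:
    """Partition the image into vertical strips and collapse each to a profile.

    Equal-width strips by default; ``boundaries`` (interior column indices)
    override the partition. Strips are summed across their width.
    """
    n_rows, n_cols = image.data.shape
    if n_lanes < 1:
        raise DensitometryError("n_lanes must be >= 1")
    if n_lanes > n_cols:
        raise DensitometryError(
            f"n_lanes={n_lanes} exceeds image width {n_cols} pixels"
        )
    if boundaries is None:
        strips = np.array_split(image.data, n_lanes, axis=1)
    else:
        if len(boundaries) != n_lanes - 1:
            raise DensitometryError("need n_lanes - 1 interior boundaries")
        strips = np.hsplit(image.data, boundaries)
    if image.flag_saturated():
        warnings.warn("image contains saturated (65535) pixels", stacklevel=2)
    times = image.lane_times or [None] * n_lanes
    return [
        LaneProfile(strip.sum(axis=1), time_min=t, lane=i)
        for i, (strip, t) in enumerate(zip(strips, times))
    ]


def quantify_band(
    profile: LaneProfile,
    window: tuple[int, int],
    flank: int = 5,
) -> float:
    """Integrated band intensity over ``window`` after linear background
    subtraction.

    The background is the straight line joining the median intensity of the
    ``flank`` positions immediately below the window to the median of the
    ``flank`` positions immediately above it; the integral is floored at 0.
    ``window`` is a half-open position interval [lo, hi).
    """
    lo, hi = window
    y = profile.intensity
    if lo >= hi:
        raise DensitometryError("empty band window")
    if lo - flank < 0 or hi + flank > y.size:
        raise DensitometryError(
            "band window touches the profile edge; no room for background flanks"
        )
    left = float(np.median(y[lo - flank : lo]))
    right = float(np.median(y[hi : hi + flank]))
    x_left = lo - (flank + 1) / 2.0
    x_right = hi + (flank - 1) / 2.0
    positions = np.arange(lo, hi)
    background = left + (right - left) * (positions - x_left) / (x_right - x_left)
    return float(max((y[lo:hi] - background).sum(), 0.0))


def normalize_timecourse(
    intensities: dict[float, float] | pd.Series,
    reference_time: float = 0.0,
) -> BandQuantification:
    """Divide each band intensity by the reference (undigested, t = 0) lane.

    Returns a tidy table (time_min, intensity, fraction_intact); the
    reference lane maps to exactly 1.
    """
    series = pd.Series(dict(intensities)).sort_index()
    if reference_time not in series.index:
        raise DensitometryError(f"no lane at reference time {reference_time}")
    ref = series.loc[reference_time]
    if ref <= 0:
        raise DensitometryError(f"reference intensity must be > 0, got {ref}")
    table = pd.DataFrame(
        {
            "time_min": series.index.to_numpy(dtype=float),
            "intensity": series.to_numpy(dtype=float),
            "fraction_intact": (series / ref).to_numpy(dtype=float),
        }
    )
    return BandQuantification(table=table)
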