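"""Grey-level to permittivity conversion and ROI hydration statistics.

The capacitive sensor reports surface water content as an 8-bit grey map;
physically the signal is the relative permittivity of the skin surface
(dry skin low, water ~81).  The device's internal calibration is not
published, so the default here is a linear map anchored at physically
motivated endpoints — grey 0 -> eps 1 (air) and grey 255 -> eps 81 (water at
~20 C) — and is overridable.  All downstream statistics (ROI means, deltas,
the hydration/TEWL ratio) are computed on the permittivity scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dataio import CapacitiveImage
from .tmatch import RoiRect

__all__ = [
    "Calibration",
    "Histogram",
    "RoiStats",
    "grey_to_permittivity",
    "roi_stats",
    "hydration_change",
    "hydration_tewl_ratio",
]


@dataclass(frozen=True)
class Calibration:
    """Affine grey-level -> relative-permittivity map.

    Sends ``grey_low -> eps_low`` and ``grey_high -> eps_high``, linearly in
    between and extrapolated outside, unclipped.
    """

    grey_low: float = 0.0
    grey_high: float = 255.0
    eps_low: float = 1.0
    eps_high: float = 81.0

    def __post_init__(self) -> None:
        if not self.grey_low < self.grey_high:
            raise ValueError("grey_low must be < grey_high")
        if not self.eps_low < self.eps_high:
            raise ValueError("eps_low must be < eps_high")

    @property
    def slope(self) -> float:
        return (self.eps_high - self.eps_low) / (self.grey_high - self.grey_low)

    def apply(self, grey: np.ndarray | float) -> np.ndarray | float:
        return self.eps_low + (np.asarray(grey, dtype=np.float64) - self.grey_low) * self.slope


#: Identity map, for analyses that stay on the raw grey scale.
IDENTITY_CALIBRATION = Calibration(0.0, 255.0, 0.0, 255.0)


@dataclass(frozen=True)
class Histogram:
    """Equal-width histogram; the last bin is right-closed, so counts always
    sum to the number of contributing pixels."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if counts.shape != (edges.size - 1,) or np.any(counts < 0):
            raise ValueError("counts must be non-negative with len(edges) - 1 entries")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class RoiStats:
    mean: float
    sd: float
    histogram: Histogram
    n_pixels: int


def grey_to_permittivity(img: CapacitiveImage, cal: Calibration) -> np.ndarray:
    """Map a frame elementwise to the permittivity scale (float64, unclipped)."""
    return np.asarray(cal.apply(img.as_float()))


def roi_stats(
    img: CapacitiveImage,
    roi: RoiRect,
    cal: Calibration | None = None,
    n_bins: int = 32,
) -> RoiStats:
    """Mean, sample SD and histogram of the permittivity-mapped ROI pixels.

    The histogram spans ``[eps_low, eps_high]`` with ``n_bins`` equal bins;
    values mapped outside the calibration span (possible only with a
    non-covering calibration) are clipped into the edge bins so the counts
    conserve the pixel count.  SD uses the n-1 denominator (0 for a single
    pixel).
    """
    cal = cal or Calibration()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not roi.contained_in(img):
        raise ValueError(f"{roi} not inside {img.shape[1]}x{img.shape[0]} image")
    vals = np.asarray(cal.apply(roi.crop(img).as_float())).ravel()
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    edges = np.linspace(cal.eps_low, cal.eps_high, n_bins + 1)
    counts, _ = np.histogram(np.clip(vals, cal.eps_low, cal.eps_high), bins=edges)
    return RoiStats(mean=mean, sd=sd, histogram=Histogram(edges, counts), n_pixels=vals.size)


def hydration_change(
    means_by_timepoint: Mapping[str, float], baseline: str = "before"
) -> dict[str, float]:
    """Per-timepoint change in mean permittivity relative to the baseline.

    ``delta(t) = mean(t) - mean(baseline)``; the baseline's own delta is 0.
    """
    if baseline not in means_by_timepoint:
        raise ValueError(f"baseline timepoint {baseline!r} missing")
    ref = float(means_by_timepoint[baseline])
    return {tp: float(m) - ref for tp, m in means_by_timepoint.items()}


def hydration_tewl_ratio(eps_mean: float, tewl_mean: float) -> float:
    """Ratio of mean skin hydration (permittivity) over mean TEWL.

    A combined index: hydration rises and TEWL falls under an occlusive film,
    so the ratio moves in one direction for both effects.
    """
    if not tewl_mean > 0:
        raise ValueError("tewl_mean must be positive")
    return float(eps_mean) / float(tewl_mean)
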