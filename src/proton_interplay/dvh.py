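"""Cumulative dose-volume histograms and the standard CTV metric panel.

All doses are expressed in percent of prescription.  V-metrics (V100, V95,
V110) are the percent of CTV volume receiving at least the given percent
of prescription, with ties counting as received (closed inequality).
D-metrics (D100, D95, D5) are the dose received by at least the given
percent of the volume, computed as exact order statistics on the voxel
samples rather than by inverting the discretised curve, which removes
binning artifacts; the curve is retained for plotting.

Hot and cold spots follow the usual screening thresholds: hot if
V110 > 2% of the volume, cold if D95 < 95% of prescription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

HOT_V110_THRESHOLD = 2.0    # % volume above 110% of prescription
COLD_D95_THRESHOLD = 95.0   # % of prescription

#: default cumulative-curve level grid: 0-130% in 0.1% steps
DEFAULT_MAX_LEVEL = 130.0
DEFAULT_LEVEL_STEP = 0.1


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: % volume receiving at least each dose level."""

    dose_levels: np.ndarray      # increasing, % of prescription
    volume_fraction: np.ndarray  # %, non-increasing, starts at 100 for level 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dose_levels) <= 0):
            raise ValueError("dose_levels must be strictly increasing")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("volume_fraction must be non-increasing")

    def at(self, level: float) -> float:
        """Volume fraction at an arbitrary dose level (step interpolation).

        Snaps to a grid level within 1e-9 so queries at nominal grid values
        are unaffected by binary round-off of the level grid.
        """
        idx = np.searchsorted(self.dose_levels, level + 1e-9, side="right") - 1
        if idx < 0:
            return 100.0
        return float(self.volume_fraction[idx])


@dataclass(frozen=True)
class DVHMetrics:
    """The CTV metric panel: V100/V95/V110 (% volume), D100/D95/D5 (% Rx)."""

    V100: float
    V95: float
    V110: float
    D100: float
    D95: float
    D5: float
    hot_flag: bool
    cold_flag: bool

    METRIC_ORDER = ("V100", "V95", "V110", "D100", "D95", "D5")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRIC_ORDER}


def _as_percent(samples, prescription: float) -> np.ndarray:
    d = np.asarray(samples, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty dose vector")
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    return d * (100.0 / prescription)


def compute_dvh(
    samples,
    prescription: float = 100.0,
    max_level: float = DEFAULT_MAX_LEVEL,
    level_step: float = DEFAULT_LEVEL_STEP,
) -> DVHCurve:
    """Cumulative DVH of equal-volume CTV dose samples.

    ``prescription`` is the dose value corresponding to 100%; samples
    already expressed in percent use the default of 100.
    """
    d = _as_percent(samples, prescription)
    levels = np.arange(0.0, max_level + level_step / 2, level_step)
    # closed inequality: ties at a level count as receiving it
    sorted_d = np.sort(d)
    above = d.size - np.searchsorted(sorted_d, levels, side="left")
    return DVHCurve(levels, 100.0 * above / d.size)


def volume_at(samples, level: float, prescription: float = 100.0) -> float:
    """Vx: percent of volume receiving at least ``level`` % of prescription."""
    d = _as_percent(samples, prescription)
    return float(100.0 * np.mean(d >= level))


def dose_at(samples, volume_pct: float, prescription: float = 100.0) -> float:
    """Dy: largest dose received by at least ``volume_pct`` % of the volume.

    Exact order statistic: with samples sorted descending, the dose at rank
    ceil(y/100 * n) (1-based) is the largest d with at least y% of voxels
    at or above d.
    """
    if not 0.0 < volume_pct <= 100.0:
        raise ValueError("volume_pct must be in (0, 100]")
    d = _as_percent(samples, prescription)
    rank = int(math.ceil(volume_pct / 100.0 * d.size))
    return float(np.sort(d)[::-1][rank - 1])


def dvh_metrics(samples, prescription: float = 100.0) -> DVHMetrics:
    """Extract the metric panel and hot/cold flags from CTV dose samples."""
    v100 = volume_at(samples, 100.0, prescription)
    v95 = volume_at(samples, 95.0, prescription)
    v110 = volume_at(samples, 110.0, prescription)
    d100 = dose_at(samples, 100.0, prescription)
    d95 = dose_at(samples, 95.0, prescription)
    d5 = dose_at(samples, 5.0, prescription)
    return DVHMetrics(
        V100=v100, V95=v95, V110=v110, D100=d100, D95=d95, D5=d5,
        hot_flag=v110 > HOT_V110_THRESHOLD,
        cold_flag=d95 < COLD_D95_THRESHOLD,
    )
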