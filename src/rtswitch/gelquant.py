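"""Gel densitometry: lane profiles -> band intensities -> species fractions
and the overall template-switching efficiency statistic.

The efficiency statistic counts *all* template-switched products (first and
multiply switched) in the numerator; the denominator is the total lane
signal, so the value is a percentage in [0, 100] and is invariant to uniform
rescaling of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BAND_LABELS",
    "TS_BANDS",
    "LaneProfile",
    "integrate_bands",
    "band_fractions",
    "ts_efficiency",
]

#: canonical band labels, in increasing migration order
BAND_LABELS = ("primer", "nta_1", "nta_2", "nta_3", "ts_1", "ts_2", "ts_3plus")
#: labels counted as template-switching products
TS_BANDS = ("ts_1", "ts_2", "ts_3plus")


@dataclass
class LaneProfile:
    """A densitometry trace: fluorescence intensity vs migration position."""

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be equal-length vectors")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"position": self.positions, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, lane_id: str = "") -> "LaneProfile":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["position"].to_numpy(), df["intensity"].to_numpy(),
                   lane_id=lane_id)


def _validate_band_table(bt: dict) -> None:
    if not bt:
        raise ValueError("band table is empty")
    vals = np.array(list(bt.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("band intensities must be non-negative")


def _rolling_min(y: np.ndarray, window: int) -> np.ndarray:
    """Rolling minimum baseline (symmetric window, edge-padded)."""
    n = y.size
    half = max(window // 2, 1)
    padded = np.pad(y, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * half + 1)
    return windows.min(axis=1)[:n]


def integrate_bands(profile: LaneProfile, band_windows: dict,
                    background: str = "none",
                    background_window: int | None = None) -> dict:
    """Trapezoidal band integration over non-overlapping position windows.

    Parameters
    ----------
    band_windows : mapping of label -> (lo, hi) position interval.
    background : 'none' or 'rolling_min'
        Optional rolling-minimum baseline subtraction before integration.

    Returns a mapping label -> integrated intensity (clamped at zero).
    """
    if background not in ("none", "rolling_min"):
        raise ValueError(f"unknown background mode {background!r}")
    pos, inten = profile.positions, profile.intensities
    lo_all, hi_all = pos[0], pos[-1]
    intervals = sorted(band_windows.items(), key=lambda kv: kv[1][0])
    for (label, (lo, hi)) in intervals:
        if lo >= hi:
            raise ValueError(f"window for {label!r} is empty")
        if lo < lo_all or hi > hi_all:
            raise ValueError(f"window for {label!r} exceeds the profile range")
    for (la, (_, hi_a)), (lb, (lo_b, _)) in zip(intervals, intervals[1:]):
        if hi_a > lo_b:
            raise ValueError(f"windows {la!r} and {lb!r} overlap")

    if background == "rolling_min":
        w = background_window or max(pos.size // 20, 3)
        inten = np.clip(inten - _rolling_min(inten, w), 0.0, None)

    out = {}
    for label, (lo, hi) in band_windows.items():
        # include interpolated endpoints so the integral covers [lo, hi] exactly
        inner = (pos > lo) & (pos < hi)
        xs = np.concatenate([[lo], pos[inner], [hi]])
        ys = np.concatenate([
            [np.interp(lo, pos, inten)], inten[inner], [np.interp(hi, pos, inten)]
        ])
        out[label] = max(float(np.trapezoid(ys, xs)), 0.0)
    return out


def band_fractions(bt: dict) -> dict:
    """Normalize a band table to per-lane fractions (sum to 1)."""
    _validate_band_table(bt)
    total = float(sum(bt.values()))
    if total <= 0:
        raise ValueError("lane total must be positive")
    return {label: v / total for label, v in bt.items()}


def ts_efficiency(bt: dict) -> float:
    """Template-switching efficiency in percent.

    100 x (sum of all switched-product bands) / (total lane signal).
    """
    _validate_band_table(bt)
    total = float(sum(bt.values()))
    if total <= 0:
        raise ValueError("lane total must be positive")
    switched = sum(float(bt.get(label, 0.0)) for label in TS_BANDS)
    return 100.0 * switched / total
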