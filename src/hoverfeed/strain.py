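"""Feeder-force signal pipeline: calibration, segmentation, detrending,
amplitude and band-power ratios, and push in body-weight units.

The analysis follows the instrumented-feeder protocol: feeds are cropped by
0.25 s at each end to discard docking/undocking spikes, each channel is
detrended with a straight line fitted to the pre- and post-feed data, and
three summaries are computed per feed and axis:

* ``amplitude_ratio`` -- peak-to-peak voltage while docked over peak-to-peak
  voltage before the first dock (values > 1 mean the docked bird shakes the
  feeder harder than the background noise floor).
* ``band_power_ratio`` -- integrated spectral power while docked over power
  before docking, for the licking band (10-15 Hz), the wingbeat band
  (35-45 Hz) and the 60 Hz mains reference (59-61 Hz).
* ``push_wb`` -- the shift of the mean signal while docked, converted
  through the weight calibration and normalized to body weight (4.0 g by
  default; positive = push toward the bird's left / upward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import StrainTrace

__all__ = [
    "CalibrationFit",
    "FeedSegment",
    "CROP_S",
    "BANDS_HZ",
    "DEFAULT_BODY_MASS_G",
    "fit_calibration",
    "segment_feeds",
    "detrend",
    "amplitude_ratio",
    "band_power_ratio",
    "compute_push",
    "analyze_trace",
    "trial_means",
]

#: Crop applied to each end of every dock interval (s), sized to discard
#: docking/undocking spike transients.
CROP_S = 0.25

#: Analysis bands (Hz): licking, wingbeat, and the mains reference taken as
#: a 2 Hz window around 60 Hz for leakage robustness.
BANDS_HZ = {"bpr_10_15": (10.0, 15.0), "bpr_35_45": (35.0, 45.0), "bpr_60": (59.0, 61.0)}

#: Average body mass of the instrumented-feeder birds (g).
DEFAULT_BODY_MASS_G = 4.0


@dataclass(frozen=True)
class CalibrationFit:
    """Through-the-origin weight calibration of one strain axis."""

    slope_V_per_g: float
    residual_rms_V: float
    n_points: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_V_per_g):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class FeedSegment:
    """One feed: raw dock interval, spike-cropped interval, and the shared
    pre-first-feed / post-last-feed reference windows."""

    raw: tuple[float, float]
    cropped: tuple[float, float]
    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    @property
    def duration(self) -> float:
        return self.cropped[1] - self.cropped[0]


def fit_calibration(mass_voltage_pairs: np.ndarray | Sequence[tuple[float, float]]) -> CalibrationFit:
    """Least-squares line through the origin: slope = sum(m*v) / sum(m^2)."""
    arr = np.asarray(mass_voltage_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("expected a non-empty (n, 2) array of (mass, voltage) pairs")
    m, v = arr[:, 0], arr[:, 1]
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    slope = float(np.sum(m * v) / np.sum(m * m))
    resid = v - slope * m
    return CalibrationFit(
        slope_V_per_g=slope,
        residual_rms_V=float(np.sqrt(np.mean(resid**2))),
        n_points=len(m),
    )


def segment_feeds(trace: StrainTrace, crop_s: float = CROP_S) -> list[FeedSegment]:
    """One :class:`FeedSegment` per dock event, cropped by ``crop_s`` at each
    end.  Docks too short to survive the crop are excluded.  The pre window
    runs from the start of the record to ``crop_s`` before the first dock;
    the post window from ``crop_s`` after the last dock to the end of the
    record -- the stand-off keeps docking/undocking spike transients out of
    the reference windows as well as out of the feeds."""
    if not trace.dock_events:
        raise ValueError("trace has no dock events")
    t0, t1 = float(trace.time[0]), float(trace.time[-1])
    pre = (t0, trace.dock_events[0][0] - crop_s)
    post = (trace.dock_events[-1][1] + crop_s, t1)
    segments = []
    for a, b in trace.dock_events:
        if b - a <= 2.0 * crop_s:
            continue  # crop would empty the interval
        segments.append(
            FeedSegment(raw=(a, b), cropped=(a + crop_s, b - crop_s), pre_window=pre, post_window=post)
        )
    return segments


def detrend(trace: StrainTrace, segments: Sequence[FeedSegment]) -> StrainTrace:
    """Subtract, per channel, a straight line fitted by ordinary least
    squares to the concatenated pre- and post-feed samples."""
    if not segments:
        raise ValueError("no feed segments supplied")
    pre, post = segments[0].pre_window, segments[0].post_window
    fit_mask = trace.mask(*pre) | trace.mask(*post)
    if not np.any(fit_mask):
        raise ValueError("pre/post windows contain no samples")
    t_fit = trace.time[fit_mask]
    new = {}
    for axis in ("horizontal", "vertical"):
        y = trace.channel(axis)
        coef = np.polynomial.polynomial.polyfit(t_fit, y[fit_mask], deg=1)
        new[axis] = y - np.polynomial.polynomial.polyval(trace.time, coef)
    return trace.replace_channels(new["horizontal"], new["vertical"])


def amplitude_ratio(trace: StrainTrace, axis: str, segment: FeedSegment) -> float:
    """Peak-to-peak amplitude while docked (cropped) over peak-to-peak
    amplitude over the pre-dock window."""
    y = trace.channel(axis)
    docked = y[trace.mask(*segment.cropped)]
    pre = y[trace.mask(*segment.pre_window)]
    if len(docked) == 0 or len(pre) == 0:
        raise ValueError("empty segment or pre-window")
    denom = float(np.ptp(pre))
    if denom == 0.0:
        raise ZeroDivisionError("pre-dock window has zero peak-to-peak amplitude")
    return float(np.ptp(docked)) / denom


def _band_power(y: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Integrated Welch PSD (1 s Hann windows, 50% overlap) over ``band``."""
    nperseg = min(len(y), int(round(fs)))
    freqs, psd = sps.welch(y, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < 2:
        raise ValueError(f"band {band} under-resolved by the spectral estimate")
    return float(np.trapezoid(psd[sel], freqs[sel]))


def band_power_ratio(
    trace: StrainTrace, axis: str, segment: FeedSegment, band_hz: tuple[float, float]
) -> float:
    """Integrated spectral power in ``band_hz`` while docked over the same
    quantity in the pre-dock window."""
    if band_hz[1] >= trace.sample_rate / 2.0:
        raise ValueError("band extends beyond the Nyquist frequency")
    y = trace.channel(axis)
    docked = y[trace.mask(*segment.cropped)]
    pre = y[trace.mask(*segment.pre_window)]
    if len(docked) < trace.sample_rate or len(pre) < trace.sample_rate:
        raise ValueError("docked segment and pre-window must each span >= 1 s")
    return _band_power(docked, trace.sample_rate, band_hz) / _band_power(
        pre, trace.sample_rate, band_hz
    )


def compute_push(
    trace: StrainTrace,
    axis: str,
    segment: FeedSegment,
    calibration: CalibrationFit,
    body_mass_g: float = DEFAULT_BODY_MASS_G,
) -> float:
    """Mean push against the feeder while docked, in body weights.

    Computed from a detrended channel as the docked-minus-pre mean voltage,
    through the calibration slope (V/g) and body mass.  Positive = toward
    the bird's left (horizontal axis) or upward (vertical axis).
    """
    if calibration.slope_V_per_g <= 0:
        raise ValueError("calibration slope must be positive")
    if body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    y = trace.channel(axis)
    docked = y[trace.mask(*segment.cropped)]
    pre = y[trace.mask(*segment.pre_window)]
    if len(docked) == 0 or len(pre) == 0:
        raise ValueError("empty segment or pre-window")
    delta_v = float(np.mean(docked) - np.mean(pre))
    return delta_v / calibration.slope_V_per_g / body_mass_g


def analyze_trace(
    trace: StrainTrace,
    calibration: dict[str, CalibrationFit],
    body_mass_g: float = DEFAULT_BODY_MASS_G,
    detrend_first: bool = True,
) -> pd.DataFrame:
    """Run the full per-feed pipeline on both axes.

    Returns one row per (feed, axis) with columns ``feed_id``, ``axis``,
    ``amplitude_ratio``, ``bpr_10_15``, ``bpr_35_45``, ``bpr_60`` and
    ``push_wb``.  The vertical axis is processed identically to the
    horizontal one and carries a ``quality_flag`` column for callers that
    need to exclude it on acquisition grounds.
    """
    segments = segment_feeds(trace)
    if not segments:
        raise ValueError("no analyzable feed segments (all docks too short)")
    work = detrend(trace, segments) if detrend_first else trace
    rows = []
    for i, seg in enumerate(segments):
        for axis in ("horizontal", "vertical"):
            row: dict = {"feed_id": i, "axis": axis, "quality_flag": ""}
            row["amplitude_ratio"] = amplitude_ratio(work, axis, seg)
            for name, band in BANDS_HZ.items():
                row[name] = band_power_ratio(work, axis, seg, band)
            row["push_wb"] = compute_push(work, axis, seg, calibration[axis], body_mass_g)
            rows.append(row)
    return pd.DataFrame(rows)


def trial_means(per_feed: pd.DataFrame) -> pd.DataFrame:
    """Per-trial aggregation: mean across feeds within each axis."""
    value_cols = [c for c in per_feed.columns if c not in ("feed_id", "axis", "quality_flag")]
    return per_feed.groupby("axis", sort=False)[value_cols].mean().reset_index()
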