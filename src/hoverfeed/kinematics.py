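"""Wingbeat-kinematic analysis of digitized landmark trajectories.

Pipeline stages, in order:

1. :func:`filter_trajectories` -- zero-phase low-pass Butterworth filtering
   with landmark-class cutoffs tied to the wingbeat frequency.
2. :func:`segment_strokes` -- per-wing stroke-plane fit, in-plane excursion
   angle, and pronation/supination detection (minimum/maximum excursion).
3. :func:`transform_frame` -- head-centered, per-wingbeat yaw-aligned
   gravitational frame built from the wingtip-path dividing line.
4. :func:`summarize_trial` -- the kinematic variables: travel angle (psi),
   sagittal and frontal body angles (chi_XZ, chi_YZ), wing bank angle (WBA),
   relative wing bank angle (RWBA), stroke amplitude, bill insertion, and
   the geometric angle-of-attack time course.
5. :func:`average_cycle` -- a phase-normalized average wingbeat for the
   quasi-steady force model.

Conventions: x forward, y toward the bird's left, z up.  WBA is half the
left-minus-right mean elevation difference (positive = left wing elevated);
RWBA is ``|WBA + chi_YZ|`` with the frontal body angle expressed as the
deviation of the dorsoventral axis from vertical (positive = tilt toward the
bird's left).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._geom import unit
from .datatypes import LANDMARK_NAMES, LandmarkSet, WingbeatCycle

__all__ = [
    "StrokeSegmentation",
    "KinematicSummary",
    "FILTER_CUTOFF_MULTIPLIERS",
    "fill_gaps",
    "estimate_wingbeat_frequency",
    "filter_trajectories",
    "segment_strokes",
    "transform_frame",
    "compute_wba",
    "compute_rwba",
    "compute_body_angles",
    "compute_travel_angle",
    "compute_geometric_alpha",
    "compute_bill_insertion",
    "summarize_trial",
    "average_cycle",
]

#: Low-pass cutoff per landmark, as a multiple of the wingbeat frequency:
#: body landmarks move slowly (head slowest), wing landmarks carry harmonics.
FILTER_CUTOFF_MULTIPLIERS = {
    "head": 2.0,
    "tail": 6.0,
    "l_shoulder": 6.0,
    "r_shoulder": 6.0,
    "l_wingtip": 8.0,
    "r_wingtip": 8.0,
    "l_p5": 8.0,
    "r_p5": 8.0,
}

_WINGS = ("left", "right")
_TIP = {"left": "l_wingtip", "right": "r_wingtip"}
_SHOULDER = {"left": "l_shoulder", "right": "r_shoulder"}
_P5 = {"left": "l_p5", "right": "r_p5"}


# ---------------------------------------------------------------------------
# ingest helpers and filtering
# ---------------------------------------------------------------------------

def fill_gaps(ls: LandmarkSet, max_gap_s: float = 0.005) -> LandmarkSet:
    """Linearly interpolate NaN runs up to ``max_gap_s``; longer gaps raise."""
    positions = {}
    max_len = int(round(max_gap_s * ls.sample_rate))
    for name in LANDMARK_NAMES:
        arr = ls.positions[name].copy()
        bad = np.isnan(arr).any(axis=1)
        if bad.any():
            # length of each NaN run
            edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
            starts, ends = edges[::2], edges[1::2]
            if np.any(ends - starts > max_len):
                raise ValueError(f"gap longer than {max_gap_s} s in landmark {name!r}")
            good = ~bad
            for k in range(3):
                arr[bad, k] = np.interp(ls.time[bad], ls.time[good], arr[good, k])
        positions[name] = arr
    return ls.copy_with(positions)


def estimate_wingbeat_frequency(
    ls: LandmarkSet, search_band_hz: tuple[float, float] = (20.0, 60.0)
) -> float:
    """Coarse wingbeat-frequency estimate from the wingtip periodogram."""
    z = ls["l_wingtip"][:, 2] - ls["l_shoulder"][:, 2]
    freqs, psd = sps.periodogram(z - z.mean(), fs=ls.sample_rate)
    sel = (freqs >= search_band_hz[0]) & (freqs <= search_band_hz[1])
    if not np.any(sel):
        raise ValueError("search band contains no spectral bins")
    return float(freqs[sel][np.argmax(psd[sel])])


def filter_trajectories(ls: LandmarkSet, wingbeat_freq_hz: float) -> LandmarkSet:
    """Zero-phase fourth-order low-pass Butterworth filtering.

    Cutoffs are ``FILTER_CUTOFF_MULTIPLIERS[name] * wingbeat_freq_hz``; the
    filter is applied forward-backward (``sosfiltfilt``), so it introduces no
    phase lag.
    """
    nyq = ls.sample_rate / 2.0
    positions = {}
    for name in LANDMARK_NAMES:
        cutoff = FILTER_CUTOFF_MULTIPLIERS[name] * wingbeat_freq_hz
        if cutoff >= nyq:
            raise ValueError(
                f"cutoff {cutoff:.1f} Hz for {name!r} reaches the Nyquist frequency {nyq:.1f} Hz"
            )
        sos = sps.butter(4, cutoff, btype="low", fs=ls.sample_rate, output="sos")
        positions[name] = sps.sosfiltfilt(sos, ls.positions[name], axis=0)
    return ls.copy_with(positions)


# ---------------------------------------------------------------------------
# stroke segmentation
# ---------------------------------------------------------------------------

@dataclass
class StrokeSegmentation:
    """Per-wing stroke transitions and the excursion signals they came from.

    Pronation is the minimum of the in-plane excursion angle, supination the
    maximum.  Times are refined to sub-frame precision by parabolic
    interpolation around the discrete extremum.
    """

    pronation_s: dict[str, np.ndarray]
    supination_s: dict[str, np.ndarray]
    pronation_deg: dict[str, np.ndarray]   # excursion value at each pronation
    supination_deg: dict[str, np.ndarray]
    excursion_deg: dict[str, np.ndarray]   # full in-plane excursion series
    plane_normal: dict[str, np.ndarray]
    wingbeat_freq_hz: float

    def n_cycles(self, wing: str) -> int:
        return max(len(self.pronation_s[wing]) - 1, 0)


def _parabolic_refine(y: np.ndarray, i: int, dt: float, t0: float) -> tuple[float, float]:
    """Sub-sample extremum location/value via a 3-point parabola."""
    if i <= 0 or i >= len(y) - 1:
        return t0 + i * dt, float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return t0 + i * dt, float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return t0 + (i + delta) * dt, float(value)


def _excursion_angle(ls: LandmarkSet, wing: str) -> tuple[np.ndarray, np.ndarray]:
    """In-plane excursion angle (deg) of the wingtip about the shoulder.

    The stroke plane is a total-least-squares fit to the shoulder-relative
    wingtip positions; the angle is measured from the straight-lateral
    direction, positive toward the bird's front.
    """
    rel = ls[_TIP[wing]] - ls[_SHOULDER[wing]]
    centered = rel - rel.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal

    fwd = unit(np.array([*(ls["head"] - ls["tail"]).mean(axis=0)[:2], 0.0]))
    left = unit(np.array([*(ls["l_shoulder"] - ls["r_shoulder"]).mean(axis=0)[:2], 0.0]))
    side = left if wing == "left" else -left
    a1 = unit(side - np.dot(side, normal) * normal)          # lateral reference
    a2 = np.cross(normal, a1)
    if np.dot(a2, fwd) < 0:
        a2 = -a2                                             # positive toward front
    theta = np.degrees(np.arctan2(rel @ a2, rel @ a1))
    return theta, normal


def segment_strokes(
    ls: LandmarkSet,
    plausibility_hz: tuple[float, float] = (20.0, 60.0),
) -> StrokeSegmentation:
    """Detect pronation/supination per wing and the wingbeat frequency.

    Requires at least three detected cycles per wing.  The wingbeat
    frequency is the reciprocal of the median inter-pronation interval
    (both wings pooled).
    """
    dt = 1.0 / ls.sample_rate
    t0 = float(ls.time[0])
    f0 = estimate_wingbeat_frequency(ls, plausibility_hz)
    min_dist = max(2, int(round(0.6 * ls.sample_rate / f0)))

    pron_s, sup_s, pron_v, sup_v, series, normals = {}, {}, {}, {}, {}, {}
    for wing in _WINGS:
        theta, normal = _excursion_angle(ls, wing)
        prom = 0.2 * float(np.std(theta))
        sup_idx, _ = sps.find_peaks(theta, distance=min_dist, prominence=prom)
        pron_idx, _ = sps.find_peaks(-theta, distance=min_dist, prominence=prom)
        if len(pron_idx) < 3:
            raise ValueError(f"fewer than 3 stroke cycles detected for the {wing} wing")
        pr = np.array([_parabolic_refine(theta, i, dt, t0) for i in pron_idx])
        su = np.array([_parabolic_refine(theta, i, dt, t0) for i in sup_idx])
        pron_s[wing], pron_v[wing] = pr[:, 0], pr[:, 1]
        sup_s[wing], sup_v[wing] = su[:, 0], su[:, 1]
        series[wing] = theta
        normals[wing] = normal

    intervals = np.concatenate([np.diff(pron_s[w]) for w in _WINGS])
    freq = 1.0 / float(np.median(intervals))
    if not plausibility_hz[0] <= freq <= plausibility_hz[1]:
        raise ValueError(f"wingbeat frequency {freq:.1f} Hz outside plausibility band")
    return StrokeSegmentation(
        pronation_s=pron_s,
        supination_s=sup_s,
        pronation_deg=pron_v,
        supination_deg=sup_v,
        excursion_deg=series,
        plane_normal=normals,
        wingbeat_freq_hz=freq,
    )


# ---------------------------------------------------------------------------
# frame transform
# ---------------------------------------------------------------------------

def _paired_cycles(seg: StrokeSegmentation) -> list[dict]:
    """Pair pronations/supinations across wings into wingbeat cycles.

    A cycle runs pronation-to-pronation; each wing contributes its own
    transition times (they may differ when wing rotation is asymmetric).
    """
    cycles = []
    n = min(len(seg.pronation_s[w]) for w in _WINGS) - 1
    for k in range(n):
        cyc = {"start": np.mean([seg.pronation_s[w][k] for w in _WINGS]),
               "end": np.mean([seg.pronation_s[w][k + 1] for w in _WINGS])}
        ok = True
        for w in _WINGS:
            p0, p1 = seg.pronation_s[w][k], seg.pronation_s[w][k + 1]
            sups = seg.supination_s[w]
            mask = (sups > p0) & (sups < p1)
            if not mask.any():
                ok = False
                break
            j = int(np.flatnonzero(mask)[0])
            cyc[w] = {
                "pron": (p0, seg.pronation_deg[w][k]),
                "next_pron": (p1, seg.pronation_deg[w][k + 1]),
                "sup": (sups[j], seg.supination_deg[w][j]),
            }
        if ok:
            cycles.append(cyc)
    if len(cycles) < 3:
        raise ValueError("fewer than 3 complete wingbeat cycles")
    return cycles


def _interp_pos(ls: LandmarkSet, name: str, t: float) -> np.ndarray:
    return np.array([np.interp(t, ls.time, ls.positions[name][:, k]) for k in range(3)])


def transform_frame(
    ls: LandmarkSet, seg: StrokeSegmentation
) -> tuple[LandmarkSet, list[dict]]:
    """Head-centered, yaw-aligned gravitational frame.

    Every frame is translated so the head sits at the origin.  Per wingbeat,
    the lateral axis is the horizontal projection of the wingtip-path
    dividing line -- the line joining the midpoints of each wing's
    head-centered wingtip positions at its stroke transitions -- and the
    vertical axis stays gravitational.  Returns the transformed landmarks
    and a per-cycle list with the frame's lab yaw.
    """
    cycles = _paired_cycles(seg)
    head = ls["head"]
    centered = {name: ls.positions[name] - head for name in LANDMARK_NAMES}

    infos = []
    for cyc in cycles:
        mids = {}
        for wing in _WINGS:
            pts = []
            for key in ("pron", "sup"):
                t_ev = cyc[wing][key][0]
                tip = _interp_pos(ls, _TIP[wing], t_ev) - _interp_pos(ls, "head", t_ev)
                pts.append(tip)
            mids[wing] = 0.5 * (pts[0] + pts[1])
        div = mids["left"] - mids["right"]
        horiz = np.array([div[0], div[1], 0.0])
        if np.linalg.norm(horiz) < 1e-9:
            raise ValueError("degenerate wingtip-path dividing line")
        y_b = horiz / np.linalg.norm(horiz)
        x_b = np.cross(y_b, np.array([0.0, 0.0, 1.0]))
        rot = np.vstack([x_b, y_b, [0.0, 0.0, 1.0]])
        infos.append(
            {"start": cyc["start"], "end": cyc["end"], "cycle": cyc,
             "rot": rot, "yaw_deg": math.degrees(math.atan2(x_b[1], x_b[0]))}
        )

    # assign every frame to the nearest cycle and rotate
    bounds = np.array([0.5 * (a["end"] + b["start"]) for a, b in zip(infos[:-1], infos[1:])])
    idx = np.searchsorted(bounds, ls.time)
    positions = {name: np.empty_like(arr) for name, arr in centered.items()}
    for k, info in enumerate(infos):
        m = idx == k
        for name in LANDMARK_NAMES:
            positions[name][m] = centered[name][m] @ info["rot"].T
    out = ls.copy_with(positions)
    return out, infos


# ---------------------------------------------------------------------------
# kinematic variables
# ---------------------------------------------------------------------------

def compute_wba(left_elev_deg: float, right_elev_deg: float) -> float:
    """Wing bank angle: half the left-minus-right mean elevation difference.
    Positive when the left wing is elevated and the right depressed."""
    return 0.5 * (left_elev_deg - right_elev_deg)


def compute_rwba(wba_deg: float, chi_yz_deg: float) -> float:
    """Relative wing bank angle ``|WBA + chi_YZ|``: zero when the wings are
    perpendicular to the dorsoventral body axis."""
    return abs(wba_deg + chi_yz_deg)


def compute_body_angles(
    head: np.ndarray, tail: np.ndarray, l_shoulder: np.ndarray, r_shoulder: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame body angles in the gravitational frame.

    ``chi_XZ`` is the elevation of the tail-to-head axis above horizontal;
    ``chi_YZ`` is the deviation of the dorsoventral axis from vertical in
    the frontal plane, positive toward the bird's left.
    """
    b = np.atleast_2d(head - tail)
    if np.any(np.linalg.norm(b, axis=1) < 1e-9):
        raise ValueError("coincident head and tail positions")
    chi_xz = np.degrees(np.arctan2(b[:, 2], np.hypot(b[:, 0], b[:, 1])))
    lateral = np.atleast_2d(l_shoulder - r_shoulder)
    dorsal = np.cross(b, lateral)
    if np.median(dorsal[:, 2]) < 0:
        dorsal = -dorsal
    chi_yz = np.degrees(np.arctan2(dorsal[:, 1], dorsal[:, 2]))
    return chi_xz, chi_yz


def compute_travel_angle(dividing_line: np.ndarray, motion_direction: Optional[str]) -> Optional[float]:
    """Signed travel angle (deg) from the wingtip-path dividing line.

    The dividing line points toward the bird's left; the bird's forward axis
    is that line rotated -90 deg about vertical.  Positive when the bird
    faces the direction of motion; ``None`` (not applicable) for hovering.
    """
    if motion_direction in (None, "hover", "none"):
        return None
    if motion_direction not in ("left", "right"):
        raise ValueError("motion_direction must be 'left', 'right' or None")
    d = np.asarray(dividing_line, dtype=float)
    fx, fy = d[1], -d[0]
    yaw = math.degrees(math.atan2(fy, fx))
    return yaw if motion_direction == "left" else -yaw


def compute_geometric_alpha(
    shoulder: np.ndarray, wingtip: np.ndarray, p5: np.ndarray
) -> np.ndarray:
    """Per-frame geometric angle of attack (deg, in [0, 90]).

    The angle between the wing plane -- through shoulder, wingtip and the
    5th-primary tip -- and the horizontal: 0 = wing flat, 90 = wing vertical.
    Frames with (near-)collinear points are flagged and linearly
    interpolated from their neighbors.
    """
    a = np.atleast_2d(wingtip - shoulder)
    b = np.atleast_2d(p5 - shoulder)
    n = np.cross(a, b)
    norms = np.linalg.norm(n, axis=1)
    scale = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    good = norms > 1e-6 * np.maximum(scale, 1e-12)
    alpha = np.full(len(n), np.nan)
    alpha[good] = np.degrees(np.arccos(np.clip(np.abs(n[good, 2]) / norms[good], 0.0, 1.0)))
    if not good.all():
        if not good.any():
            raise ValueError("all frames collinear; wing plane undefined")
        idx = np.arange(len(alpha))
        alpha[~good] = np.interp(idx[~good], idx[good], alpha[good])
    return alpha


def compute_bill_insertion(
    head: np.ndarray,
    forward: np.ndarray,
    mouth_point: np.ndarray,
    mouth_normal: np.ndarray,
    culmen_length_m: float,
) -> np.ndarray:
    """Per-frame bill insertion as a percentage of the exposed culmen.

    The bill is modeled as a straight segment of ``culmen_length_m`` from
    the head landmark along the head's forward axis; insertion is the
    fraction of that segment beyond the feeder mouth plane (normal pointing
    into the feeder), clamped to [0, 100].
    """
    if culmen_length_m <= 0:
        raise ValueError("culmen length must be positive")
    head = np.atleast_2d(head)
    forward = unit(np.atleast_2d(forward))
    n_hat = unit(np.asarray(mouth_normal, dtype=float))
    tip = head + culmen_length_m * forward
    s_base = (head - mouth_point) @ n_hat
    s_tip = (tip - mouth_point) @ n_hat
    span = s_tip - s_base
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (np.clip(s_tip, 0.0, None) - np.clip(s_base, 0.0, None)) / span
    frac = np.where(np.abs(span) < 1e-12, (s_tip > 0).astype(float), frac)
    return np.clip(100.0 * frac, 0.0, 100.0)


# ---------------------------------------------------------------------------
# trial summary and phase-normalized average cycle
# ---------------------------------------------------------------------------

@dataclass
class KinematicSummary:
    """Per-trial means of the kinematic variables (degrees / percent)."""

    mode: str
    wingbeat_freq_hz: float
    n_wingbeats: int
    psi_deg: Optional[float]
    chi_xz_ds_deg: float
    chi_xz_us_deg: float
    chi_yz_ds_deg: float
    chi_yz_us_deg: float
    wba_ds_deg: float
    wba_us_deg: float
    rwba_ds_deg: float
    rwba_us_deg: float
    stroke_amplitude_deg: float
    bill_insertion_pct: Optional[float]
    per_wingbeat: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "per_wingbeat"}
        return d


def _window_mean(time: np.ndarray, values: np.ndarray, start: float, end: float) -> float:
    m = (time >= start) & (time < end)
    if not m.any():
        return float("nan")
    return float(np.mean(values[m]))


def summarize_trial(
    ls: LandmarkSet,
    mode: Optional[str] = None,
    rwba_aggregation: str = "mean_of_abs",
    prefiltered: bool = False,
) -> KinematicSummary:
    """Full kinematic summary of one recording.

    ``rwba_aggregation`` selects whether RWBA is averaged across wingbeats
    after taking the absolute value per wingbeat (``"mean_of_abs"``) or the
    absolute value is applied to the across-wingbeat mean (``"abs_of_mean"``);
    the two differ only when the signed quantity straddles zero.
    """
    if rwba_aggregation not in ("mean_of_abs", "abs_of_mean"):
        raise ValueError("rwba_aggregation must be 'mean_of_abs' or 'abs_of_mean'")
    mode = mode or ls.meta.get("mode", "hover")

    work = ls if prefiltered else filter_trajectories(ls, estimate_wingbeat_frequency(ls))
    seg = segment_strokes(work)
    trans, infos = transform_frame(work, seg)

    elev = {}
    for wing in _WINGS:
        rel = trans[_TIP[wing]] - trans[_SHOULDER[wing]]
        elev[wing] = np.degrees(np.arcsin(np.clip(rel[:, 2] / np.linalg.norm(rel, axis=1), -1, 1)))
    chi_xz, chi_yz = compute_body_angles(
        trans["head"], trans["tail"], trans["l_shoulder"], trans["r_shoulder"]
    )
    alpha = {
        wing: compute_geometric_alpha(trans[_SHOULDER[wing]], trans[_TIP[wing]], trans[_P5[wing]])
        for wing in _WINGS
    }

    has_bill = "feeder_mouth_point" in ls.meta
    if has_bill:
        # horizontal forward axis from the shoulder line (free of the
        # lateral leak a rolled body axis would introduce)
        fwd = np.cross(ls["l_shoulder"] - ls["r_shoulder"], [0.0, 0.0, 1.0])
        fwd[:, 2] = 0.0
        bill_series = compute_bill_insertion(
            ls["head"],
            fwd,
            np.asarray(ls.meta["feeder_mouth_point"], dtype=float),
            np.asarray(ls.meta["feeder_mouth_normal"], dtype=float),
            float(ls.meta["culmen_length_m"]),
        )

    rows = []
    for info in infos:
        cyc = info["cycle"]
        # per-wing stroke-phase windows
        win = {}
        for wing in _WINGS:
            p0, _ = cyc[wing]["pron"]
            s0, _ = cyc[wing]["sup"]
            p1, _ = cyc[wing]["next_pron"]
            win[wing] = {"ds": (p0, s0), "us": (s0, p1)}
        t = trans.time
        row: dict = {"start_s": info["start"], "end_s": info["end"], "yaw_deg": info["yaw_deg"]}
        for phase in ("ds", "us"):
            e_l = _window_mean(t, elev["left"], *win["left"][phase])
            e_r = _window_mean(t, elev["right"], *win["right"][phase])
            row[f"wba_{phase}"] = compute_wba(e_l, e_r)
            # body windows: average of the two wings' windows
            b0 = np.mean([win[w][phase][0] for w in _WINGS])
            b1 = np.mean([win[w][phase][1] for w in _WINGS])
            row[f"chi_xz_{phase}"] = _window_mean(t, chi_xz, b0, b1)
            row[f"chi_yz_{phase}"] = _window_mean(t, chi_yz, b0, b1)
            row[f"rwba_{phase}"] = compute_rwba(row[f"wba_{phase}"], row[f"chi_yz_{phase}"])
            row[f"alpha_left_{phase}"] = _window_mean(t, alpha["left"], *win["left"][phase])
            row[f"alpha_right_{phase}"] = _window_mean(t, alpha["right"], *win["right"][phase])
        row["phi_sp"] = np.mean(
            [cyc[w]["sup"][1] - 0.5 * (cyc[w]["pron"][1] + cyc[w]["next_pron"][1]) for w in _WINGS]
        )
        if has_bill:
            row["bill_pct"] = _window_mean(ls.time, bill_series, info["start"], info["end"])
        rows.append(row)
    per_wb = pd.DataFrame(rows)

    psi = None
    if mode in ("left", "right"):
        psi = float(np.mean([compute_travel_angle(_yaw_to_div(y), mode) for y in per_wb["yaw_deg"]]))

    def agg_rwba(phase: str) -> float:
        if rwba_aggregation == "mean_of_abs":
            return float(per_wb[f"rwba_{phase}"].mean())
        return abs(float(per_wb[f"wba_{phase}"].mean() + per_wb[f"chi_yz_{phase}"].mean()))

    return KinematicSummary(
        mode=mode,
        wingbeat_freq_hz=seg.wingbeat_freq_hz,
        n_wingbeats=len(per_wb),
        psi_deg=psi,
        chi_xz_ds_deg=float(per_wb["chi_xz_ds"].mean()),
        chi_xz_us_deg=float(per_wb["chi_xz_us"].mean()),
        chi_yz_ds_deg=float(per_wb["chi_yz_ds"].mean()),
        chi_yz_us_deg=float(per_wb["chi_yz_us"].mean()),
        wba_ds_deg=float(per_wb["wba_ds"].mean()),
        wba_us_deg=float(per_wb["wba_us"].mean()),
        rwba_ds_deg=agg_rwba("ds"),
        rwba_us_deg=agg_rwba("us"),
        stroke_amplitude_deg=float(per_wb["phi_sp"].mean()),
        bill_insertion_pct=float(per_wb["bill_pct"].mean()) if "bill_pct" in per_wb else None,
        per_wingbeat=per_wb,
    )


def _yaw_to_div(yaw_deg: float) -> np.ndarray:
    """Bird-left dividing-line direction for a lab-frame yaw (deg)."""
    r = math.radians(yaw_deg)
    return np.array([-math.sin(r), math.cos(r), 0.0])


def average_cycle(
    ls: LandmarkSet,
    n_points: int = 200,
    downstroke_fraction: float = 0.48,
    mode: Optional[str] = None,
    prefiltered: bool = False,
) -> WingbeatCycle:
    """Phase-normalized average wingbeat from a landmark recording.

    Each wing's downstroke (pronation to supination) is resampled to
    ``round(downstroke_fraction * n_points)`` points and its upstroke to the
    remainder, then averaged across wingbeats.  Returns excursion,
    elevation and geometric angle of attack per wing, plus the measured
    wingbeat frequency, stroke amplitude, body velocity and travel angle.
    """
    mode = mode or ls.meta.get("mode", "hover")
    work = ls if prefiltered else filter_trajectories(ls, estimate_wingbeat_frequency(ls))
    seg = segment_strokes(work)
    trans, infos = transform_frame(work, seg)
    t = trans.time

    nd = int(round(downstroke_fraction * n_points))
    nu = n_points - nd
    series = {}
    for wing in _WINGS:
        rel = trans[_TIP[wing]] - trans[_SHOULDER[wing]]
        elev = np.degrees(np.arcsin(np.clip(rel[:, 2] / np.linalg.norm(rel, axis=1), -1, 1)))
        alpha = compute_geometric_alpha(trans[_SHOULDER[wing]], trans[_TIP[wing]], trans[_P5[wing]])
        series[wing] = {"excursion": seg.excursion_deg[wing], "elevation": elev, "alpha": alpha}

    acc = {w: {k: [] for k in ("excursion", "elevation", "alpha")} for w in _WINGS}
    for info in infos:
        cyc = info["cycle"]
        for wing in _WINGS:
            p0 = cyc[wing]["pron"][0]
            s0 = cyc[wing]["sup"][0]
            p1 = cyc[wing]["next_pron"][0]
            t_ds = p0 + ((np.arange(nd) + 0.5) / nd) * (s0 - p0)
            t_us = s0 + ((np.arange(nu) + 0.5) / nu) * (p1 - s0)
            t_all = np.concatenate([t_ds, t_us])
            for key in ("excursion", "elevation", "alpha"):
                acc[wing][key].append(np.interp(t_all, t, series[wing][key]))

    mean = {w: {k: np.mean(v, axis=0) for k, v in acc[w].items()} for w in _WINGS}
    phi_sp = float(
        np.mean([mean[w]["excursion"].max() - mean[w]["excursion"].min() for w in _WINGS])
    )

    # body velocity in the bird frame (mean yaw)
    v_lab = np.array(
        [np.polynomial.polynomial.polyfit(ls.time, ls["head"][:, k], 1)[1] for k in range(3)]
    )
    yaw = math.radians(float(np.mean([i["yaw_deg"] for i in infos])))
    rot = np.array(
        [[math.cos(yaw), math.sin(yaw), 0.0], [-math.sin(yaw), math.cos(yaw), 0.0], [0, 0, 1.0]]
    )
    v_bird = rot @ v_lab

    psi = None
    if mode in ("left", "right"):
        psi = float(
            np.mean([compute_travel_angle(_yaw_to_div(i["yaw_deg"]), mode) for i in infos])
        )
    return WingbeatCycle(
        wingbeat_freq_hz=seg.wingbeat_freq_hz,
        excursion_deg={w: mean[w]["excursion"] for w in _WINGS},
        elevation_deg={w: mean[w]["elevation"] for w in _WINGS},
        alpha_deg={w: mean[w]["alpha"] for w in _WINGS},
        downstroke_fraction=downstroke_fraction,
        stroke_amplitude_deg=phi_sp,
        v_body=v_bird,
        psi_deg=psi,
        travel_direction=None if mode == "hover" else mode,
    )
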