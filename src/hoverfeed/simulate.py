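"""Synthetic strain traces and landmark trajectories for pipeline testing.

No recordings from the original experiments are deposited anywhere, so this
module generates inputs with the statistical structure the downstream
analyses assume:

* :func:`generate_strain_trace` emulates the instrumented-feeder voltage
  recordings: licking-band (10-15 Hz) and wingbeat-band (35-45 Hz) tones
  present only while the bird is docked, continuous 60 Hz mains pickup and
  slow drift, docking/undocking spike transients, additive noise, and a mean
  "push" offset in gram-equivalents while docked.
* :func:`generate_landmark_trajectories` emulates video-digitized 3D
  trajectories of the eight anatomical landmarks during hovering or lateral
  feeder tracking, with controllable wingbeat frequency, stroke amplitude,
  left-right elevation asymmetry (wing bank angle), body angles, travel
  angle, angle-of-attack schedule, and digitization noise.
* :func:`generate_calibration_recording` emulates the weight-calibration
  procedure (2, 5 and 10 g standards).

Every generator is deterministic under its seed.  Asymmetry parameters are
the per-maneuver study means (see :func:`preset_params`); a parameter set
with all asymmetries zero is a perfectly mirror-symmetric hover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

from ._geom import Z_HAT, chord_direction, unit, wing_direction
from .datatypes import LandmarkSet, StrainTrace, WingbeatCycle

__all__ = [
    "StrainSimParams",
    "KinematicSimParams",
    "generate_strain_trace",
    "generate_landmark_trajectories",
    "generate_calibration_recording",
    "synthetic_wingbeat_cycle",
    "preset_params",
    "mirror_params",
]


# ---------------------------------------------------------------------------
# strain traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainSimParams:
    """Parameters of one synthetic two-channel strain recording.

    Amplitudes are volts at the amplifier output; ``push_offset_g`` and
    ``calibration_slope`` are per axis (horizontal, vertical).  Band
    amplitudes apply to the horizontal channel; the vertical channel scales
    them by ``vertical_band_gain`` (bill-transmitted oscillations couple more
    strongly into the vertical axis).
    """

    sample_rate: float = 1000.0
    pre_s: float = 4.0
    post_s: float = 4.0
    dock_intervals: tuple[tuple[float, float], ...] = ((4.0, 12.0),)
    push_offset_g: tuple[float, float] = (0.32, 0.0)   # positive = left / up
    licking_amp: float = 0.05
    licking_freq: float = 12.0
    wingbeat_amp: float = 0.15
    wingbeat_freq: float = 40.0
    mains_amp: float = 0.02
    mains_freq: float = 60.0
    drift_slope: float = 0.002          # V/s
    spike_amp: float = 0.5
    spike_tau: float = 0.03             # s, transient decay constant
    noise_sd: float = 0.01
    calibration_slope: tuple[float, float] = (0.159, 0.164)  # V/g
    vertical_band_gain: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pre_s < 3.0 or self.post_s < 3.0:
            raise ValueError("pre_s and post_s must each be >= 3 s")
        top = max(self.licking_freq, self.wingbeat_freq, self.mains_freq)
        if self.sample_rate <= 2.0 * top:
            raise ValueError("sample_rate must exceed twice the highest injected frequency")
        if not self.dock_intervals:
            raise ValueError("at least one dock interval is required")
        prev = -math.inf
        for a, b in self.dock_intervals:
            if b <= a or a < prev:
                raise ValueError("dock intervals must be ordered and non-degenerate")
            prev = b
        if self.dock_intervals[0][0] < self.pre_s:
            raise ValueError("first dock interval must start after pre_s")


def generate_strain_trace(params: StrainSimParams) -> StrainTrace:
    """Simulate a two-channel feeder strain recording.

    Licking/wingbeat tones and the push offset exist only inside dock
    intervals; mains pickup, drift and noise run throughout; each dock and
    undock transition carries an exponential spike transient (which the
    analysis crop is designed to discard).
    """
    p = params
    fs = p.sample_rate
    duration = p.dock_intervals[-1][1] + p.post_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    if p.dock_intervals[-1][1] >= t[-1]:
        raise ValueError("dock intervals must end before the recording does")

    rng = np.random.default_rng(p.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)  # lick, wingbeat, mains

    base = p.drift_slope * t + p.mains_amp * np.sin(2 * np.pi * p.mains_freq * t + phases[2])
    docked = (
        p.licking_amp * np.sin(2 * np.pi * p.licking_freq * t + phases[0])
        + p.wingbeat_amp * np.sin(2 * np.pi * p.wingbeat_freq * t + phases[1])
    )

    dock_mask = np.zeros(n, dtype=bool)
    for a, b in p.dock_intervals:
        dock_mask |= (t >= a) & (t < b)

    spikes = np.zeros(n)
    if p.spike_amp != 0.0:
        for a, b in p.dock_intervals:
            for t0, sign in ((a, 1.0), (b, -1.0)):
                seg = (t >= t0) & (t < t0 + 8 * p.spike_tau)
                spikes[seg] += sign * p.spike_amp * np.exp(-(t[seg] - t0) / p.spike_tau)

    channels = []
    for axis, gain in ((0, 1.0), (1, p.vertical_band_gain)):
        noise = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else 0.0
        push_v = p.push_offset_g[axis] * p.calibration_slope[axis]
        ch = base + spikes + noise + dock_mask * (gain * docked + push_v)
        channels.append(ch)

    return StrainTrace(
        time=t,
        horizontal=channels[0],
        vertical=channels[1],
        dock_events=list(p.dock_intervals),
        sample_rate=fs,
    )


def generate_calibration_recording(
    slope_V_per_g: float,
    weights_g: Sequence[float] = (2.0, 5.0, 10.0),
    noise_sd: float = 0.0,
    n_repeats: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Simulated calibration points: columns (mass_g, voltage_V).

    Voltage is ``slope * mass`` plus Gaussian noise; the default weights are
    the 2, 5 and 10 g standards hung from the feeder.
    """
    weights = np.asarray(weights_g, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    rng = np.random.default_rng(seed)
    masses = np.tile(weights, n_repeats)
    volts = slope_V_per_g * masses
    if noise_sd > 0:
        volts = volts + rng.normal(0.0, noise_sd, size=len(masses))
    return np.column_stack([masses, volts])


# ---------------------------------------------------------------------------
# phase profiles
# ---------------------------------------------------------------------------

def _transition_weight(
    phi: np.ndarray, d: float, w: float, sup_shift: float = 0.0
) -> np.ndarray:
    """Smooth periodic weight: 1 inside the downstroke, 0 inside the
    upstroke, cosine ramps of width ``w`` (cycle fraction) centered on
    pronation (phi = 0) and supination (phi = d + sup_shift)."""

    def smooth(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * x))

    c2 = d + sup_shift
    half = w / 2.0
    if not half < c2 - half or not c2 + half < 1.0 - half:
        raise ValueError("transition ramps overlap; reduce width or shift")
    phi = np.mod(phi, 1.0)
    dist0 = np.mod(phi + 0.5, 1.0) - 0.5          # signed distance to pronation
    dist_s = phi - c2                              # distance to supination
    return np.select(
        [np.abs(dist0) <= half, np.abs(dist_s) <= half, (phi > half) & (phi < c2)],
        [smooth((dist0 + half) / w), 1.0 - smooth((dist_s + half) / w), 1.0],
        default=0.0,
    )


def _solve_interior_values(
    d: float, w: float, mean_ds: float, mean_us: float
) -> tuple[float, float]:
    """Interior (plateau) values such that the stroke-phase *means* of the
    blended profile equal the requested means despite the transition ramps."""
    phi = (np.arange(4000) + 0.5) / 4000.0
    wt = _transition_weight(phi, d, w)
    b_ds = float(np.mean(wt[phi < d]))
    b_us = float(np.mean(wt[phi >= d]))
    A = np.array([[b_ds, 1.0 - b_ds], [b_us, 1.0 - b_us]])
    a_ds, a_us = np.linalg.solve(A, np.array([mean_ds, mean_us]))
    return float(a_ds), float(a_us)


# ---------------------------------------------------------------------------
# landmark trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinematicSimParams:
    """Parameters of one synthetic landmark recording.

    Per-stroke-phase values (``*_ds`` / ``*_us``) are the means over the
    corresponding half-stroke; the generator adjusts the interior plateau of
    its smooth transition profiles so those means are met exactly.  Defaults
    describe a perfectly mirror-symmetric hover; :func:`preset_params` loads
    the per-maneuver study means.
    """

    mode: str = "hover"                     # hover | left | right
    wingbeat_freq: float = 39.0             # Hz (tracking presets use 41)
    downstroke_fraction: float = 0.48
    stroke_amplitude_deg: float = 150.0     # in-plane wingtip sweep
    wba_offset_ds_deg: float = 0.0          # + = left wing elevated
    wba_offset_us_deg: float = 0.0
    chi_xz_ds_deg: float = 66.8             # sagittal body pitch above horizontal
    chi_xz_us_deg: float = 65.4
    chi_yz_ds_deg: float = 0.0              # frontal tilt from vertical, + = left
    chi_yz_us_deg: float = 0.0
    alpha_ds_deg: float = 40.0              # geometric angle of attack, mid-stroke
    alpha_us_deg: float = 40.0
    supination_shift: tuple[float, float] = (0.0, 0.0)  # (left, right), cycle fraction
    travel_angle_deg: Optional[float] = None  # psi; None for hover
    feeder_speed_m_s: float = 0.0
    bill_insertion_pct: float = 19.8
    elevation_amp_deg: float = 10.0         # wingtip dips/rises about the stroke plane
    transition_width: float = 0.12          # ramp width, cycle fraction
    noise_sd_m: float = 0.0003              # digitization noise
    n_wingbeats: int = 8
    seed: int = 0
    # morphometrics (m)
    wing_length_m: float = 0.0525
    body_length_m: float = 0.055
    shoulder_width_m: float = 0.018
    shoulder_drop_m: float = 0.012
    p5_span_fraction: float = 0.62
    chord_length_m: float = 0.0129
    culmen_length_m: float = 0.020

    def __post_init__(self) -> None:
        if self.mode not in ("hover", "left", "right"):
            raise ValueError("mode must be hover, left or right")
        if not 0.0 < self.downstroke_fraction < 1.0:
            raise ValueError("downstroke_fraction must be in (0, 1)")
        if self.wingbeat_freq <= 0:
            raise ValueError("wingbeat_freq must be positive")
        if not 0.0 < self.stroke_amplitude_deg <= 180.0:
            raise ValueError("stroke amplitude must be in (0, 180] degrees")
        if abs(self.bill_insertion_pct) > 100.0:
            raise ValueError("bill insertion must be within +/-100%")
        if self.n_wingbeats < 1:
            raise ValueError("n_wingbeats must be >= 1")


#: Per-maneuver mean asymmetries observed in the study (left lateral
#: tracking, hovering, right lateral tracking).
_PRESETS = {
    "hover": dict(
        mode="hover",
        wingbeat_freq=39.0,
        wba_offset_ds_deg=0.0,
        wba_offset_us_deg=-0.6,
        chi_xz_ds_deg=66.8,
        chi_xz_us_deg=65.4,
        chi_yz_ds_deg=0.2,
        chi_yz_us_deg=0.2,
        travel_angle_deg=None,
        feeder_speed_m_s=0.0,
        bill_insertion_pct=19.8,
        supination_shift=(0.0, 0.0),
    ),
    "left": dict(
        mode="left",
        wingbeat_freq=41.0,
        wba_offset_ds_deg=4.0,
        wba_offset_us_deg=7.9,
        chi_xz_ds_deg=59.1,
        chi_xz_us_deg=57.6,
        chi_yz_ds_deg=3.5,
        chi_yz_us_deg=2.6,
        travel_angle_deg=21.9,
        feeder_speed_m_s=0.15,
        bill_insertion_pct=24.8,
        supination_shift=(0.04, -0.04),   # leading (left) wing rotation delayed
    ),
    "right": dict(
        mode="right",
        wingbeat_freq=41.0,
        wba_offset_ds_deg=-2.6,
        wba_offset_us_deg=-7.4,
        chi_xz_ds_deg=56.5,
        chi_xz_us_deg=54.5,
        chi_yz_ds_deg=-1.8,
        chi_yz_us_deg=-1.3,
        travel_angle_deg=-10.3,
        feeder_speed_m_s=0.15,
        bill_insertion_pct=27.7,
        supination_shift=(-0.04, 0.04),   # leading (right) wing rotation delayed
    ),
}


def preset_params(mode: str, **overrides) -> KinematicSimParams:
    """Study-condition parameter sets for hovering and left/right tracking."""
    if mode not in _PRESETS:
        raise KeyError(f"unknown preset {mode!r}")
    kw = dict(_PRESETS[mode])
    kw.update(overrides)
    return KinematicSimParams(**kw)


def mirror_params(p: KinematicSimParams) -> KinematicSimParams:
    """Reflect a parameter set through the sagittal plane.

    Swaps left/right travel, negates the laterally signed angles, and swaps
    the per-wing rotation-timing shifts.  Mirroring a hover returns an
    equivalent hover with negated lateral asymmetries.
    """
    mode = {"left": "right", "right": "left", "hover": "hover"}[p.mode]
    return replace(
        p,
        mode=mode,
        wba_offset_ds_deg=-p.wba_offset_ds_deg,
        wba_offset_us_deg=-p.wba_offset_us_deg,
        chi_yz_ds_deg=-p.chi_yz_ds_deg,
        chi_yz_us_deg=-p.chi_yz_us_deg,
        travel_angle_deg=None if p.travel_angle_deg is None else p.travel_angle_deg,
        supination_shift=(p.supination_shift[1], p.supination_shift[0]),
    )


def _yaw_frame(p: KinematicSimParams) -> tuple[float, np.ndarray, np.ndarray, int]:
    """Lab-frame yaw angle (rad), forward/left unit vectors and travel sign."""
    psi = p.travel_angle_deg or 0.0
    if p.mode == "left":
        sign, yaw = 1, math.radians(psi)
    elif p.mode == "right":
        sign, yaw = -1, -math.radians(psi)
    else:
        sign, yaw = 0, 0.0
    f_hat = np.array([math.cos(yaw), math.sin(yaw), 0.0])
    l_hat = np.array([-math.sin(yaw), math.cos(yaw), 0.0])
    return yaw, f_hat, l_hat, sign


def _cycle_waveforms(phi: np.ndarray, p: KinematicSimParams) -> dict[str, np.ndarray]:
    """Evaluate the continuous per-phase waveforms underlying the generator.

    Returns excursion, per-wing elevation, per-wing geometric alpha and
    per-wing chord flip (+1 downstroke orientation, -1 upstroke) at the
    cycle phases ``phi`` (cycle fraction, pronation at 0).
    """
    d, w = p.downstroke_fraction, p.transition_width
    phi = np.mod(np.asarray(phi, dtype=float), 1.0)
    in_ds = phi < d
    u_ds = phi / d
    u_us = (phi - d) / (1.0 - d)

    half = p.stroke_amplitude_deg / 2.0
    zeta = np.where(in_ds, -half * np.cos(np.pi * u_ds), half * np.cos(np.pi * u_us))
    e_osc = p.elevation_amp_deg * np.where(in_ds, -np.sin(np.pi * u_ds), np.sin(np.pi * u_us))

    wba_i = _solve_interior_values(d, w, p.wba_offset_ds_deg, p.wba_offset_us_deg)
    wt = _transition_weight(phi, d, w)
    wba = wba_i[1] + (wba_i[0] - wba_i[1]) * wt

    out = {
        "zeta": zeta,
        "elev_left": wba + e_osc,
        "elev_right": -wba + e_osc,
        "wba": wba,
    }
    for wing, shift in (("left", p.supination_shift[0]), ("right", p.supination_shift[1])):
        wt_w = _transition_weight(phi, d, w, sup_shift=shift)
        out[f"alpha_{wing}"] = p.alpha_us_deg + (p.alpha_ds_deg - p.alpha_us_deg) * wt_w
        out[f"flip_{wing}"] = 2.0 * wt_w - 1.0
    return out


def _body_frame(phi: np.ndarray, p: KinematicSimParams) -> dict[str, np.ndarray]:
    """Per-phase body orientation vectors in the lab frame."""
    d, w = p.downstroke_fraction, p.transition_width
    yaw, f_hat, l_hat, _ = _yaw_frame(p)
    wt = _transition_weight(phi, d, w)

    xz_i = _solve_interior_values(d, w, p.chi_xz_ds_deg, p.chi_xz_us_deg)
    chi_xz = np.radians(xz_i[1] + (xz_i[0] - xz_i[1]) * wt)
    yz_i = _solve_interior_values(d, w, p.chi_yz_ds_deg, p.chi_yz_us_deg)
    chi_yz = np.radians(yz_i[1] + (yz_i[0] - yz_i[1]) * wt)
    # The frontal tilt is a gravitational roll about the forward horizontal
    # axis (rolling about the steeply pitched body axis would mostly yaw the
    # bird); with rho = -chi_yz the dorsoventral axis projects into the
    # frontal plane at exactly chi_yz from vertical, positive toward left.
    rho = -chi_yz

    cx, sx = np.cos(chi_xz)[:, None], np.sin(chi_xz)[:, None]
    cr, sr = np.cos(rho)[:, None], np.sin(rho)[:, None]
    u_body = cx * f_hat + cr * sx * Z_HAT - sr * sx * l_hat
    l_vec = cr * l_hat + sr * Z_HAT
    d_vec = -sx * f_hat + cr * cx * Z_HAT - sr * cx * l_hat
    return {"u_body": u_body, "l_vec": l_vec, "d_vec": d_vec, "f_hat": f_hat, "l_hat": l_hat}


def generate_landmark_trajectories(params: KinematicSimParams) -> LandmarkSet:
    """Simulate 3D landmark trajectories at 1,000 frames/s.

    The wingtip sweeps a near-horizontal stroke plane with an asymmetric
    half-period sinusoid (downstroke:upstroke split per
    ``downstroke_fraction``), the wings carry the requested per-phase bank
    asymmetry, the body axis follows the per-phase pitch/roll angles, the
    head translates with the feeder in tracking modes, and all landmarks
    receive i.i.d. Gaussian positional noise.
    """
    p = params
    fs = 1000.0
    n = int(round(p.n_wingbeats / p.wingbeat_freq * fs)) + 1
    t = np.arange(n) / fs
    phi = np.mod(p.wingbeat_freq * t, 1.0)

    yaw, f_hat, l_hat, travel_sign = _yaw_frame(p)
    wav = _cycle_waveforms(phi, p)
    body = _body_frame(phi, p)

    head = np.zeros((n, 3))
    head[:, 1] = travel_sign * p.feeder_speed_m_s * t
    tail = head - p.body_length_m * body["u_body"]
    sh_center = head - p.shoulder_drop_m * body["u_body"]
    l_sh = sh_center + 0.5 * p.shoulder_width_m * body["l_vec"]
    r_sh = sh_center - 0.5 * p.shoulder_width_m * body["l_vec"]

    positions = {"head": head, "tail": tail, "l_shoulder": l_sh, "r_shoulder": r_sh}
    for wing, side, sh in (("left", 1, l_sh), ("right", -1, r_sh)):
        span = wing_direction(wav["zeta"], wav[f"elev_{wing}"], side, f_hat, l_hat)
        tip = sh + p.wing_length_m * span
        chord = chord_direction(span, f_hat, wav[f"alpha_{wing}"], wav[f"flip_{wing}"])
        p5 = sh + p.p5_span_fraction * p.wing_length_m * span + p.chord_length_m * chord
        positions[f"{wing[0]}_wingtip"] = tip
        positions[f"{wing[0]}_p5"] = p5

    if p.noise_sd_m > 0:
        rng = np.random.default_rng(p.seed)
        for name in positions:
            positions[name] = positions[name] + rng.normal(0.0, p.noise_sd_m, size=(n, 3))

    # Feeder mouth plane: normal +x (into the feeder), positioned so the
    # requested fraction of the culmen sits inside the feeder.
    mouth_x = p.culmen_length_m * math.cos(yaw) * (1.0 - p.bill_insertion_pct / 100.0)
    meta = {
        "mode": p.mode,
        "feeder_speed_m_s": p.feeder_speed_m_s,
        "feeder_mouth_point": [mouth_x, 0.0, 0.0],
        "feeder_mouth_normal": [1.0, 0.0, 0.0],
        "feeder_tracks_bird": True,
        "culmen_length_m": p.culmen_length_m,
        "wingbeat_freq_hz": p.wingbeat_freq,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(p).items()},
    }
    return LandmarkSet(time=t, positions=positions, sample_rate=fs, meta=meta)


def synthetic_wingbeat_cycle(params: KinematicSimParams, n_points: int = 200) -> WingbeatCycle:
    """Sample the generator's continuous waveforms into a phase-normalized
    :class:`WingbeatCycle` (noise-free), for direct use by the quasi-steady
    model and for resolution-refinement checks at arbitrary ``n_points``."""
    p = params
    d = p.downstroke_fraction
    nd = int(round(d * n_points))
    phi = np.empty(n_points)
    phi[:nd] = (np.arange(nd) + 0.5) / nd * d
    phi[nd:] = d + (np.arange(n_points - nd) + 0.5) / (n_points - nd) * (1.0 - d)

    wav = _cycle_waveforms(phi, p)
    yaw, _, _, travel_sign = _yaw_frame(p)
    v_lab = np.array([0.0, travel_sign * p.feeder_speed_m_s, 0.0])
    rot = np.array(
        [[math.cos(-yaw), -math.sin(-yaw), 0.0],
         [math.sin(-yaw), math.cos(-yaw), 0.0],
         [0.0, 0.0, 1.0]]
    )
    v_bird = rot @ v_lab

    return WingbeatCycle(
        wingbeat_freq_hz=p.wingbeat_freq,
        excursion_deg={"left": wav["zeta"].copy(), "right": wav["zeta"].copy()},
        elevation_deg={"left": wav["elev_left"], "right": wav["elev_right"]},
        alpha_deg={"left": wav["alpha_left"], "right": wav["alpha_right"]},
        downstroke_fraction=d,
        stroke_amplitude_deg=p.stroke_amplitude_deg,
        v_body=v_bird,
        psi_deg=p.travel_angle_deg,
        travel_direction=None if p.mode == "hover" else p.mode,
    )
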