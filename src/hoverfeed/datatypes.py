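"""Shared in-memory containers for recordings and derived cycles.

Three containers move between modules:

* :class:`StrainTrace` -- two-channel feeder strain-voltage time series with
  docking event marks (the instrumented-feeder experiment).
* :class:`LandmarkSet` -- 3D trajectories of eight digitized anatomical
  landmarks (the moving-feeder kinematics experiment).
* :class:`WingbeatCycle` -- one phase-normalized average wingbeat, the input
  to the quasi-steady aerodynamic model.

All containers round-trip losslessly through plain-text formats (CSV plus a
JSON side-car for event marks / metadata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["LANDMARK_NAMES", "StrainTrace", "LandmarkSet", "WingbeatCycle"]

#: Canonical landmark order: top of head, tip of middle tail feather, the two
#: shoulders, the two wingtips, and the tips of the two 5th primaries.
LANDMARK_NAMES = (
    "head",
    "tail",
    "l_shoulder",
    "r_shoulder",
    "l_wingtip",
    "r_wingtip",
    "l_p5",
    "r_p5",
)


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class StrainTrace:
    """Two-channel strain-voltage recording with dock/undock event marks.

    Parameters
    ----------
    time
        Sample times in seconds, uniformly spaced.
    horizontal, vertical
        Amplified bridge voltages for the two axes.
    dock_events
        ``[start, end]`` times (s) during which the bird was docked;
        non-overlapping and time-ordered, strictly inside the record.
    sample_rate
        Samples per second (1000 Hz in the rig).
    """

    time: np.ndarray
    horizontal: np.ndarray
    vertical: np.ndarray
    dock_events: list[tuple[float, float]]
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time)
        self.horizontal = _as_float_array(self.horizontal)
        self.vertical = _as_float_array(self.vertical)
        if not (len(self.time) == len(self.horizontal) == len(self.vertical)):
            raise ValueError("channel lengths differ")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")
        self.dock_events = [(float(a), float(b)) for a, b in self.dock_events]
        t0, t1 = float(self.time[0]), float(self.time[-1])
        prev_end = t0
        for a, b in self.dock_events:
            if not (t0 < a < b < t1):
                raise ValueError(f"dock event ({a}, {b}) outside recording span")
            if a < prev_end:
                raise ValueError("dock events must be non-overlapping and ordered")
            prev_end = b

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel(self, axis: str) -> np.ndarray:
        if axis not in ("horizontal", "vertical"):
            raise KeyError(axis)
        return getattr(self, axis)

    def mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of samples with ``start <= t < end``."""
        return (self.time >= start) & (self.time < end)

    def replace_channels(self, horizontal: np.ndarray, vertical: np.ndarray) -> "StrainTrace":
        return StrainTrace(
            time=self.time.copy(),
            horizontal=horizontal,
            vertical=vertical,
            dock_events=list(self.dock_events),
            sample_rate=self.sample_rate,
        )

    # -- plain-text I/O ----------------------------------------------------
    def to_csv(self, path: str | Path, events_path: str | Path | None = None) -> None:
        """Write the trace as CSV (time_s, horizontal_V, vertical_V, event)
        with dock events additionally in a JSON side-car."""
        path = Path(path)
        event = np.zeros(len(self.time), dtype=int)
        for a, b in self.dock_events:
            event |= self.mask(a, b).astype(int)
        pd.DataFrame(
            {
                "time_s": self.time,
                "horizontal_V": self.horizontal,
                "vertical_V": self.vertical,
                "event": event,
            }
        ).to_csv(path, index=False)
        ev = Path(events_path) if events_path else path.with_suffix(".events.json")
        ev.write_text(json.dumps({"docks": [list(d) for d in self.dock_events]}))

    @classmethod
    def from_csv(cls, path: str | Path, events_path: str | Path | None = None) -> "StrainTrace":
        path = Path(path)
        df = pd.read_csv(path)
        ev = Path(events_path) if events_path else path.with_suffix(".events.json")
        docks = json.loads(ev.read_text())["docks"]
        t = df["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1000.0
        return cls(
            time=t,
            horizontal=df["horizontal_V"].to_numpy(),
            vertical=df["vertical_V"].to_numpy(),
            dock_events=[tuple(d) for d in docks],
            sample_rate=rate,
        )


@dataclass
class LandmarkSet:
    """Time-indexed 3D positions (m) of the eight anatomical landmarks.

    Axes are gravitational: x forward (feeder long axis), y lateral
    (positive toward the bird's left when facing +x), z vertical up.

    ``meta`` carries recording context the landmarks alone cannot supply:
    flight mode, feeder mouth-plane geometry, exposed culmen length, and the
    feeder translation speed.
    """

    time: np.ndarray
    positions: dict[str, np.ndarray]  # name -> (n, 3)
    sample_rate: float = 1000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time)
        n = len(self.time)
        for name in LANDMARK_NAMES:
            if name not in self.positions:
                raise ValueError(f"missing landmark {name!r}")
            arr = _as_float_array(self.positions[name])
            if arr.shape != (n, 3):
                raise ValueError(f"landmark {name!r} has shape {arr.shape}, expected ({n}, 3)")
            self.positions[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def copy_with(self, positions: dict[str, np.ndarray]) -> "LandmarkSet":
        return LandmarkSet(
            time=self.time.copy(),
            positions=positions,
            sample_rate=self.sample_rate,
            meta=dict(self.meta),
        )

    # -- plain-text I/O ----------------------------------------------------
    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Tidy CSV: time_s, landmark, x_m, y_m, z_m; metadata JSON side-car."""
        path = Path(path)
        rows = []
        for name in LANDMARK_NAMES:
            arr = self.positions[name]
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "landmark": name,
                        "x_m": arr[:, 0],
                        "y_m": arr[:, 1],
                        "z_m": arr[:, 2],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        mp = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        mp.write_text(json.dumps(self.meta, default=float))

    @classmethod
    def from_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "LandmarkSet":
        path = Path(path)
        df = pd.read_csv(path)
        mp = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        meta = json.loads(mp.read_text()) if mp.exists() else {}
        positions = {}
        t_ref = None
        for name, sub in df.groupby("landmark", sort=False):
            sub = sub.sort_values("time_s")
            positions[name] = sub[["x_m", "y_m", "z_m"]].to_numpy()
            t_ref = sub["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t_ref))) if len(t_ref) > 1 else 1000.0
        return cls(time=t_ref, positions=positions, sample_rate=rate, meta=meta)


@dataclass
class WingbeatCycle:
    """Phase-normalized average wingbeat for both wings.

    ``n_points`` phase samples span one period; the first
    ``round(downstroke_fraction * n_points)`` are downstroke.  With the
    standard 48:52 split and 200 points the samples are equally spaced in
    time.  Angles are degrees; the stroke plane is taken horizontal with
    excursion measured from straight-lateral toward the bird's front.
    """

    wingbeat_freq_hz: float
    excursion_deg: dict[str, np.ndarray]   # "left"/"right" -> (n,)
    elevation_deg: dict[str, np.ndarray]
    alpha_deg: dict[str, np.ndarray]       # geometric angle of attack
    downstroke_fraction: float = 0.48
    stroke_amplitude_deg: Optional[float] = None
    v_body: np.ndarray = field(default_factory=lambda: np.zeros(3))  # bird frame, m/s
    psi_deg: Optional[float] = None        # travel angle; None for hovering
    travel_direction: Optional[str] = None  # "left" | "right" | None

    def __post_init__(self) -> None:
        self.v_body = _as_float_array(self.v_body)
        n = None
        for d in (self.excursion_deg, self.elevation_deg, self.alpha_deg):
            for wing in ("left", "right"):
                if wing not in d:
                    raise ValueError(f"missing wing {wing!r}")
                d[wing] = _as_float_array(d[wing])
                if n is None:
                    n = len(d[wing])
                elif len(d[wing]) != n:
                    raise ValueError("all cycle arrays must share one length")
        if not 0.0 < self.downstroke_fraction < 1.0:
            raise ValueError("downstroke_fraction must be in (0, 1)")
        if self.wingbeat_freq_hz <= 0:
            raise ValueError("wingbeat frequency must be positive")

    @property
    def n_points(self) -> int:
        return len(self.excursion_deg["left"])

    @property
    def n_down(self) -> int:
        return int(round(self.downstroke_fraction * self.n_points))

    @property
    def period_s(self) -> float:
        return 1.0 / self.wingbeat_freq_hz

    def times(self) -> np.ndarray:
        """Sample times (s) of the phase points within one period.

        Points sit at phase-cell midpoints so the stroke transitions fall on
        cell boundaries (second-order accurate cycle averages).
        """
        n, nd = self.n_points, self.n_down
        T, d = self.period_s, self.downstroke_fraction
        t = np.empty(n)
        t[:nd] = (np.arange(nd) + 0.5) / nd * d * T
        t[nd:] = d * T + (np.arange(n - nd) + 0.5) / (n - nd) * (1.0 - d) * T
        return t

    def phase_is_down(self) -> np.ndarray:
        out = np.zeros(self.n_points, dtype=bool)
        out[: self.n_down] = True
        return out

    # -- plain-text I/O ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "wingbeat_freq_hz": self.wingbeat_freq_hz,
            "downstroke_fraction": self.downstroke_fraction,
            "stroke_amplitude_deg": self.stroke_amplitude_deg,
            "v_body": self.v_body.tolist(),
            "psi_deg": self.psi_deg,
            "travel_direction": self.travel_direction,
            "excursion_deg": {k: v.tolist() for k, v in self.excursion_deg.items()},
            "elevation_deg": {k: v.tolist() for k, v in self.elevation_deg.items()},
            "alpha_deg": {k: v.tolist() for k, v in self.alpha_deg.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "WingbeatCycle":
        d = json.loads(Path(path).read_text())
        return cls(
            wingbeat_freq_hz=d["wingbeat_freq_hz"],
            excursion_deg={k: np.array(v) for k, v in d["excursion_deg"].items()},
            elevation_deg={k: np.array(v) for k, v in d["elevation_deg"].items()},
            alpha_deg={k: np.array(v) for k, v in d["alpha_deg"].items()},
            downstroke_fraction=d["downstroke_fraction"],
            stroke_amplitude_deg=d.get("stroke_amplitude_deg"),
            v_body=np.array(d.get("v_body", [0, 0, 0])),
            psi_deg=d.get("psi_deg"),
            travel_direction=d.get("travel_direction"),
        )
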