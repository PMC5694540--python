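"""Quasi-steady blade-element aerodynamic force model for hovering flight.

The wing is treated as a single blade element at the radius of gyration
``R_gyr = r2 * L`` carrying the full wing area ``S``.  At each of the
``n_points`` phase samples of a :class:`~hoverfeed.datatypes.WingbeatCycle`
the model computes, per wing:

* the incident velocity ``V_incident = -V_wing - V_induced*z - V_body``
  (air velocity relative to the wing: the wing's own motion and the body
  translation enter reversed, the induced downwash points down),
* the aerodynamic angle of attack between the wing plane and
  ``V_incident``,
* empirical lift/drag coefficients (sinusoidal fits measured on spinning
  Anna's hummingbird wings, separate curves for down- and upstroke),
* lift ``|L| = 1/2 C_L rho S |V_incident|^2`` perpendicular to the flow
  (direction: leading-edge x incident velocity, oriented upward) and drag
  along the flow.

Induced velocity uses the Rankine-Froude actuator-disk estimate for
hovering, held constant through the cycle.  Forces are reported in body
weights (fractions of ``M g``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from ._geom import Z_HAT, chord_direction, plane_normal, unit, wing_direction
from .datatypes import WingbeatCycle

__all__ = [
    "WingMorphology",
    "AeroCoefficients",
    "ForceTimeSeries",
    "radius_of_gyration",
    "actuator_disk_area",
    "induced_velocity",
    "lift_drag_coefficients",
    "incident_velocity",
    "instantaneous_forces",
    "net_forces",
]

_WINGS = ("left", "right")


@dataclass(frozen=True)
class WingMorphology:
    """Morphological and environmental constants (species means).

    Defaults: wing area 6.78e-4 m^2, wing length 0.0525 m, non-dimensional
    second-moment radius 0.499, body mass 4.68 g, air density 1.18 kg/m^3.
    """

    wing_area_m2: float = 6.78e-4
    wing_length_m: float = 0.0525
    r2: float = 0.499
    body_mass_kg: float = 0.00468
    air_density: float = 1.18
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r2 > 1.0:
            raise ValueError("r2 must be <= 1")

    @property
    def radius_of_gyration_m(self) -> float:
        return radius_of_gyration(self.r2, self.wing_length_m)

    @property
    def weight_N(self) -> float:
        return self.body_mass_kg * self.gravity

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "WingMorphology":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# Coefficient curve: offset + amplitude * cos(freq_per_deg * (alpha - alpha_shift)
#                                             + phase_rad)
# The per-degree frequency constants multiply alpha in degrees; the phase
# offsets are radians and the cosine is evaluated in radians (mixed-unit
# convention of the published fits).
_Curve = tuple[float, float, float, float, float]


@dataclass(frozen=True)
class AeroCoefficients:
    """Empirical lift/drag coefficient curves for Anna's hummingbird wings.

    Each curve is (offset, amplitude, freq_per_deg, phase_rad,
    alpha_shift_deg); the upstroke curves are parameterized in
    ``alpha - 180`` per their published sign convention.
    """

    cl_down: _Curve = (0.0031, 1.5842, 0.0301, 4.7124, 0.0)
    cd_down: _Curve = (8.3171, 8.1909, 0.0073, 3.1416, 0.0)
    cl_up: _Curve = (0.0028, 1.1251, 0.0332, 4.6963, 180.0)
    cd_up: _Curve = (1.1993, 1.0938, 0.0281, 3.1277, 180.0)

    def __post_init__(self) -> None:
        for name in ("cl_down", "cd_down", "cl_up", "cd_up"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} amplitude must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in asdict(self).items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "AeroCoefficients":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**{k: tuple(v) for k, v in d.items()})


def radius_of_gyration(r2: float, wing_length_m: float) -> float:
    """Spanwise station ``r2 * L`` at which wing velocity is evaluated."""
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must be in (0, 1]")
    if wing_length_m <= 0:
        raise ValueError("wing length must be positive")
    return r2 * wing_length_m


def actuator_disk_area(phi_sp_deg: float, wing_length_m: float) -> float:
    """Area swept by the actuator disk: ``(phi_sp / 180) * pi * L^2``."""
    if not 0.0 < phi_sp_deg <= 360.0:
        raise ValueError("stroke amplitude must be in (0, 360] degrees")
    if wing_length_m <= 0:
        raise ValueError("wing length must be positive")
    return (phi_sp_deg / 180.0) * math.pi * wing_length_m**2


def induced_velocity(
    body_mass_kg: float, gravity: float, air_density: float, disk_area_m2: float
) -> float:
    """Rankine-Froude hovering induced velocity ``sqrt(M g / (2 rho A))``,
    applied as a uniform downward air velocity through the stroke plane."""
    if min(body_mass_kg, gravity, air_density, disk_area_m2) <= 0:
        raise ValueError("all arguments must be positive")
    return math.sqrt(body_mass_kg * gravity / (2.0 * air_density * disk_area_m2))


def _eval_curve(curve: _Curve, alpha_deg: np.ndarray) -> np.ndarray:
    offset, amp, freq, phase, shift = curve
    return offset + amp * np.cos(freq * (np.asarray(alpha_deg, dtype=float) - shift) + phase)


def lift_drag_coefficients(
    alpha_aero_deg: np.ndarray | float,
    stroke_phase: str,
    coefficients: AeroCoefficients | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lift and drag coefficients at aerodynamic angle of attack (deg).

    ``stroke_phase`` selects the downstroke or upstroke curve pair.  The
    curves are periodic; angles outside the fitted range extrapolate along
    the cosine.
    """
    c = coefficients or AeroCoefficients()
    if stroke_phase == "down":
        return _eval_curve(c.cl_down, alpha_aero_deg), _eval_curve(c.cd_down, alpha_aero_deg)
    if stroke_phase == "up":
        return _eval_curve(c.cl_up, alpha_aero_deg), _eval_curve(c.cd_up, alpha_aero_deg)
    raise ValueError("stroke_phase must be 'down' or 'up'")


def incident_velocity(
    wing_velocity: np.ndarray, v_induced: float, v_body: np.ndarray
) -> np.ndarray:
    """Air velocity relative to the blade element.

    The wing's own motion and the body translation enter reversed (the air
    streams past the moving wing); the induced velocity is a downward
    vector of magnitude ``v_induced``.
    """
    wing_velocity = np.asarray(wing_velocity, dtype=float)
    return -wing_velocity - v_induced * Z_HAT - np.asarray(v_body, dtype=float)


@dataclass
class ForceTimeSeries:
    """Instantaneous per-wing and net forces over one wingbeat (body weights).

    ``lift``/``drag``/``total`` map wing name to an (n, 3) array in the
    bird-centered frame (x forward, y left, z up); ``net`` sums the wings.
    ``weights`` are the phase-sample durations used for cycle averages.
    """

    times_s: np.ndarray
    weights: np.ndarray
    lift: dict[str, np.ndarray]
    drag: dict[str, np.ndarray]
    total: dict[str, np.ndarray] = field(default=None)
    net: np.ndarray = field(default=None)
    alpha_aero_deg: dict[str, np.ndarray] = field(default_factory=dict)
    v_incident: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate: dict[str, np.ndarray] = field(default_factory=dict)
    psi_deg: Optional[float] = None
    travel_direction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.total is None:
            self.total = {w: self.lift[w] + self.drag[w] for w in self.lift}
        if self.net is None:
            self.net = sum(self.total.values())

    def cycle_average(self, values: np.ndarray | None = None) -> np.ndarray:
        """Duration-weighted mean over the wingbeat (defaults to net force)."""
        v = self.net if values is None else values
        w = self.weights / self.weights.sum()
        return np.tensordot(w, v, axes=(0, 0))


def _phase_velocity(pos: np.ndarray, t: np.ndarray, period: float) -> np.ndarray:
    """Central-difference velocity on the periodic phase grid."""
    p_prev = np.roll(pos, 1, axis=0)
    p_next = np.roll(pos, -1, axis=0)
    t_prev = np.roll(t, 1)
    t_prev[0] -= period
    t_next = np.roll(t, -1)
    t_next[-1] += period
    return (p_next - p_prev) / (t_next - t_prev)[:, None]


def instantaneous_forces(
    cycle: WingbeatCycle,
    morphology: WingMorphology | None = None,
    coefficients: AeroCoefficients | None = None,
) -> ForceTimeSeries:
    """Evaluate the blade-element model over one phase-normalized wingbeat.

    Phase points where the incident velocity vanishes produce zero force and
    are flagged in ``degenerate``.
    """
    morph = morphology or WingMorphology()
    coef = coefficients or AeroCoefficients()
    n, nd = cycle.n_points, cycle.n_down
    t = cycle.times()
    period = cycle.period_s
    t_next = np.roll(t, -1)
    t_next[-1] += period
    weights = t_next - t

    phi_sp = cycle.stroke_amplitude_deg
    if phi_sp is None:
        phi_sp = float(
            np.mean([np.ptp(cycle.excursion_deg[w]) for w in _WINGS])
        )
    v_ind = induced_velocity(
        morph.body_mass_kg,
        morph.gravity,
        morph.air_density,
        actuator_disk_area(phi_sp, morph.wing_length_m),
    )

    f_hat = np.array([1.0, 0.0, 0.0])
    l_hat = np.array([0.0, 1.0, 0.0])
    r_gyr = morph.radius_of_gyration_m
    q_scale = 0.5 * morph.air_density * morph.wing_area_m2 / morph.weight_N
    is_down = cycle.phase_is_down()
    flip = np.where(is_down, 1.0, -1.0)

    lift, drag, alpha_aero, v_inc_all, degen = {}, {}, {}, {}, {}
    for wing, side in (("left", 1), ("right", -1)):
        span = wing_direction(
            cycle.excursion_deg[wing], cycle.elevation_deg[wing], side, f_hat, l_hat
        )
        pos = r_gyr * span
        v_wing = _phase_velocity(pos, t, period)
        v_inc = incident_velocity(v_wing, v_ind, cycle.v_body)
        speed = np.linalg.norm(v_inc, axis=1)
        bad = speed < 1e-12
        v_hat = unit(v_inc)

        chord = chord_direction(span, f_hat, cycle.alpha_deg[wing], flip)
        normal = plane_normal(span, chord)
        beta = np.degrees(np.arcsin(np.clip(np.abs(np.sum(normal * v_hat, axis=1)), 0, 1)))

        cl = np.empty(n)
        cd = np.empty(n)
        cl[is_down], cd[is_down] = lift_drag_coefficients(beta[is_down], "down", coef)
        cl[~is_down], cd[~is_down] = lift_drag_coefficients(beta[~is_down], "up", coef)

        q = q_scale * speed**2  # dynamic pressure * S / (M g)
        lift_dir = unit(np.cross(span, v_inc))
        sign = np.where(lift_dir[:, 2:3] < 0.0, -1.0, 1.0)
        lift_dir = lift_dir * sign
        L = (q * cl)[:, None] * lift_dir
        D = (q * cd)[:, None] * v_hat
        L[bad] = 0.0
        D[bad] = 0.0

        lift[wing], drag[wing] = L, D
        alpha_aero[wing] = beta
        v_inc_all[wing] = v_inc
        degen[wing] = bad

    return ForceTimeSeries(
        times_s=t,
        weights=weights,
        lift=lift,
        drag=drag,
        alpha_aero_deg=alpha_aero,
        v_incident=v_inc_all,
        degenerate=degen,
        psi_deg=cycle.psi_deg,
        travel_direction=cycle.travel_direction,
    )


def net_forces(
    series: ForceTimeSeries,
    psi_deg: Optional[float] = None,
    travel_direction: Optional[str] = None,
) -> dict:
    """Cycle-averaged forces (body weights) in the bird-centered frame.

    Returns vertical (z), forward (x) and lateral (y, positive = bird's
    left) components, plus -- when a travel direction and travel angle psi
    are available -- the projection of the mean horizontal force onto the
    direction of travel (positive = along travel).
    """
    psi = psi_deg if psi_deg is not None else series.psi_deg
    direction = travel_direction or series.travel_direction
    mean = series.cycle_average()
    out = {
        "vertical_wb": float(mean[2]),
        "forward_wb": float(mean[0]),
        "lateral_wb": float(mean[1]),
        "travel_wb": None,
    }
    if direction in ("left", "right") and psi is not None:
        yaw = math.radians(psi if direction == "left" else -psi)
        t_lab = np.array([0.0, 1.0, 0.0]) if direction == "left" else np.array([0.0, -1.0, 0.0])
        rot = np.array(
            [[math.cos(yaw), math.sin(yaw), 0.0],
             [-math.sin(yaw), math.cos(yaw), 0.0],
             [0.0, 0.0, 1.0]]
        )
        t_bird = rot @ t_lab
        out["travel_wb"] = float(mean @ t_bird)
    return out
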