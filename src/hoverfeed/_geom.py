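"""Small vector-geometry helpers shared by the generator and the aero model.

The wing is represented by a span direction (shoulder to wingtip) plus a
chord direction; together they define the wing plane.  The chord convention
is shared between the synthetic-trajectory generator (which places the 5th
primary landmark) and the quasi-steady model (which reconstructs the plane
from the stored geometric angle of attack), so the two stay consistent.
"""

from __future__ import annotations

import numpy as np

Z_HAT = np.array([0.0, 0.0, 1.0])


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize along ``axis``; zero vectors are returned unchanged."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    n = np.where(n == 0.0, 1.0, n)
    return v / n


def wing_direction(
    zeta_deg: np.ndarray,
    elev_deg: np.ndarray,
    side: int,
    f_hat: np.ndarray,
    l_hat: np.ndarray,
) -> np.ndarray:
    """Unit span direction from stroke-plane excursion and elevation.

    ``zeta_deg`` is the in-plane excursion measured from straight-lateral
    toward the bird's front; ``elev_deg`` the elevation above horizontal.
    ``side`` is +1 for the left wing, -1 for the right.  ``f_hat``/``l_hat``
    are the horizontal forward and bird-left unit vectors (arrays broadcast).
    """
    z = np.radians(np.asarray(zeta_deg, dtype=float))[..., None]
    e = np.radians(np.asarray(elev_deg, dtype=float))[..., None]
    lateral = side * np.asarray(l_hat, dtype=float)
    return np.cos(e) * (np.cos(z) * lateral + np.sin(z) * f_hat) + np.sin(e) * Z_HAT


def chord_direction(
    span: np.ndarray,
    f_hat: np.ndarray,
    alpha_deg: np.ndarray,
    flip: np.ndarray,
) -> np.ndarray:
    """Unit chord direction for geometric angle of attack ``alpha_deg``.

    ``flip`` in [-1, 1] orients the chord for the stroke direction: +1 during
    downstroke (leading edge forward and up), -1 during upstroke (the wing is
    supinated), with intermediate values tracing the rotation continuously
    through a vertical chord at stroke reversal.
    """
    span = np.asarray(span, dtype=float)
    f_hat = np.broadcast_to(np.asarray(f_hat, dtype=float), span.shape)
    a = np.radians(np.asarray(alpha_deg, dtype=float))[..., None]
    flip = np.asarray(flip, dtype=float)[..., None]
    f_perp = unit(f_hat - np.sum(f_hat * span, axis=-1, keepdims=True) * span)
    m = -flip * f_perp
    return unit(np.cos(a) * m - np.sin(a) * Z_HAT)


def plane_normal(span: np.ndarray, chord: np.ndarray) -> np.ndarray:
    """Unit wing-plane normal, oriented with a non-negative vertical part."""
    n = unit(np.cross(span, chord))
    sign = np.where(n[..., 2:3] < 0.0, -1.0, 1.0)
    return n * sign


def plane_angle_to_horizontal(normal: np.ndarray) -> np.ndarray:
    """Dihedral angle (deg, in [0, 90]) between a plane and the horizontal."""
    c = np.clip(np.abs(np.asarray(normal)[..., 2]), 0.0, 1.0)
    return np.degrees(np.arccos(c))
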