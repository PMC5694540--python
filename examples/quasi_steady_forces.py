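"""Quasi-steady blade-element forces for the three maneuvers.

Builds phase-normalized average wingbeats (200 points, 48:52
downstroke:upstroke) from the per-maneuver kinematic presets and evaluates
the blade-element model: coefficient curves measured on real wings, incident
velocity from wing motion + Rankine-Froude downwash + body translation.
"""

import hoverfeed as hf
from hoverfeed import aero

morph = aero.WingMorphology()
v_ind = aero.induced_velocity(
    morph.body_mass_kg, morph.gravity, morph.air_density,
    aero.actuator_disk_area(150.0, morph.wing_length_m),
)
print(f"induced velocity (150 deg stroke):  {v_ind:.2f} m/s downward\n")

print(f"{'axis (wb)':22s} {'left':>8s} {'hover':>8s} {'right':>8s}")
out = {}
for mode in ("left", "hover", "right"):
    cycle = hf.synthetic_wingbeat_cycle(hf.preset_params(mode))
    out[mode] = aero.net_forces(aero.instantaneous_forces(cycle))

for label, key in (("vertical (weight supp.)", "vertical_wb"),
                   ("forward thrust", "forward_wb"),
                   ("lateral (+ = left)", "lateral_wb"),
                   ("along travel", "travel_wb")):
    cells = []
    for mode in ("left", "hover", "right"):
        v = out[mode][key]
        cells.append(f"{v:8.3f}" if v is not None else f"{'-':>8s}")
    print(f"{label:22s} {cells[0]} {cells[1]} {cells[2]}")

# The lateral column is the headline: during leftward tracking the net
# lateral force points right (negative), and during rightward tracking it
# points left (positive) -- the bird steers against the feeder's motion, it
# does not fly with it.  Hovering lateral forces from the two wings cancel.
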