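"""Angular geometry of the projected background patterns.

Builds the rig's stimulus specification (0.5 m screen, 1050 px, viewed from
0.25 m) and prints the visual angles a docked bird experiences, plus a short
deterministic dot-field rendering.
"""

from hoverfeed import stimulus

spec = stimulus.StimulusSpec()  # rig dot-field defaults

extent = stimulus.angular_extent(spec.screen_width_m, spec.viewing_distance_m)
print(f"screen extent:            {extent:.1f} deg of the frontal visual field")

sf = stimulus.grating_spatial_frequency(4, extent)
print(f"grating (4 cycles):       {sf:.3f} cycles/deg")

dot = stimulus.pixels_to_degrees(spec.dot_diameter_px, spec.screen_px, extent)
print(f"dot diameter (40 px):     {dot:.1f} deg")

w_exact = stimulus.translation_angular_speed(0.15, spec.viewing_distance_m)
w_linear = stimulus.translation_angular_speed_linear(0.15, spec.screen_width_m, spec.screen_px, extent)
print(f"0.15 m/s feeder motion:   {w_exact:.1f} deg/s (exact) / {w_linear:.1f} deg/s (linear px map)")

frames = stimulus.render_dotfield_frames(
    stimulus.StimulusSpec(motion_direction="left", motion_speed_deg_s=48.0), duration_s=0.5, seed=0
)
print(f"dot-field render:         {frames.shape[0]} frames x {frames.shape[1]} dots (count conserved)")

# The printed angles are what the experiment holds constant: the same screen
# covers ~90 deg whether it shows a grating or a dot-field, so pattern speed
# and direction are the only things that differ between trials.
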