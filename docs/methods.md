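# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `hoverfeed`. It is the package's own account of its
science; every number it mentions is computed by the test suite or by
`scripts/acceptance.py`.

## Coordinate frames and conventions

Gravitational axes throughout: **x** forward along the feeder's long axis,
**y** lateral and positive toward the bird's left when facing +x, **z**
vertical up. Angles are degrees unless noted.

* **Wing elevation** — angle of the shoulder→wingtip vector above
  horizontal.
* **WBA** — (left − right)/2 of the per-phase mean elevations; positive =
  left wing elevated.
* **χ_GR,XZ** — elevation of the tail→head axis above horizontal (sagittal
  body pitch).
* **χ_GR,YZ** — deviation of the dorsoventral axis from vertical in the
  frontal (YZ) plane, positive toward the bird's left. Stored as a
  deviation from vertical (values near 0 for an upright bird): only this
  convention makes RWBA = |WBA + χ_GR,YZ| compose correctly.
* **Ψ** — yaw of the bird relative to facing the feeder dead-on, positive
  when facing the direction of travel; reported as *not applicable* for
  hovering, where travel has no direction.
* **Geometric α** — dihedral angle in [0°, 90°] between the wing plane
  (shoulder, wingtip, 5th-primary tip) and horizontal; 0° = flat wing.

## Strain-signal pipeline

Feeds are the marked dock intervals, cropped by 0.25 s at each end to
discard dock/undock spike transients. The pre-feed window runs from the
start of the record to 0.25 s *before* the first dock, and the post-feed
window from 0.25 s *after* the last dock to the end. The stand-off on the
reference windows is a deliberate extension of the feed crop: undocking
transients decay over tens of milliseconds into the post window and would
otherwise tilt the detrend line and bias the push estimate; with the
stand-off, all summaries are bitwise-invariant to spikes confined within
0.25 s of the transitions (verified in the acceptance suite).

Detrending fits one straight line (OLS, slope + intercept) to the
concatenated pre+post samples per channel and subtracts it everywhere.
Calibration is least squares through the origin, `slope = Σmv / Σm²`, from
2/5/10 g standards. Push is (docked mean − pre mean) / slope / body mass,
with the 4.0 g average body mass of the stationary-feeder birds.

Band power uses a Welch PSD (1 s Hann windows, 50% overlap) integrated by
the trapezoid rule over 10–15 Hz, 35–45 Hz, and 59–61 Hz. The estimator,
window and integral-vs-mean normalization are implementation choices — the
reported quantities are *ratios* (docked/pre) of the same functional, so
they are insensitive to the normalization. The 60 Hz mains reference is
widened to a 2 Hz band for leakage robustness. The amplitude ratio is
docked/pre-dock peak-to-peak, oriented so that a bird shaking the feeder
gives values above one. The vertical channel is processed identically to
the horizontal one and carries a quality flag; distrust of a particular
axis is an acquisition matter, not an algorithmic branch.

## Synthetic data

No recordings are deposited, so the generators define the test conditions.

**Strain traces** (1000 Hz): licking (default 12 Hz, 0.05 V) and wingbeat
(40 Hz, 0.15 V) tones plus a push offset (0.32 g ≈ 0.08 wb by default, the
scale of the observed lateral responses) exist only inside dock intervals;
60 Hz mains (0.02 V), linear drift (2 mV/s) and white noise (10 mV) run
throughout; dock/undock transitions carry exponential spikes (0.5 V,
τ = 30 ms) for the crop to remove. The vertical channel scales the
bill-transmitted tones by 2.5, mirroring the stronger vertical coupling in
the rig. Calibration slopes default to 0.159 (horizontal) and 0.164 V/g.

**Landmark trajectories** (8 landmarks, 1000 frames/s): the wingtip sweeps
a horizontal stroke plane with an asymmetric-half-period sinusoid — 48% of
the cycle pronation→supination, 52% back — at 150° amplitude (a typical
hovering stroke for this species) and 39 Hz (hover) / 41 Hz (tracking).
Elevation superposes a ±10° oscillation (down at mid-downstroke) and the
per-phase wing-bank offset. Per-phase parameters (WBA, χ angles) follow
smooth profiles with cosine transition ramps (width 0.12 cycle); the
plateau values are solved from a 2×2 linear system so the *phase means*
equal the requested values exactly despite the ramps. The frontal tilt is
implemented as a gravitational roll about the forward horizontal axis:
rolling about the steeply pitched body axis would mostly yaw the bird and
contaminate the dividing-line frame, whereas the gravitational roll makes
the measured χ_GR,YZ equal the parameter identically. (The residual
χ_GR,XZ bias from this construction is < 0.3° and inside the 1° recovery
tolerance.) The per-maneuver presets carry the observed mean asymmetries
for left tracking, hovering and right tracking (WBA_DS 4.0 / 0.0 / −2.6,
WBA_US 7.9 / −0.6 / −7.4, χ_YZ,DS 3.5 / 0.2 / −1.8, Ψ 21.9 / — / −10.3,
bill insertion 24.8 / 19.8 / 27.7%, feeder speed 0.15 m/s for tracking),
with the leading wing's rotation delayed and the trailing wing's advanced
by 0.04 cycle at supination. Gaussian positional noise (0.3 mm) emulates
digitization error; it is additive and white, which is all the pipeline's
filters assume.

What the generator does **not** emulate: camera projection and DLT
reconstruction error structure, wing deformation/twist, non-sinusoidal
stroke waveforms, inter-wingbeat variability, and feeder direction
reversals. Passing tests therefore demonstrate correctness of the analysis
chain under the stated signal model, not robustness to every artifact of
real video.

## Kinematic analysis

Filtering: zero-phase low-pass Butterworth (`scipy` fourth-order design run
forward–backward), cutoffs tied to the wingbeat frequency — 2× for the
head, 6× for shoulders and tail, 8× for wingtips and 5th primaries. The
forward–backward pass doubles the effective order and cancels phase lag;
the 200 Hz component of a head trace is attenuated by more than 40 dB at a
39 Hz wingbeat while the passband stays within 5%.

Stroke segmentation fits the stroke plane by total least squares (SVD) to
shoulder-relative wingtip positions, measures the in-plane excursion angle
from the lateral axis (positive toward the bird's front), and takes
pronation/supination as the per-cycle minima/maxima, refined to sub-frame
precision with a three-point parabola (at 1000 frames/s and ~40 Hz there
are only ~25 frames per cycle, so refinement matters for the frequency
estimate). Wingbeat frequency is the reciprocal of the median
inter-pronation interval; ties between equal extrema resolve to the
earliest sample. A global plane per wing is used for detection; per-cycle
quantities (stroke amplitude) come from the refined extremum values.

The transformed frame puts the head at the origin every frame; per
wingbeat, the lateral axis is the horizontal projection of the
**wingtip-path dividing line** — the line joining, for each wing, the
midpoint of its head-centered wingtip positions at pronation and
supination. The construction from both wings' transition midpoints is an
interpretation choice (the defining transitions are not otherwise pinned
down) and is recorded as such. The vertical axis stays gravitational.

Downstroke/upstroke assignment for summaries uses each wing's *detected*
pronation→supination interval; the fixed 48:52 split is applied only when
building the phase-normalized average wingbeat passed to the force model,
matching the model's stated assumption. RWBA is averaged across wingbeats
after the absolute value by default (`mean_of_abs`); the alternative
(`abs_of_mean`) is a configuration switch because the two orders differ
when the signed quantity straddles zero, and either could underlie a
published per-condition mean. Bill insertion models the bill as a straight
segment of the exposed culmen along the head's forward axis (derived from
the shoulder line, which is immune to body roll) and reports the fraction
beyond the feeder mouth plane, clamped to [0, 100]%.

## Quasi-steady model

A single blade element at `R_gyr = r₂ L` (r₂ = 0.499, L = 0.0525 m)
carries the full wing area S = 6.78·10⁻⁴ m²; ρ = 1.18 kg/m³,
M = 4.68 g. The published coefficient sinusoids use a mixed-unit
convention — per-degree frequency constants multiply α in degrees, the
phase offsets (≈3π/2, ≈π) are radians, the cosine is evaluated in
radians — which is the only reading that puts C_L,down(0°) ≈ 0 and the
C_D,down minimum at 0°, as physically required. The upstroke curves are
parameterized in (α − 180) as published; the pipeline feeds them the
angle between the wing plane and the incident flow (in [0°, 90°]) for both
strokes, which places the upstroke lift peak near 38° for the inverted
wing.

Incident velocity composes the air motion relative to the wing: the wing's
own velocity (central differences of the blade-element position on the
periodic phase grid) and the body translation enter reversed; the
Rankine–Froude induced velocity `sqrt(Mg/2ρA_disk)` enters as a constant
downward vector, during upstroke as well as downstroke (the actuator-disk
estimate is a cycle-average quantity; applying it uniformly is an
assumption). `A_disk = (Φ_sp/180)·π·L²` is implemented exactly as
published even though at Φ_sp = 360° it spans two full disks; the intended
per-wing vs whole-disk geometry is not derivable from the definition.

Lift acts along `(shoulder→wingtip) × V_incident`, sign-fixed upward; drag
along `V_incident`. The leading-edge vector is taken as the span direction
(shoulder→wingtip) — a convention, since the published definition names
the leading edge without constructing it. The wing-plane normal is
reconstructed from the geometric α with a chord convention shared with the
landmark generator (leading edge forward-up during downstroke, supinated
during upstroke, rotating through vertical at the reversals), so the
generator→kinematics→model chain is self-consistent.

Phase points sit at cell midpoints of the 48:52 grid (96 + 104 of 200
points are then equally spaced in time). Midpoint placement makes the
stroke transitions fall on cell boundaries, so cycle averages of the
piecewise-smooth integrand converge at second order: the 200-point
evaluation agrees with a 10,000-point evaluation within 0.5% across random
parameter draws (acceptance suite). Degenerate phase points with vanishing
incident velocity produce zero force and are flagged. Cycle averages are
duration-weighted; the travel-direction force rotates the mean horizontal
force into the travel axis through Ψ.

With the default synthetic kinematics the model supports ≈0.51 of body
weight in hover and produces a forward-thrust surplus of ≈0.3 wb. Both
reflect the flat-plane α of a twist-less wing — the proximal wing truly
operates at higher α than the distal wing, and ignoring twist inflates
upstroke drag/thrust — plus the fact that the synthetic α schedule is a
stylized two-level waveform rather than measured rotation profiles. The
*differential* quantities the model exists for (lateral force sign and
left/right mirror structure) are robust to this: mirrored kinematics give
exactly mirrored forces, and both tracking directions yield net lateral
force opposing travel.

## Numerical and degenerate-input policy

* Validation errors (`ValueError`) for: dock events outside/overlapping the
  record, non-uniform sampling, cutoffs at/above Nyquist, fewer than three
  detected wingbeat cycles, stroke amplitudes above 180°, zero-length
  dividing lines, coincident head/tail, bands above Nyquist.
* Docks ≤ 0.5 s are excluded from analysis (the crop would empty them).
* Collinear wing-plane frames are flagged and linearly interpolated.
* Landmark gaps ≤ 5 ms are linearly interpolated on ingest; longer gaps
  are rejected.
* All generators are deterministic functions of their seed
  (`numpy.random.default_rng`).

## Problem sizes

Defaults keep every stage desk-scale: strain records of ~16 s at 1000 Hz,
landmark records of 8 wingbeats at 1000 frames/s, 200-point force cycles
(10,000 points only in the refinement check), 50 seeds in the recovery
sweep. The full test suite runs in a few seconds.

## Known limitations

* Single blade element: no spanwise integration, no wing twist, no
  rotational lift, added mass, or wake capture — absolute force magnitudes
  are indicative, differential/symmetry results are the reliable outputs.
* The synthetic α schedule and stroke waveform are stylized; recovery
  tolerances quantify the pipeline, not biological variability.
* χ_GR,YZ is measured across the short shoulder baseline and inherits
  ~0.5° of noise at the default digitization error; per-trial means over
  more wingbeats shrink this.
* The stationary-feeder statistics layer (mixed models, post-hoc
  contrasts) is out of scope; per-feed summaries are exported for external
  statistical software.
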