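# Methods

## Scope and model

`echonav` is a discrete-time (one step per sonar call), 2-D, closed-loop
model of obstacle avoidance by a bat-like sonar robot.  The agent is a
unicycle of radius 0.165 m; each 50 ms interpulse interval it emits a call,
processes the returned echo train into two scalars — the nearest-reflector
distance estimate d̂ and the onset interaural level difference (ILD) — and
executes one motor command (body rotation Δθ, head rotation Δϕ, speed v).
Everything is synthetic: no recorded acoustics or trajectories enter the
package.

## Acoustics

**Scenes as point-scatterer ensembles.**  Physical reflectors are
represented by collision geometry (discs, segments) plus clouds of point
scatterers with log-normal reflection strengths.  A pole carries 20
scatterers uniform in a 0.10 m disc (log-normal σ = 0.5 around base
strength 0.01) — several overlapping glints per call, as foliage produces.
Walls carry a scatterer every 3 cm.  Two wall finishes are distinguished,
matching the physical setups being emulated: the arena's plain cardboard
panels are *quasi-specular* — each wall scatterer's return is weighted by
cos⁸ of the incidence angle, so a panel is loud near perpendicular
incidence and nearly silent when approached obliquely (σ = 0.15, positional
jitter ±0.5 cm); the corridor's egg-carton lining is *diffuse* (exponent 0,
σ = 0.5, jitter ±2 cm), returning extended echo cascades from every
direction.  No image-source (multipath) model is used; walls are their
scatterers.

**Synthesis.**  For a call from position p with gaze direction g, every
scatterer within 6 m range and ±90° of gaze contributes to each ear a copy
of the emitted pulse (1.5 ms raised-cosine 40 kHz burst, unit source level)
delayed by 2r/c (c = 343 m/s) and scaled by
strength · D_emit(az) · D_ear(az, side) · r⁻² · 10^(−2·1.3·r/20).
Azimuth is positive to the right of the gaze axis; turn angles elsewhere
are positive counterclockwise, so "right ear louder → turn left" keeps a
consistent sign.  The emitter is a 10 mm circular piston; ear gains are
mirrored Gaussians (peaks ±25°, σ = 40°) approximating a bat-like HRTF with
a monotone frontal ILD gradient.  Both ears sit at the robot centre: the
model carries a pure level-difference cue and no time difference, because
the controllers use only relative loudness.  The direct emission pickup
(amplitude 1) is added at time zero, and independent Gaussian receiver
noise per channel on top.  The 6 m range cap keeps the 35 ms recording
inside the 50 ms interval.

**Receiver noise (default RMS 2 × 10⁻⁵ of the source level).**  This value
was calibrated once so that the synthetic sonar behaves like a practical
40 kHz system: clutter at 0.3–3 m is detected reliably on-axis, while weak
lateral echoes (emitter and ear gains both small beyond ~60–70° off gaze)
drop below the detection threshold — so pointing the head away from an
obstacle raises the detected distance, a property the closed-loop behaviour
depends on.  At much lower noise the sonar becomes implausibly
omniscient; at much higher noise frontal wall detection fails.

## Auditory processing

Each channel passes through a single-channel cochlear model: 4th-order
gammatone bandpass at 40 kHz (scipy's standard formulation, ERB-scaled
bandwidth) → half-wave rectification → power-law compression with exponent
0.4 → 2nd-order Butterworth low-pass at 1 kHz, applied forward-only
(causal, as in a real-time system).  The cochlear envelope of the bare
emission is subtracted (clipped at zero) over its window.  Detection: local
maxima (strictly above the previous sample, at least equal to the next, so
plateaus resolve to the earlier sample); the earliest peak exceeding the
threshold in either ear is the first echo.  The threshold is 10× the RMS
cochlear output of a pure-noise calibration call (a deterministic function
of the noise level), floored at 10⁻⁹ for noise-free runs.  Onset energies
are the per-ear envelope sums over 300 samples (1 ms at 300 kHz) starting
150 samples before the shared first-echo peak.

The envelope of a detected echo peaks about 1.1 ms after its onset (pulse
envelope ~0.75 ms to peak, plus gammatone and low-pass group delays), so
d̂ = c·t_peak/2 overestimates range by ≈ 0.19 m.  This bias is physical —
the same filters impose it on any real-time implementation — and stays
within half the two-way pulse length (0.26 m), the resolution limit of a
1.5 ms call.

## Control laws

All laws interpolate linearly and clamp outside their breakpoints
(distances in [0.3, 1.5] m, gaze in [0°, 45°]); endpoints are chosen so
per-call displacement spans 5–15 cm and the turn-rate feasibility bound
holds (below).

- Rotation magnitude: 50° at d̂ ≤ 0.3 m down to 25° at d̂ ≥ 1.5 m
  (head rates 1000–500 °/s at the 50 ms interval).
- Fixed-Head speed: 1 m/s near to 3 m/s far.
- DLAL speed: 3 m/s at ϕ = 0 to 1 m/s at |ϕ| ≥ 45°.
- Turn sign: away from the louder ear; exact energy ties are broken by a
  fair coin from the trial's seeded generator; an undetected echo keeps the
  previous sign and reads d̂ as 1.5 m (open space ahead).

**DLAL body law.**  The body turn *rate* tracks the delayed head angle,
θ̇ = k·ϕ(t−τ), k = 10 s⁻¹, τ = 50 ms, so Δθᵢ = k·ϕ_τ·δt = ϕ_τ/2 per call.
The gain is a rate constant (units s⁻¹), as in the gaze-tracking law it
descends from; with the head scanning ±25–50° per call this yields body
rates on the order of a few hundred °/s, the scale observed in gaze-led
steering.  Treating k as a per-call angular gain instead would command
body turns of up to 900° per 50 ms, which no flyer or wheeled platform
executes.

**Head servo timing.**  The commanded head swings (25–50°) at the head's
500–1000 °/s rotation rates occupy essentially the whole interpulse
interval, so the head *arrives* at its commanded angle one interval after
the command.  The head-angle history is therefore time-stamped at arrival,
and ϕ(t−τ) is linearly interpolated from that record; with τ equal to one
interval, the body follows the angle commanded two calls back.  (Any
finite servo speed gives this result when τ is a multiple of the interval;
only an instantaneous head would behave differently, and that variant
makes gaze scanning nearly indistinguishable from the Fixed Head strategy
in closed loop.)  An optional clamp of |Δθ| to the feasibility bound is
available and off by default.

**Feasibility bound.**  Ω = G·9.81/v rad/s with G = 4 limits centripetal
acceleration to 4 g.  Under the default laws the commanded Fixed-Head body
rates (1000 °/s at v = 1 m/s; 500 °/s at v = 3 m/s) sit below the bound
(2248 and 749 °/s) across the whole distance range; `feasibility_check`
returns the margin curve.

## Environments

**Arena** (3 × 4 m, walled): 11 poles (4 cm tubes, collision radius
0.02 m) placed by rejection sampling — pairwise spacing ≥ 0.4 m, every
pole's nearest neighbour < 1 m, centres ≥ 0.6 m from the walls.  The wall
margin keeps pole–wall gaps wider than the robot diameter (0.33 m):
free-standing obstacles in a walled cage are not jammed against the
panels, and narrower margins create impassable funnels that change the
failure mode of every strategy.  Within these constraints the layout, the
scatterer positions and the strengths are all seed-deterministic.

**Corridor** (0.9 m wide, 3 m long): two diffuse rough walls, goal line at
x = 3 m.  Trials start centred at the entrance with ±10° heading jitter
and end at the goal, on collision, on turn-around (heading component along
the axis negative for 10 consecutive calls with decreasing axial position),
or — rarely — when the call budget runs out ("timeout", counted as
failure).

**Collision handling.**  Contacts are checked at the midpoint and endpoint
of every step (a ≤ 15 cm step cannot tunnel through any primitive given
the 0.37 m combined diameters).  In the arena the robot is repositioned at
1 cm clearance facing directly away from the contacted surface and the
trial continues — a deterministic analogue of an experimenter turning the
robot away and resuming.  Corridor trials terminate on contact.

## Randomness and reproducibility

Each trial owns a seed; a `SeedSequence` splits it into named streams for
receiver noise, control draws (ties, random-walk turns) and initial-pose
sampling.  Experiments derive trial seeds as base_seed + index.  Identical
(environment, seed) pairs produce bit-identical trials; the test suite
asserts this end to end.

## Experiment sizes and variability

The replica experiment is 10 trials × 600 calls per strategy in the arena
(30 s of simulated flight per trial) and 20 trials per strategy in the
corridor — the sizes of the original designs; a full arena comparison of
three strategies runs in about a minute on one core.  The two headline
quantities (percent reduction in pooled collisions per metre, DLAL vs.
random walk and Fixed Head vs. DLAL) are ratios of small collision counts:
the Fixed Head strategy collides only about ten times per experiment, so
both reductions can shift by ten or more percentage points between arena
layouts and trial seeds.  Any single seeded run — like any single physical
experiment — is one draw from these distributions; the ordering of the
three strategies is stable across seeds, the exact percentages are not.

## What the synthetic data does and does not capture

The generator reproduces the features the steering problem depends on:
dense overlapping echo trains with no separable reflectors, range-dependent
attenuation, beam-limited detection, a monotone frontal ILD, and clutter
densities matching the physical setups.  It omits multipath and
second-order scattering, Doppler, frequency-dependent reflector responses,
elevation/3-D effects, interaural time differences, continuous-time motor
dynamics (turns complete instantaneously between calls), and sensor
imperfections beyond additive Gaussian noise.  Passing tests therefore
demonstrate properties of the model under these idealisations, not
performance guarantees for hardware in real acoustics.

## Known limitations

- The ear-gain parametrisation (mirrored Gaussians) is a smooth stand-in
  for a measured HRTF; real pinnae have lateral sidelobes and a noisier
  ILD off-axis, which would further degrade gaze scanning.
- d̂ carries the +0.19 m envelope-peak bias discussed above; all laws
  operate on the biased estimate, as a real-time system would.
- The collision-reduction ratios are chaotic in the arena layout at the
  published experiment size; comparisons between strategies are robust,
  exact percentages are not.
- The turn-around detector is a fixed rule (10-call run); the original
  protocol relied on experimenter judgement.
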