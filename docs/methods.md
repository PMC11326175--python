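# Methods

## Model

An agent is a point fish in a circular arena (diameter 6.5 cm) with a
pose (x, y, heading), an internal state `s`, and a bout phase.
Headings are degrees, counter-clockwise positive, wrapped to
(−180, 180]; a right turn is a negative heading change.  Time advances
in steps of Δt = 1/50 s.

**Perception.**  Every other agent or stimulus dot is reduced to a
bearing in the focal frame and a vertical retinal occupancy
`v = 2·arctan(H/d)` (degrees), where `H` is the object's half-extent —
the dot radius, or the fish-height parameter for conspecifics — and
`d` the center-to-center distance.  Objects with |bearing| > 165° fall
in the rear blind zone and are invisible, for occupancy and looming
alike.  Bearings left of the heading are positive; an object at exactly
0° belongs to the right eye (a measure-zero tie broken
deterministically).  Simulated agents use the per-object mode with no
occlusion correction; the rasterized mode (1° bearing grid, each cell
carrying the occupancy of the nearest covering object, disc coverage
half-width `arcsin(H/d)`) exists for analyzing recorded scenes and is
validated against a 0.01° ray-casting oracle.

**Turning policy.**  On each bout the probability of turning right is
`0.5 + a'·(Σ_L v² − Σ_R v²)/Σv`, clamped to [0, 1] after summation,
with Σv over both eyes.  This is the linear-bias closed form of the
general weighted-bias rule `0.5 + Σ w_i·bias(v_i)` with
`w_i = v_i/Σv`; a tabulated bias curve is supported and the two
evaluations agree to 1e-12 when the table is linear.  The events the
slope is estimated from are bouts annotated with the occupancy
difference at onset; the fit is least squares through the origin of
(fraction turned away − 0.5) against bin centers, weighted by per-bin
event counts, because occupancy bins are heavily unbalanced in
practice.

**Internal state.**  `τ ds/dt = s_rest − s + r·Input(t)`, integrated by
forward Euler (input varies per step; the exact exponential solution is
retained as the test oracle and agrees to <1e-4 relative over 2 h at
Δt = 1/50 s).  `Input(t)` is the maximal single-object increase in
occupancy between consecutive steps, floored at 0.  In the default
`neighbor_induced` mode the previous occupancy is re-projected from the
*current* focal pose, so self-motion through a static scene contributes
exactly nothing — this reproduces the stationary-dot null without any
tuning; a `raw` mode (occupancy change as experienced) is a config
switch.  For ego-anchored (closed-loop) stimuli the loom is the change
in egocentric dot distance/radius, which encodes the same quantity.
`Input` is in degrees per step and `r = 13` is taken as calibrated at
Δt = 1/50 s.  `s` is clamped to `[s_rest, s_start + D]`, keeping the
effective slope `a' = a·(1 − (s − s_start)/D)` in
`[0, a·(1 + s_start/D)]`: no response reversal is ever produced.

**Bouts.**  An idle agent starts a bout with fixed probability per
step; executing agents are refractory for the 320 ms bout.  The idle
probability is `rate·Δt / (1 − rate·(T_bout − Δt))` so that the
*emergent* onset-to-onset rate equals the configured 1.64 Hz — the
published rate describes observed fish behavior, which includes the
bout refractory (`refractory_compensation=False` restores the literal
`rate·Δt`).  At onset the full turn angle is applied instantly and the
0.1 cm displacement is spread linearly over the 16 steps, truncated at
the arena wall (position clamped to the boundary, remaining
displacement dropped).  Turn magnitudes are drawn from a two-component
mixture: forward bouts |N(0°, 10°)| and turn bouts |N(35°, 15°)|, half
each; the sign comes from the policy.  All four numbers are
config-exposed stand-ins for unpublished empirical distributions.

**Walls.**  The probability that a bout is a wall-avoidance bout is
logistic in wall distance, half-maximal at 1.25 body lengths with
steepness 4 per body length (a stand-in for an unpublished empirical
curve; 1.25 BL echoes the analysis exclusion radius).  A wall bout
ignores neighbors and turns away from the outward radial direction;
below 1.25 BL neighbors are ignored even for non-wall bouts.

**Update order.**  Per step and per agent in fixed index order:
perception (from the previous-step snapshot of all poses) → integrator
→ bout decision/advance.  The synchronous snapshot removes
order-dependence.  All randomness flows from one `numpy` Generator per
world, so runs are bitwise reproducible from (seed, config);
per-repetition seeds derive from the master seed via
`SeedSequence(master, spawn_key=(rep,))`.

**Density switches.**  Shrinking removes uniformly chosen agents and
leaves survivors untouched; growing places new agents uniformly within
0.9 of the arena diameter with states drawn from a normal distribution
matched to the incumbents' mean and SD (clamped to the state bounds).

## Stimuli

Streams are dot fields at the simulation step (a 60 Hz export exists
for rig use; generating at Δt avoids resampling artifacts in
simulation).  World-frame streams: trajectory replay (one 0.75 cm
radius dot per fish; looping with the acknowledged restart
discontinuity), a frozen random frame (stationary control), and 19
looming dots on a hexagonal lattice whose radii follow a three-state
grow/shrink/hold Markov schedule (default ±0.8 cm/s, switching at
1.64 Hz) clamped to [0.075, 0.9] cm — an explicit stochastic stand-in
for unpublished resampled loom traces.  Focal-frame streams (re-anchored
to the agent each step, as in closed-loop VR): 19 dots orbiting at the
modal k-th-nearest-neighbor distances of a source recording (0.05 cm
histogram bins), advancing in bout-like arcs with per-bout random
CW/CCW direction; and the single-dot protocols sweeping from ±75° to
±30° in 5 s trials with side drawn per trial and radius/distance
schedules linear in trial time.  Surrogate source trajectories are
independent bout-walkers (the simulator with the social term disabled),
so their bout statistics are the configured ones by construction.

## Analysis

Velocities are central differences; speeds feed a threshold bout
detector (0.15 cm/s on a 3-frame boxcar, 40 ms merge window) calibrated
on simulated ground truth.  Bouts separated by less than ~2 frames are
physically unresolvable by any speed threshold, so detected counts
undercount by ~13% at 1.64 Hz; at sparse rates recovery is exact.
Nearest-neighbor series are per-frame, per-animal, with 60 s block
means; shuffled controls rebuild pseudo-groups from different source
groups (filling from used groups when sources run out) with independent
random circular time shifts.  Exposure effects are ΔNN = after − before
per animal; recovery series are fitted with
`N(t) = N_inf + (N0 − N_inf)·e^(−t/λ)`.  "Time to baseline" is the time
at which the fitted curve re-attains the pre-exposure baseline; the
first sample inside a 5% band of baseline is also reported, but with a
~9% exposure effect that band triggers at roughly half recovery, so the
fitted crossing is the quantity that corresponds to "return to
baseline".  Exclusion filters: any group member immobile (smoothed
speed < 0.05 cm/s) for >50% of frames drops the group; single animals
with bout rate < 0.25 Hz are dropped.

## Protocol experiments and problem sizes

The recovery experiment runs, per repetition: 20 min at 4 virtual
neighbors (baseline), 20 min at 19, then branches of {0, 10, 20, 30,
40, 50, 60, 80} min with 0 neighbors, each followed by a 20 min
low-density probe in which NN is measured — branching from the shared
post-exposure state mirrors the separate experimental cohorts, and
20 min probes match the experimental measurement blocks.  24 seeded
repetitions; the exponential is fitted to the repetition-mean series.
Replay sources are 5 min of surrogate trajectories presented in a loop,
as in the exposure-time experiments.  Across master seeds the fitted
baseline crossing scatters between roughly 45 and 80 min (center near
60 min) — the dominant source is between-cohort variation in the
surrogate streams' loom statistics — and the fit R² lies between ~0.95
and ~0.99.  The exposure-time, stationary
null and split/merge checks in the test suite use 10–24 repetitions
with 10–20 min segments — sizes chosen to make the directional effects
statistically unambiguous.

## What the synthetic data do and do not show

Surrogate bout-walkers emulate fish-like locomotion statistics (rate,
displacement, duration, turn mixture, wall confinement) but not the
social structure, speed modulation or pose kinematics of real
recordings: dots derived from them evoke realistic occupancy and loom
*statistics*, not the exact experienced distributions.  Passing tests
therefore establishes that the model mechanism produces the
experience-dependent phenomenology under fish-like input — baseline NN
at 4 neighbors (~1.6 cm) and the split/merge pattern land close to the
published measurements — not that it quantitatively reproduces any real
fish's trajectory.  Absolute quantities that inherit the surrogate loom
statistics (e.g. the recovery time, via the state gain accumulated
during exposure) carry that caveat.

## Numerical choices and limitations

Forward Euler at Δt/τ ≈ 1e-6 per step; clamped state; probabilities
clamped after summation; bout truncation solves the boundary
intersection exactly; ties (bearing 0°, wall direction at the arena
center) broken deterministically or symmetrically at random.  The
stepping core is JIT-compiled (numba) scalar code sharing its formulas
with the public numpy functions; a consistency test pins the two routes
to each other at 1e-9.  Not modeled: hydrodynamics, body deformation,
collisions, 3-D swimming, occlusion among neighbors during simulation,
photometric properties of the projection, and any non-visual (olfactory,
somatosensory) density cue.
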