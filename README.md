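# zfschool

Agent-based modeling and analysis of **experience-dependent collective
behavior in larval zebrafish** (7 dpf).  Young larvae swim in discrete
bouts and keep their distance from group mates by turning away from the
eye with the higher retinal occupancy.  This repulsion is not hardwired:
after tens of minutes at a higher group density, fish tolerate closer
neighbors, and the change persists for hours and reverses only slowly.
`zfschool` implements a time-varying state-space model of this process
together with the virtual-reality (VR) stimulus protocols and trajectory
statistics used to characterize it.

## The model

Each agent perceives every neighbor (or projected dot) j as a vertical
retinal occupancy

    v_j = 2 * arctan(H_j / d_j)

at its horizontal bearing, within a visual field of ±165° (30° rear
blind zone).  The probability of a rightward turn on the next bout is a
binocular comparison of occupancy-weighted squared occupancies (weights
w_i = v_i / Σv):

    p(turn right) = 0.5 + a' * [ Σ_left v_i² − Σ_right v_i² ] / Σv      (clamped to [0, 1])

The gain a' is modulated by a hidden internal state s(t) driven by a
**leaky integrator of looming events** — the maximal per-step increase
in any object's retinal occupancy:

    τ ds/dt = s_rest − s(t) + r * Input(t),        a' = a * (1 − (s − s_start) / D)

With τ = 6 h the integrator operates in its linear regime on
experimental time scales: denser groups evoke more looming, s rises,
turning weakens, and nearest-neighbor (NN) distances shrink — and the
effect outlives the exposure by hours.  Defaults (arena diameter 6.5 cm,
Δt = 1/50 s, bouts of 0.1 cm / 320 ms at 1.64 Hz, a = 0.0104 (VR) or
0.00372 (groups), r = 13, s_start = 0.6, D = 0.19 or 0.1) are the
published simulation parameters.

Included besides the simulator (single agent in VR, or N interacting
agents with mid-session density splits/merges): generators for every VR
stimulus — trajectory replay as 1.5 cm dots, surrogate bout-walker
trajectories, a frozen stationary frame, rotating rings at modal k-NN
distances (translation without loom), a looming hexagon (loom without
translation), and the three single-dot sweeps — plus trajectory
analysis: central-difference kinematics, bout detection,
nearest-neighbor series with shuffled controls, turn-probability maps,
exposure/recovery protocol summaries and cohort exclusion filters.

## Worked example

A single simulated fish watches 4 virtual neighbors for 20 min, then 19
for 20 min, then 4 again:

```python
import numpy as np
from zfschool import SimulationConfig, World
from zfschool.experiments import make_replay

cfg = SimulationConfig()                    # single-agent VR defaults
low = make_replay(4, seed=11)               # 4 surrogate neighbors as dots
high = make_replay(19, seed=12)

fish = World(cfg, n_agents=1, seed=7)
before = fish.run(20 * 60, stimulus=low, record_stride=5)
fish.run(20 * 60, stimulus=high, record_stride=5)
after = fish.run(20 * 60, stimulus=low, record_stride=5)

print(f"NN before: {before.nn_to_stimulus().mean():.2f} cm   "
      f"NN after: {after.nn_to_stimulus().mean():.2f} cm")
print(f"internal state s: {before.s[0,0]:.3f} -> {after.s[-1,0]:.3f}")
print(f"turning gain a': {before.a_eff[0,0]:.5f} -> {after.a_eff[-1,0]:.5f} /deg")
```

prints

```
NN before: 1.59 cm   NN after: 1.49 cm
internal state s: 0.600 -> 0.741
turning gain a': 0.01040 -> 0.00269 /deg
```

The high-density epoch drives the internal state up by ~0.14, halving
(and more) the turning gain; back at low density the fish now swims
0.10 cm closer to its virtual neighbors — the signature
history-dependence of the model.  A command-line layer exposes the same
machinery: `zfschool simulate`, `zfschool stimulus`, `zfschool analyze`
and `zfschool fitcheck` (see `--help`).

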