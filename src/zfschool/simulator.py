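"""Agent-based simulation of bout-swimming larvae in a circular arena.

Two modes share one stepping core:

* **VR mode** — a single simulated fish responds to a stream of
  projected dots (:mod:`zfschool.stimuli`), mirroring the closed-loop
  virtual-reality assay.
* **Group mode** — N fully interacting agents perceive each other as
  visual objects; group size can be changed mid-session (density
  split/merge protocols).

Each agent, when idle, decides per time step (probability
``bout_rate * dt``) to perform a bout: the heading rotates by the full
sampled turn angle at bout onset and the 0.1 cm displacement is spread
linearly over the 320 ms bout, truncated at the arena boundary.  Turn
direction follows the wall-avoidance rule near the wall and otherwise
the binocular occupancy policy with the state-modulated slope.  All
agents update synchronously (perception uses previous-step poses) and
all randomness flows from a single seeded generator, so runs are
bitwise reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .retina import OccupancyProfile, wrap_angle
from .state import IntegratorParams, effective_slope

__all__ = [
    "SimulationConfig",
    "BoutPlan",
    "Segment",
    "SegmentResult",
    "SessionResult",
    "World",
    "decide_bout",
    "plan_bout",
    "step_world",
    "resize_group",
    "run_session",
    "repetition_seed",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All simulation parameters (single-agent VR defaults).

    Units: cm, seconds, Hz, degrees.  ``a`` is the baseline slope of the
    occupancy response (probability per degree); ``fish_height_cm`` is
    used as the half-extent of a conspecific in the occupancy formula.
    """

    arena_diameter_cm: float = 6.5
    dt_s: float = 1.0 / 50.0
    fish_length_cm: float = 0.4
    fish_height_cm: float = 0.4
    bout_rate_hz: float = 1.64
    bout_size_cm: float = 0.1
    bout_duration_ms: float = 320.0
    a: float = 0.0104
    tau_hr: float = 6.0
    r: float = 13.0
    s_rest: float = 0.0
    s_start: float = 0.6
    D: float = 0.19
    looming_mode: Literal["neighbor_induced", "raw"] = "neighbor_induced"
    seed: int | None = None
    duration_s: float = 1200.0
    n_repetitions: int = 24
    # turn-angle magnitude mixture (forward bouts vs turn bouts)
    turn_fraction: float = 0.5
    forward_sd_deg: float = 10.0
    turn_mean_deg: float = 35.0
    turn_sd_deg: float = 15.0
    # wall policy
    wall_half_bl: float = 1.25
    wall_steepness_per_bl: float = 4.0
    wall_ignore_bl: float = 1.25
    field_limit_deg: float = 165.0
    start_fraction: float = 0.9
    social: bool = True
    integrator_enabled: bool = True
    # make the emergent onset-to-onset bout rate equal bout_rate_hz by
    # compensating the idle-step probability for the bout refractory
    refractory_compensation: bool = True

    def __post_init__(self):
        if self.dt_s <= 0 or self.arena_diameter_cm <= 0:
            raise ValueError("dt and arena diameter must be positive")
        if self.bout_rate_hz * self.dt_s >= 1.0:
            raise ValueError("bout_rate * dt must be < 1")

    @classmethod
    def vr_defaults(cls, **overrides) -> "SimulationConfig":
        """Single agent responding to projected dots (a=0.0104, height 0.4)."""
        return cls(**overrides)

    @classmethod
    def group_defaults(cls, **overrides) -> "SimulationConfig":
        """Interacting agents (a=0.00372, height 0.2, D=0.1)."""
        kw = dict(a=0.00372, fish_height_cm=0.2, D=0.1)
        kw.update(overrides)
        return cls(**kw)

    # derived quantities -------------------------------------------------
    @property
    def arena_radius_cm(self) -> float:
        return self.arena_diameter_cm / 2.0

    @property
    def bout_prob_per_step(self) -> float:
        """Bout-onset probability per idle step.

        A bout occupies the agent for its full duration, so onsets are a
        renewal process: duration + geometric idle wait.  With
        compensation the idle probability is raised so the emergent
        onset rate equals ``bout_rate_hz``; without it the literal
        ``bout_rate * dt`` is used.
        """
        p = self.bout_rate_hz * self.dt_s
        if not self.refractory_compensation:
            return p
        # onset-to-onset cycle: (1/p - 1) idle steps + bout_steps busy steps
        # (the onset step is both the Bernoulli success and the first busy
        # step); solve cycle = 1/rate for p
        duty = self.bout_rate_hz * (self.bout_steps - 1) * self.dt_s
        if duty >= 1.0:
            raise ValueError("bout rate * bout duration must be < 1")
        return p / (1.0 - duty)

    @property
    def bout_steps(self) -> int:
        return max(1, round(self.bout_duration_ms / 1000.0 / self.dt_s))

    @property
    def integrator(self) -> IntegratorParams:
        return IntegratorParams(
            tau_s=self.tau_hr * 3600.0, r=self.r, s_rest=self.s_rest,
            s_start=self.s_start, D=self.D,
        )

    def kernel_params(self) -> np.ndarray:
        par = np.zeros(K.N_PARAMS)
        par[K.P_DT] = self.dt_s
        par[K.P_ARENA_R] = self.arena_radius_cm
        par[K.P_FISH_LEN] = self.fish_length_cm
        par[K.P_HALF_EXT] = self.fish_height_cm
        par[K.P_BOUT_P] = self.bout_prob_per_step
        par[K.P_BOUT_STEPS] = self.bout_steps
        par[K.P_BOUT_SIZE] = self.bout_size_cm
        par[K.P_A_BASE] = self.a
        par[K.P_TAU] = self.tau_hr * 3600.0
        par[K.P_RSCALE] = self.r
        par[K.P_S_REST] = self.s_rest
        par[K.P_S_START] = self.s_start
        par[K.P_D] = self.D
        par[K.P_S_MIN] = self.s_rest
        par[K.P_S_MAX] = self.s_start + self.D
        par[K.P_W_HALF] = self.wall_half_bl
        par[K.P_W_STEEP] = self.wall_steepness_per_bl
        par[K.P_W_IGNORE] = self.wall_ignore_bl
        par[K.P_TURN_FRAC] = self.turn_fraction
        par[K.P_FWD_SD] = self.forward_sd_deg
        par[K.P_TURN_MEAN] = self.turn_mean_deg
        par[K.P_TURN_SD] = self.turn_sd_deg
        par[K.P_FIELD] = self.field_limit_deg
        par[K.P_LOOM_RAW] = 1.0 if self.looming_mode == "raw" else 0.0
        par[K.P_SOCIAL] = 1.0 if self.social else 0.0
        par[K.P_INTEG] = 1.0 if self.integrator_enabled else 0.0
        return par

    def to_dict(self) -> dict:
        return asdict(self)


def repetition_seed(master_seed: int, repetition: int) -> int:
    """Per-repetition child seed: stable counter scheme below 2**31."""
    return int(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(repetition),))
        .generate_state(1, dtype=np.uint32)[0] % (2**31)
    )


def decide_bout(config: SimulationConfig, rng: np.random.Generator) -> bool:
    """Bernoulli bout decision for an idle agent (p = bout_rate * dt)."""
    return bool(rng.random() < config.bout_prob_per_step)


@dataclass(frozen=True)
class BoutPlan:
    turn_deg: float
    displacement_cm: float
    duration_ms: float
    wall_triggered: bool


def plan_bout(
    config: SimulationConfig,
    pose_xy: Sequence[float],
    heading_deg: float,
    left: OccupancyProfile,
    right: OccupancyProfile,
    s: float,
    rng: np.random.Generator,
) -> BoutPlan:
    """Choose turn direction and magnitude for a triggered bout.

    Wall avoidance has priority: with probability given by the logistic
    wall policy the agent ignores neighbors and turns away from the
    nearest wall.  Otherwise (and outside wall proximity) the direction
    follows the occupancy policy with the state-modulated slope.
    """
    x, y = float(pose_xy[0]), float(pose_xy[1])
    rad = float(np.hypot(x, y))
    wall_bl = (config.arena_radius_cm - rad) / config.fish_length_cm
    p_wall = 1.0 / (
        1.0 + np.exp(config.wall_steepness_per_bl * (wall_bl - config.wall_half_bl))
    )
    wall_triggered = rng.random() < p_wall
    if wall_triggered:
        if rad > 1e-9:
            phi = float(wrap_angle(np.degrees(np.arctan2(y, x)) - heading_deg))
            sign = -1.0 if phi > 0.0 else 1.0
        else:
            sign = -1.0 if rng.random() < 0.5 else 1.0
        mag = abs(rng.normal(config.turn_mean_deg, config.turn_sd_deg))
    else:
        p_right = 0.5
        if config.social and wall_bl >= config.wall_ignore_bl:
            vl, vr = left.occupancy_deg, right.occupancy_deg
            total = float(vl.sum() + vr.sum())
            if total > 0:
                a_eff = effective_slope(config.a, s, config.integrator)
                p_right = 0.5 + a_eff * float((vl**2).sum() - (vr**2).sum()) / total
                p_right = min(1.0, max(0.0, p_right))
        sign = -1.0 if rng.random() < p_right else 1.0
        if rng.random() < config.turn_fraction:
            mag = abs(rng.normal(config.turn_mean_deg, config.turn_sd_deg))
        else:
            mag = abs(rng.normal(0.0, config.forward_sd_deg))
    return BoutPlan(
        turn_deg=float(sign * mag),
        displacement_cm=config.bout_size_cm,
        duration_ms=config.bout_duration_ms,
        wall_triggered=bool(wall_triggered),
    )


_EMPTY_DOTS = np.full((1, 0, 3), np.nan)


@dataclass
class Segment:
    """One protocol segment: a stimulus stream or a group-size target."""

    duration_s: float
    stimulus: "object | None" = None  # StimulusStream
    n_agents: int | None = None
    label: str = ""

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("segment duration must be > 0")


@dataclass
class SegmentResult:
    """Recorded output of one segment at the record stride."""

    label: str
    times_s: np.ndarray
    local_steps: np.ndarray  # step index within the segment for each record
    agent_ids: np.ndarray
    x: np.ndarray          # (n_rec, n_agents)
    y: np.ndarray
    heading: np.ndarray
    s: np.ndarray
    loom_input: np.ndarray
    a_eff: np.ndarray
    bouting: np.ndarray
    bouts: pd.DataFrame
    stimulus: "object | None" = None

    def trajectory_table(self) -> pd.DataFrame:
        n_rec, n = self.x.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times_s, n),
                "agent_id": np.tile(self.agent_ids, n_rec),
                "x_cm": self.x.ravel(),
                "y_cm": self.y.ravel(),
                "heading_deg": self.heading.ravel(),
                "bouting": self.bouting.ravel().astype(int),
            }
        )

    def state_table(self) -> pd.DataFrame:
        n_rec, n = self.s.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times_s, n),
                "agent_id": np.tile(self.agent_ids, n_rec),
                "s": self.s.ravel(),
                "input_deg": self.loom_input.ravel(),
                "a_eff": self.a_eff.ravel(),
            }
        )

    def nn_to_stimulus(self) -> np.ndarray:
        """Per-record distance from each agent to its nearest stimulus dot (cm)."""
        if self.stimulus is None:
            raise ValueError("segment has no stimulus")
        return self.stimulus.nearest_dot_distance(self.local_steps, self.x, self.y)


@dataclass
class SessionResult:
    segments: list[SegmentResult]
    config: SimulationConfig
    seed: int | None = None

    def trajectory_table(self) -> pd.DataFrame:
        return pd.concat(
            [s.trajectory_table().assign(segment=s.label) for s in self.segments],
            ignore_index=True,
        )

    def state_table(self) -> pd.DataFrame:
        return pd.concat(
            [s.state_table().assign(segment=s.label) for s in self.segments],
            ignore_index=True,
        )

    def bout_table(self) -> pd.DataFrame:
        return pd.concat(
            [s.bouts.assign(segment=s.label) for s in self.segments],
            ignore_index=True,
        )


class World:
    """Mutable simulation state: agent arrays, clock and RNG."""

    def __init__(
        self,
        config: SimulationConfig,
        n_agents: int = 1,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.config = config
        if rng is not None:
            self.rng = rng
        else:
            self.rng = np.random.default_rng(
                seed if seed is not None else config.seed
            )
        self.clock_s = 0.0
        self.step_count = 0
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.heading = np.empty(0)
        self.s = np.empty(0)
        self.bout_left = np.empty(0, dtype=np.int64)
        self.bout_dx = np.empty(0)
        self.bout_dy = np.empty(0)
        self.prev_x = np.empty(0)
        self.prev_y = np.empty(0)
        self.prev_h = np.empty(0)
        if n_agents > 0:
            self._append_agents(n_agents, s_values=np.full(n_agents, config.s_start))

    # -- construction helpers -------------------------------------------
    def _random_pose(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        r_max = self.config.start_fraction * self.config.arena_diameter_cm / 2.0
        r = r_max * np.sqrt(self.rng.random(n))
        ang = self.rng.uniform(-np.pi, np.pi, n)
        head = self.rng.uniform(-180.0, 180.0, n)
        return r * np.cos(ang), r * np.sin(ang), wrap_angle(head)

    def _append_agents(self, n: int, s_values: np.ndarray):
        x, y, h = self._random_pose(n)
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, y])
        self.heading = np.concatenate([self.heading, h])
        self.s = np.concatenate([self.s, np.asarray(s_values, dtype=float)])
        self.bout_left = np.concatenate([self.bout_left, np.zeros(n, dtype=np.int64)])
        self.bout_dx = np.concatenate([self.bout_dx, np.zeros(n)])
        self.bout_dy = np.concatenate([self.bout_dy, np.zeros(n)])
        self._reset_prev()

    def _reset_prev(self):
        self.prev_x = self.x.copy()
        self.prev_y = self.y.copy()
        self.prev_h = self.heading.copy()

    @property
    def n_agents(self) -> int:
        return self.x.size

    def clone(self, reseed: int | None = None) -> "World":
        """Deep copy of the world; optionally with a fresh RNG seed."""
        w = copy.deepcopy(self)
        if reseed is not None:
            w.rng = np.random.default_rng(reseed)
        return w

    # -- stepping ---------------------------------------------------------
    def run(
        self,
        duration_s: float,
        stimulus=None,
        record_stride: int = 1,
        label: str = "",
    ) -> SegmentResult:
        """Advance the world ``duration_s`` seconds against ``stimulus``.

        The stimulus stream (or None) is bound for the whole call; its
        frames loop if shorter than the segment.  Perception resets at
        the segment boundary (no loom is attributed to the stimulus
        switch itself).
        """
        cfg = self.config
        n_steps = int(round(duration_s / cfg.dt_s))
        if n_steps < 0:
            raise ValueError("duration must be >= 0")
        if stimulus is not None:
            dots = stimulus.frames_for_dt(cfg.dt_s)
            focal = 1 if stimulus.frame_ref == "focal" else 0
        else:
            dots = _EMPTY_DOTS
            focal = 0
        self._reset_prev()

        n = self.n_agents
        stride = int(record_stride)
        n_rec = n_steps // stride if stride > 0 else 0
        rec = [np.empty((n_rec, n)) for _ in range(7)]
        cap = int(n_steps * cfg.bout_prob_per_step * n * 2 + 64)
        bl_agent = np.empty(cap, dtype=np.int64)
        bl_onset = np.empty(cap, dtype=np.int64)
        bl_turn = np.empty(cap)
        bl_docc = np.empty(cap)
        bl_wall = np.empty(cap)
        bl_ae = np.empty(cap)
        bl_s = np.empty(cap)
        bl_away = np.empty(cap, dtype=np.int64)
        bl_social = np.empty(cap, dtype=np.int64)

        nb, nrec = K.run_world(
            self.x, self.y, self.heading, self.s,
            self.prev_x, self.prev_y, self.prev_h,
            self.bout_left, self.bout_dx, self.bout_dy,
            dots, focal, 0,
            n_steps, self.step_count,
            cfg.kernel_params(), self.rng, stride,
            rec[0], rec[1], rec[2], rec[3], rec[4], rec[5], rec[6],
            bl_agent, bl_onset, bl_turn, bl_docc, bl_wall, bl_ae, bl_s,
            bl_away, bl_social,
        )
        t0 = self.clock_s
        step0 = self.step_count
        self.step_count += n_steps
        self.clock_s += n_steps * cfg.dt_s

        local_steps = (np.arange(n_rec) + 1) * stride - 1
        times = t0 + (local_steps + 1) * cfg.dt_s
        onset_t = bl_onset[:nb] * cfg.dt_s
        bouts = pd.DataFrame(
            {
                "agent_id": bl_agent[:nb],
                "onset_step": bl_onset[:nb],
                "onset_time_s": onset_t,
                "offset_time_s": onset_t + cfg.bout_steps * cfg.dt_s,
                "duration_ms": np.full(nb, cfg.bout_steps * cfg.dt_s * 1000.0),
                "turn_deg": bl_turn[:nb],
                "docc_deg": bl_docc[:nb],
                "wall_dist_bl": bl_wall[:nb],
                "a_eff": bl_ae[:nb],
                "s": bl_s[:nb],
                "turned_away": bl_away[:nb],
                "mode": pd.Categorical.from_codes(
                    np.clip(bl_social[:nb], 0, 2),
                    categories=["wall", "spontaneous", "social"],
                ),
            }
        )
        return SegmentResult(
            label=label,
            times_s=times[:nrec],
            local_steps=local_steps[:nrec],
            agent_ids=np.arange(n),
            x=rec[0][:nrec], y=rec[1][:nrec], heading=rec[2][:nrec],
            s=rec[3][:nrec], loom_input=rec[4][:nrec], a_eff=rec[5][:nrec],
            bouting=rec[6][:nrec], bouts=bouts, stimulus=stimulus,
        )

    def step(self, stimulus=None) -> "World":
        """Advance a single time step (thin wrapper over :meth:`run`)."""
        self.run(self.config.dt_s, stimulus=stimulus, record_stride=1)
        return self


def step_world(world: World, stimulus=None) -> World:
    """Advance ``world`` by one time step in place and return it."""
    return world.step(stimulus)


def resize_group(world: World, new_n: int, rng: np.random.Generator | None = None) -> World:
    """Shrink or grow the group in place (density split/merge).

    Shrinking removes uniformly sampled agents, leaving survivors
    untouched.  Growing places new agents at random poses within the
    initial-placement disc with internal states drawn from a normal
    distribution matched to the mean and SD of the current agents'
    states (clamped to the state bounds).
    """
    if new_n < 1:
        raise ValueError("new_n must be >= 1")
    rng = rng if rng is not None else world.rng
    n = world.n_agents
    if new_n == n:
        return world
    if new_n < n:
        keep = np.sort(rng.choice(n, size=new_n, replace=False))
        for name in ("x", "y", "heading", "s", "bout_left", "bout_dx", "bout_dy"):
            setattr(world, name, getattr(world, name)[keep])
        world._reset_prev()
        return world
    if n == 0:
        raise ValueError("cannot grow an empty world")
    mean, sd = float(world.s.mean()), float(world.s.std())
    n_new = new_n - n
    p = world.config.integrator
    s_new = np.clip(rng.normal(mean, sd, n_new), p.s_min, p.s_max)
    world._append_agents(n_new, s_values=s_new)
    return world


def run_session(
    config: SimulationConfig,
    protocol: Sequence[Segment],
    seed: int | None = None,
    n_agents: int = 1,
    record_stride: int = 1,
) -> SessionResult:
    """Execute a schedule of stimulus / group-size segments.

    Each segment either presents a stimulus stream to the current agents
    or first resizes the group to ``n_agents`` and then runs for its
    duration.  Trajectories and state traces are emitted at the record
    stride (1 = every step, i.e. 1/dt Hz).
    """
    if len(protocol) == 0:
        raise ValueError("protocol must contain at least one segment")
    world = World(config, n_agents=n_agents, seed=seed)
    out = []
    for k, seg in enumerate(protocol):
        if seg.n_agents is not None and seg.n_agents != world.n_agents:
            resize_group(world, seg.n_agents)
        res = world.run(
            seg.duration_s,
            stimulus=seg.stimulus,
            record_stride=record_stride,
            label=seg.label or f"segment_{k}",
        )
        out.append(res)
    return SessionResult(segments=out, config=config, seed=seed)
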