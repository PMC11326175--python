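"""Virtual-reality stimulus generators.

Every stimulus is a :class:`StimulusStream`: a time-indexed field of
dark dots (position, radius) presented to a focal fish.  World-frame
streams (trajectory replay, stationary dots, looming hexagon) place
dots in arena coordinates; focal-frame streams (rotational rings,
single dot) are defined egocentrically — x forward, y to the left of
the heading — and are re-anchored to the focal animal every simulation
step, as in closed-loop VR.

Generators cover the experimental protocols: replay of (surrogate or
recorded) conspecific trajectories as 1.5 cm dots, a frozen frame of
such a replay (stationary control), dots circling the focal fish on
rings at the modal k-th-nearest-neighbor distances (translation without
looming), a hexagonal formation of stationary dots whose radii grow and
shrink (looming without translation), and the three single-dot
protocols (constant size, approaching, growing).  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .simulator import SimulationConfig, World

__all__ = [
    "StimulusStream",
    "SingleDotProtocol",
    "surrogate_trajectories",
    "replay_stream",
    "stationary_frame_stream",
    "rotational_rings",
    "looming_hexagon",
    "single_dot_stream",
    "knn_distance_modes",
    "concat_groups",
]

DEFAULT_DOT_RADIUS_CM = 0.75  # dots of diameter 1.5 cm


@dataclass
class StimulusStream:
    """A sequence of dot frames at a fixed frame period.

    ``frames`` has shape (n_frames, n_dots, 3) with columns
    (x_cm, y_cm, radius_cm); a NaN x marks an absent dot.  Streams loop
    when presented for longer than their length (the restart introduces
    a momentary discontinuity, as in the experiments).
    """

    frames: np.ndarray
    frame_period_s: float
    frame_ref: Literal["world", "focal"] = "world"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_dots, 3)")
        if self.frames.shape[0] == 0:
            raise ValueError("stream must contain at least one frame")
        if not self.frame_period_s > 0:
            raise ValueError("frame period must be > 0")
        radii = self.frames[:, :, 2]
        if np.any(radii[np.isfinite(radii)] < 0):
            raise ValueError("dot radii must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_dots(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    def dots_at(self, t_s: float) -> np.ndarray:
        """Dot field at time ``t_s`` (looping)."""
        idx = int(np.floor(t_s / self.frame_period_s)) % self.n_frames
        return self.frames[idx]

    def frames_for_dt(self, dt_s: float) -> np.ndarray:
        """Frames resampled (nearest index) onto the simulation step."""
        if abs(self.frame_period_s - dt_s) < 1e-12:
            return self.frames
        n_out = max(1, int(round(self.duration_s / dt_s)))
        src = (np.floor(np.arange(n_out) * dt_s / self.frame_period_s + 1e-9)
               .astype(int) % self.n_frames)
        return self.frames[src]

    def resampled(self, frame_period_s: float) -> "StimulusStream":
        """Same stimulus at a different frame rate (e.g. 60 Hz rig export)."""
        return StimulusStream(
            frames=self.frames_for_dt(frame_period_s),
            frame_period_s=frame_period_s,
            frame_ref=self.frame_ref,
            metadata=dict(self.metadata, resampled_from_s=self.frame_period_s),
        )

    def downsample(self, factor: int) -> "StimulusStream":
        """Keep every ``factor``-th frame: dots traverse the same paths
        ``factor`` times faster (the increased-speed protocol)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return StimulusStream(
            frames=self.frames[::factor],
            frame_period_s=self.frame_period_s,
            frame_ref=self.frame_ref,
            metadata=dict(self.metadata, speed_factor=factor),
        )

    def nearest_dot_distance(
        self, local_steps: np.ndarray, x: np.ndarray, y: np.ndarray
    ) -> np.ndarray:
        """Distance from each agent to its nearest dot (cm) per record.

        ``local_steps`` are simulation-step indices within the segment
        in which this stream was presented; ``x``/``y`` have shape
        (n_records, n_agents).
        """
        idx = np.asarray(local_steps, dtype=int) % self.n_frames
        dots = self.frames[idx]  # (n_rec, K, 3)
        dx = dots[:, :, 0]
        dy = dots[:, :, 1]
        valid = np.isfinite(dx) & (dots[:, :, 2] > 0)
        if self.frame_ref == "focal":
            d = np.hypot(dx, dy)
            d = np.where(valid, d, np.inf)
            return np.broadcast_to(d.min(axis=1)[:, None], x.shape).copy()
        diffx = x[:, None, :] - dx[:, :, None]
        diffy = y[:, None, :] - dy[:, :, None]
        d = np.hypot(diffx, diffy)
        d = np.where(valid[:, :, None], d, np.inf)
        return d.min(axis=1)

    # -- CSV round trip ---------------------------------------------------
    def to_csv(self, path: str | Path):
        n_f, n_d, _ = self.frames.shape
        t = np.repeat(np.arange(n_f) * self.frame_period_s, n_d)
        df = pd.DataFrame(
            {
                "time_s": t,
                "dot_id": np.tile(np.arange(n_d), n_f),
                "x_cm": self.frames[:, :, 0].ravel(),
                "y_cm": self.frames[:, :, 1].ravel(),
                "radius_cm": self.frames[:, :, 2].ravel(),
                "frame_ref": self.frame_ref,
            }
        )
        df.to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusStream":
        df = pd.read_csv(path)
        required = {"time_s", "dot_id", "x_cm", "y_cm", "radius_cm", "frame_ref"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"stimulus CSV missing columns: {sorted(missing)}")
        times = np.sort(df["time_s"].unique())
        n_d = int(df["dot_id"].max()) + 1
        frames = np.full((times.size, n_d, 3), np.nan)
        t_index = {t: i for i, t in enumerate(times)}
        rows_t = df["time_s"].map(t_index).to_numpy()
        rows_d = df["dot_id"].to_numpy(dtype=int)
        frames[rows_t, rows_d, 0] = df["x_cm"]
        frames[rows_t, rows_d, 1] = df["y_cm"]
        frames[rows_t, rows_d, 2] = df["radius_cm"]
        period = float(times[1] - times[0]) if times.size > 1 else 1.0 / 50.0
        return cls(frames=frames, frame_period_s=period,
                   frame_ref=str(df["frame_ref"].iloc[0]))


def _walker_config(config: SimulationConfig | None) -> SimulationConfig:
    from dataclasses import replace
    cfg = config if config is not None else SimulationConfig()
    return replace(cfg, social=False, integrator_enabled=False)


def surrogate_trajectories(
    n_fish: int,
    duration_s: float,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    record_stride: int = 1,
) -> pd.DataFrame:
    """Surrogate fish trajectories: independent bout-walkers in the arena.

    Fish draw bout timing, sizes and turn angles from the configured
    bout-statistics distributions but do not interact; wall avoidance
    confines them to the arena.  Used as source material for replay
    stimuli when recorded trajectories are not available.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    cfg = _walker_config(config)
    world = World(cfg, n_agents=n_fish, seed=seed)
    seg = world.run(duration_s, record_stride=record_stride, label="surrogate")
    df = seg.trajectory_table().rename(columns={"agent_id": "animal_id"})
    return df.drop(columns=["bouting"])


def _table_to_arrays(trajectories: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(times, positions (n_frames, n_fish, 2)) from a tidy trajectory table."""
    df = trajectories
    id_col = next(
        (c for c in ("animal_id", "fish_id", "agent_id") if c in df.columns), None
    )
    if id_col is None or "time_s" not in df.columns:
        raise ValueError("trajectory table needs time_s and an animal id column")
    piv_x = df.pivot_table(index="time_s", columns=id_col, values="x_cm")
    piv_y = df.pivot_table(index="time_s", columns=id_col, values="y_cm")
    pos = np.stack([piv_x.to_numpy(), piv_y.to_numpy()], axis=2)
    return piv_x.index.to_numpy(dtype=float), pos


def replay_stream(
    trajectories: pd.DataFrame,
    dot_radius_cm: float = DEFAULT_DOT_RADIUS_CM,
    loop: bool = True,
    frame_period_s: float | None = None,
) -> StimulusStream:
    """Present recorded/surrogate fish as dark dots at their positions.

    One dot per fish per frame, default radius 0.75 cm (1.5 cm
    diameter).  Streams loop by construction when presented past their
    end (``loop`` is retained for protocol metadata).
    """
    if len(trajectories) == 0:
        raise ValueError("empty trajectory table")
    times, pos = _table_to_arrays(trajectories)
    period = frame_period_s
    if period is None:
        period = float(times[1] - times[0]) if times.size > 1 else 1.0 / 50.0
    frames = np.concatenate(
        [pos, np.full(pos.shape[:2] + (1,), dot_radius_cm)], axis=2
    )
    return StimulusStream(
        frames=frames, frame_period_s=period, frame_ref="world",
        metadata={"protocol": "replay", "dot_radius_cm": dot_radius_cm, "loop": loop},
    )


def stationary_frame_stream(
    trajectories: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    duration_s: float | None = None,
    dot_radius_cm: float = DEFAULT_DOT_RADIUS_CM,
) -> StimulusStream:
    """A single randomly chosen replay frame, frozen for the whole
    presentation (stationary-dot control: occupancy without motion)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times, pos = _table_to_arrays(trajectories)
    k = int(rng.integers(0, pos.shape[0]))
    frame = np.concatenate(
        [pos[k], np.full((pos.shape[1], 1), dot_radius_cm)], axis=1
    )[None, :, :]
    return StimulusStream(
        frames=frame, frame_period_s=1.0 / 50.0, frame_ref="world",
        metadata={"protocol": "stationary", "source_frame": k,
                  "duration_s": duration_s},
    )


def knn_distance_modes(
    trajectories: pd.DataFrame, k_max: int, bin_cm: float = 0.05,
    frame_stride: int = 10,
) -> np.ndarray:
    """Histogram modes of the k-th nearest-neighbor distance, k=1..k_max."""
    _, pos = _table_to_arrays(trajectories)
    pos = pos[::frame_stride]
    n_fish = pos.shape[1]
    if n_fish < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} fish to estimate {k_max} NN modes")
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=3))
    d[:, np.arange(n_fish), np.arange(n_fish)] = np.inf
    d.sort(axis=2)
    modes = np.empty(k_max)
    for k in range(k_max):
        vals = d[:, :, k].ravel()
        vals = vals[np.isfinite(vals)]
        edges = np.arange(0.0, vals.max() + bin_cm, bin_cm)
        hist, _ = np.histogram(vals, bins=edges)
        j = int(hist.argmax())
        modes[k] = 0.5 * (edges[j] + edges[j + 1])
    return modes


def rotational_rings(
    source_trajectories: pd.DataFrame,
    n_dots: int = 19,
    rng: np.random.Generator | int | None = None,
    duration_s: float = 60.0,
    frame_period_s: float = 1.0 / 50.0,
    dot_radius_cm: float = DEFAULT_DOT_RADIUS_CM,
    config: SimulationConfig | None = None,
) -> StimulusStream:
    """Dots orbiting the focal fish on fixed rings: translation, no loom.

    Ring k sits at the modal distance of the k-th nearest neighbor in
    the source trajectories.  Each dot advances its angular position in
    bout-like steps (bout rate/duration/size from the simulation
    defaults; arc length per bout equals the bout displacement), with
    clockwise/counter-clockwise direction resampled per bout.  Dot
    distances to the focal fish are constant, so the stream evokes zero
    neighbor-induced looming.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = config if config is not None else SimulationConfig()
    radii = knn_distance_modes(source_trajectories, k_max=n_dots)
    n_frames = int(round(duration_s / frame_period_s))
    bout_p = cfg.bout_rate_hz * frame_period_s
    bout_steps = max(1, round(cfg.bout_duration_ms / 1000.0 / frame_period_s))

    theta = rng.uniform(-np.pi, np.pi, n_dots)
    remaining = np.zeros(n_dots, dtype=int)
    dtheta = np.zeros(n_dots)
    frames = np.empty((n_frames, n_dots, 3))
    n_bouts = np.zeros(n_dots, dtype=int)
    cw = np.zeros(n_dots, dtype=int)
    for t in range(n_frames):
        idle = remaining <= 0
        start = idle & (rng.random(n_dots) < bout_p)
        if start.any():
            direction = np.where(rng.random(n_dots) < 0.5, 1.0, -1.0)
            arc = cfg.bout_size_cm / radii  # radians traversed per bout
            dtheta[start] = direction[start] * arc[start] / bout_steps
            remaining[start] = bout_steps
            n_bouts[start] += 1
            cw[start] += (direction[start] < 0).astype(int)
        moving = remaining > 0
        theta[moving] += dtheta[moving]
        remaining[moving] -= 1
        frames[t, :, 0] = radii * np.cos(theta)
        frames[t, :, 1] = radii * np.sin(theta)
        frames[t, :, 2] = dot_radius_cm
    return StimulusStream(
        frames=frames, frame_period_s=frame_period_s, frame_ref="focal",
        metadata={
            "protocol": "rotational_rings", "radii_cm": radii.tolist(),
            "n_bouts": n_bouts.tolist(), "n_cw": cw.tolist(),
        },
    )


def _hex_lattice(n_points: int, spacing_cm: float) -> np.ndarray:
    """The ``n_points`` hexagonal-lattice points closest to the origin."""
    m = 4
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            px = spacing_cm * (i + 0.5 * j)
            py = spacing_cm * (np.sqrt(3) / 2.0) * j
            pts.append((px * px + py * py, px, py))
    pts.sort()
    return np.array([(p[1], p[2]) for p in pts[:n_points]])


def looming_hexagon(
    n_dots: int = 19,
    r_min_cm: float = 0.075,
    r_max_cm: float = 0.9,
    rng: np.random.Generator | int | None = None,
    duration_s: float = 60.0,
    frame_period_s: float = 1.0 / 50.0,
    spacing_cm: float = 1.2,
    grow_rate_cm_s: float = 0.8,
    switch_rate_hz: float = 1.64,
) -> StimulusStream:
    """Stationary dots in a hexagonal formation that loom: size change
    without translation.

    Dot radii follow a three-state (grow / shrink / hold) Markov
    schedule — a stochastic stand-in for resampled replay loom traces —
    clamped to [r_min, r_max]; positions never move.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pos = _hex_lattice(n_dots, spacing_cm)
    n_frames = int(round(duration_s / frame_period_s))
    rates = np.array([grow_rate_cm_s, -grow_rate_cm_s, 0.0]) * frame_period_s
    state = rng.integers(0, 3, n_dots)
    radii = rng.uniform(r_min_cm, r_max_cm, n_dots)
    p_switch = switch_rate_hz * frame_period_s
    frames = np.empty((n_frames, n_dots, 3))
    for t in range(n_frames):
        flip = rng.random(n_dots) < p_switch
        if flip.any():
            state[flip] = rng.integers(0, 3, int(flip.sum()))
        radii = np.clip(radii + rates[state], r_min_cm, r_max_cm)
        frames[t, :, 0] = pos[:, 0]
        frames[t, :, 1] = pos[:, 1]
        frames[t, :, 2] = radii
    return StimulusStream(
        frames=frames, frame_period_s=frame_period_s, frame_ref="world",
        metadata={"protocol": "looming_hexagon", "r_min_cm": r_min_cm,
                  "r_max_cm": r_max_cm},
    )


@dataclass(frozen=True)
class SingleDotProtocol:
    """Parameters of the tangentially sweeping single-dot stimulus.

    In every 5 s trial a dot appears on a randomly chosen side at
    |bearing| 75 deg and sweeps in bout-like steps to |bearing| 30 deg,
    with zero inter-trial gap.  The three kinds differ in their radius /
    distance schedules (linear in trial time):

    * ``moving``: radius 0.15 cm at distance 0.42 cm — constant ~40 deg.
    * ``moving_closer``: radius 0.075 cm, distance 0.92 -> 0.22 cm.
    * ``moving_growing``: distance 0.35 cm, radius 0.025 -> 0.13 cm.
    """

    kind: Literal["moving", "moving_closer", "moving_growing"] = "moving"
    trial_length_s: float = 5.0
    start_bearing_deg: float = 75.0
    end_bearing_deg: float = 30.0
    inter_stimulus_s: float = 0.0

    def schedules(self, frac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(radius_cm, distance_cm) at fractional trial time ``frac``."""
        if self.kind == "moving":
            return np.full_like(frac, 0.15), np.full_like(frac, 0.42)
        if self.kind == "moving_closer":
            return np.full_like(frac, 0.075), 0.92 + (0.22 - 0.92) * frac
        if self.kind == "moving_growing":
            return 0.025 + (0.13 - 0.025) * frac, np.full_like(frac, 0.35)
        raise ValueError(f"unknown single-dot kind {self.kind!r}")


def single_dot_stream(
    protocol: SingleDotProtocol,
    rng: np.random.Generator | int | None = None,
    duration_s: float = 60.0,
    frame_period_s: float = 1.0 / 50.0,
    config: SimulationConfig | None = None,
) -> StimulusStream:
    """Focal-frame stream of repeated single-dot trials.

    The bearing advances from 75 to 30 deg (sign = presentation side,
    drawn uniformly per trial) in bout-like steps: bout onsets follow
    the bout-rate Bernoulli process and the sweep is divided equally
    among the trial's bouts.  Returns trial metadata (side, onset) in
    ``metadata['trials']``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cfg = config if config is not None else SimulationConfig()
    n_frames = int(round(duration_s / frame_period_s))
    trial_frames = int(round(protocol.trial_length_s / frame_period_s))
    gap_frames = int(round(protocol.inter_stimulus_s / frame_period_s))
    bout_steps = max(1, round(cfg.bout_duration_ms / 1000.0 / frame_period_s))
    bout_p = cfg.bout_rate_hz * frame_period_s

    frames = np.full((n_frames, 1, 3), np.nan)
    trials = []
    t = 0
    while t < n_frames:
        side = 1.0 if rng.random() < 0.5 else -1.0
        # bout onsets within the trial
        onsets = [
            k for k in range(0, trial_frames - bout_steps + 1)
            if rng.random() < bout_p
        ]
        if not onsets:
            onsets = [0]
        step_deg = (protocol.end_bearing_deg - protocol.start_bearing_deg) / len(onsets)
        sweep = np.zeros(trial_frames)
        for o in onsets:
            inc = np.zeros(trial_frames)
            inc[o:o + bout_steps] = np.linspace(
                step_deg / bout_steps, step_deg, bout_steps
            )
            inc[o + bout_steps:] = step_deg
            sweep += inc
        bearing = protocol.start_bearing_deg + sweep
        frac = np.arange(trial_frames) / max(1, trial_frames - 1)
        radius, dist = protocol.schedules(frac)
        n_use = min(trial_frames, n_frames - t)
        th = np.radians(side * bearing[:n_use])
        frames[t:t + n_use, 0, 0] = dist[:n_use] * np.cos(th)
        frames[t:t + n_use, 0, 1] = dist[:n_use] * np.sin(th)
        frames[t:t + n_use, 0, 2] = radius[:n_use]
        trials.append({"onset_s": t * frame_period_s, "side": int(side),
                       "n_bouts": len(onsets)})
        t += trial_frames + gap_frames
    return StimulusStream(
        frames=frames, frame_period_s=frame_period_s, frame_ref="focal",
        metadata={"protocol": f"single_dot_{protocol.kind}", "trials": trials,
                  "trial_length_s": protocol.trial_length_s},
    )


def concat_groups(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge trajectory tables into one larger virtual group (e.g. two
    20-fish recordings presented together as 40 dots), offsetting ids."""
    out = []
    offset = 0
    for df in tables:
        id_col = next(c for c in ("animal_id", "fish_id", "agent_id") if c in df.columns)
        d = df.copy()
        d[id_col] = d[id_col] + offset
        d = d.rename(columns={id_col: "animal_id"})
        offset = int(d["animal_id"].max()) + 1
        out.append(d)
    merged = pd.concat(out, ignore_index=True)
    common = merged.groupby("animal_id")["time_s"].max().min()
    return merged[merged["time_s"] <= common].reset_index(drop=True)
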