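"""High-level experiment protocols built on the simulator and stimuli.

These routines reproduce, in silico, the density-switch protocols used
to characterize experience-dependent modulation: a single simulated
fish facing replayed virtual neighbors whose density changes over the
session, and groups of interacting agents that are split or merged.
They are the building blocks behind the reproduction checks in the test
suite and the acceptance script.

Standard conditions (not tuning knobs): virtual low density is 4
neighbors, high density 19; replay sources are 5 min of surrogate
trajectories presented in a loop; densities switch after 20 min of
exposure; 24 seeded repetitions per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import RecoveryFit, fit_recovery
from .simulator import SimulationConfig, World, repetition_seed, resize_group
from .stimuli import replay_stream, stationary_frame_stream, surrogate_trajectories

__all__ = [
    "bout_statistics",
    "make_replay",
    "RecoveryResult",
    "vr_recovery_experiment",
    "vr_exposure_experiment",
    "vr_stationary_null",
    "group_split_merge",
]

LOW_DENSITY = 4
HIGH_DENSITY = 19
SOURCE_MIN = 5.0  # minutes of surrogate source material per stream (looped)


def bout_statistics(
    seed: int, duration_s: float = 1200.0, config: SimulationConfig | None = None
) -> dict:
    """Emergent bout statistics of one unstimulated agent.

    Returns the bout rate (bouts per second of idle-inclusive elapsed
    time), the mean bout duration (ms) and mean bout path length (cm)
    from the simulator's own bout log, plus displacement measured from
    the trajectory.
    """
    cfg = config if config is not None else SimulationConfig()
    world = World(cfg, n_agents=1, seed=seed)
    seg = world.run(duration_s, record_stride=1, label="free_swim")
    bouts = seg.bouts
    rate = len(bouts) / duration_s
    # net displacement per bout from the trajectory record
    disp = []
    steps = cfg.bout_steps
    for onset in bouts["onset_step"].to_numpy():
        i0 = int(onset) - 1  # record index of the step before onset
        i1 = i0 + steps
        if i0 < 0 or i1 >= seg.x.shape[0]:
            continue
        disp.append(
            float(np.hypot(seg.x[i1, 0] - seg.x[i0, 0], seg.y[i1, 0] - seg.y[i0, 0]))
        )
    return {
        "bout_rate_hz": rate,
        "mean_duration_ms": float(bouts["duration_ms"].mean()) if len(bouts) else np.nan,
        "mean_displacement_cm": float(np.mean(disp)) if disp else np.nan,
        "n_bouts": len(bouts),
        "segment": seg,
    }


def make_replay(n_fish: int, seed: int, source_min: float = SOURCE_MIN,
                config: SimulationConfig | None = None):
    """A replay stream of ``n_fish`` surrogate fish (looped source)."""
    table = surrogate_trajectories(n_fish, source_min * 60.0, config=config, seed=seed)
    return replay_stream(table)


def _segment_nn(seg) -> float:
    """Mean agent-to-nearest-dot distance over a stimulated segment."""
    return float(seg.nn_to_stimulus().mean())


@dataclass
class RecoveryResult:
    """Outcome of the high-density -> zero-neighbor recovery protocol."""

    zero_minutes: np.ndarray          # probed 0-neighbor exposure times
    nn_probe: np.ndarray              # (n_reps, n_probes) probe NN, cm
    baseline: np.ndarray              # per-repetition baseline NN, cm
    fit: RecoveryFit                  # exponential fit to the rep-mean series
    time_to_baseline_min: float       # fitted curve re-attains the baseline
    band_crossing_min: float          # first probe inside the 5% band (mean)
    per_rep_ttb_min: np.ndarray       # per-repetition 5%-band crossings


def vr_recovery_experiment(
    seed: int,
    n_reps: int = 24,
    baseline_min: float = 20.0,
    high_min: float = 20.0,
    zero_minutes: tuple = (0, 10, 20, 30, 40, 50, 60, 80),
    probe_min: float = 20.0,
    band: float = 0.05,
    config: SimulationConfig | None = None,
    record_stride: int = 5,
) -> RecoveryResult:
    """Recovery of NN distance after high-density exposure.

    Per repetition: 20 min at low virtual density (baseline NN), 20 min
    at high density, then — branching from the same post-exposure state,
    as the experimental cohorts do — increasing durations of 0 neighbors
    each followed by a short low-density probe in which NN is measured.
    The repetition-mean NN(t) series is fitted with a single
    exponential.  The headline time-to-baseline is the time at which
    that fitted curve re-attains the mean pre-exposure baseline ("return
    to baseline"); the first probe falling inside a ``band`` fraction of
    the baseline is reported alongside (it triggers at partial recovery
    whenever the exposure effect exceeds the band width).
    """
    cfg = config if config is not None else SimulationConfig()
    zero_minutes = np.asarray(zero_minutes, dtype=float)
    nn = np.empty((n_reps, zero_minutes.size))
    baseline = np.empty(n_reps)
    ttb = np.full(n_reps, np.nan)
    for rep in range(n_reps):
        rs = repetition_seed(seed, rep)
        low = make_replay(LOW_DENSITY, rs + 1, config=cfg)
        high = make_replay(HIGH_DENSITY, rs + 2, config=cfg)
        world = World(cfg, n_agents=1, seed=rs)
        base_seg = world.run(baseline_min * 60.0, stimulus=low,
                             record_stride=record_stride, label="baseline_low")
        baseline[rep] = _segment_nn(base_seg)
        world.run(high_min * 60.0, stimulus=high, record_stride=record_stride,
                  label="high")
        for k, zm in enumerate(zero_minutes):
            branch = world.clone(reseed=rs + 100 + k)
            if zm > 0:
                branch.run(zm * 60.0, record_stride=50,
                           label="zero")
            probe = branch.run(probe_min * 60.0, stimulus=low,
                               record_stride=record_stride, label="probe_low")
            nn[rep, k] = _segment_nn(probe)
        inside = np.abs(nn[rep] - baseline[rep]) <= band * baseline[rep]
        if inside.any():
            ttb[rep] = zero_minutes[np.argmax(inside)]
    mean_series = nn.mean(axis=0)
    base = float(baseline.mean())
    fit = fit_recovery(zero_minutes * 60.0, mean_series, baseline=base, band=band)
    # time at which the fitted exponential crosses the baseline value
    num = fit.n_0 - fit.n_inf
    den = base - fit.n_inf
    if num != 0 and den != 0 and num / den > 1.0:
        t_cross = fit.lambda_s / 60.0 * np.log(num / den)
    else:
        # curve starts at/above baseline or never reaches it: fall back
        # to the first probe of the mean series inside the band
        inside = np.abs(mean_series - base) <= band * base
        t_cross = float(zero_minutes[np.argmax(inside)]) if inside.any() else np.nan
    band_cross = np.nan
    inside_mean = np.abs(mean_series - base) <= band * base
    if inside_mean.any():
        band_cross = float(zero_minutes[np.argmax(inside_mean)])
    return RecoveryResult(
        zero_minutes=zero_minutes,
        nn_probe=nn,
        baseline=baseline,
        fit=fit,
        time_to_baseline_min=float(t_cross),
        band_crossing_min=band_cross,
        per_rep_ttb_min=ttb,
    )


def vr_exposure_experiment(
    seed: int,
    n_reps: int = 24,
    exposure_minutes: tuple = (5, 10, 20, 40),
    baseline_min: float = 10.0,
    after_min: float = 10.0,
    config: SimulationConfig | None = None,
    record_stride: int = 5,
) -> dict:
    """ΔNN (after - before, at low density) vs high-density exposure time.

    Branches each repetition's post-baseline state into the different
    exposure durations so that exposure time is the only difference.
    Returns mean ΔNN per exposure time (expected to decrease with
    exposure).
    """
    cfg = config if config is not None else SimulationConfig()
    exposure_minutes = np.asarray(exposure_minutes, dtype=float)
    dnn = np.empty((n_reps, exposure_minutes.size))
    for rep in range(n_reps):
        rs = repetition_seed(seed, rep)
        low = make_replay(LOW_DENSITY, rs + 1, config=cfg)
        high = make_replay(HIGH_DENSITY, rs + 2, config=cfg)
        world = World(cfg, n_agents=1, seed=rs)
        base = world.run(baseline_min * 60.0, stimulus=low,
                         record_stride=record_stride, label="baseline")
        nn_before = _segment_nn(base)
        for k, em in enumerate(exposure_minutes):
            branch = world.clone(reseed=rs + 200 + k)
            branch.run(em * 60.0, stimulus=high, record_stride=record_stride,
                       label="high")
            after = branch.run(after_min * 60.0, stimulus=low,
                               record_stride=record_stride, label="after")
            dnn[rep, k] = _segment_nn(after) - nn_before
    return {
        "exposure_minutes": exposure_minutes,
        "delta_nn": dnn,
        "mean_delta_nn": dnn.mean(axis=0),
    }


def vr_stationary_null(
    seed: int,
    n_reps: int = 12,
    baseline_min: float = 10.0,
    exposure_min: float = 20.0,
    after_min: float = 10.0,
    config: SimulationConfig | None = None,
    record_stride: int = 5,
) -> dict:
    """Stationary high-density dots: no looming, hence no modulation.

    Pairs each repetition with a moving-replay exposure branch from the
    same baseline state, so the null (stationary) and the effect
    (moving) are directly comparable.  Also returns the state traces of
    the stationary branch, which should follow the zero-input decay.
    """
    cfg = config if config is not None else SimulationConfig()
    dnn_stat = np.empty(n_reps)
    dnn_move = np.empty(n_reps)
    s_start_stat = np.empty(n_reps)
    s_end_stat = np.empty(n_reps)
    loom_sum = np.empty(n_reps)
    for rep in range(n_reps):
        rs = repetition_seed(seed, rep)
        low = make_replay(LOW_DENSITY, rs + 1, config=cfg)
        source_high = surrogate_trajectories(
            HIGH_DENSITY, SOURCE_MIN * 60.0, config=cfg, seed=rs + 2
        )
        high = replay_stream(source_high)
        stat = stationary_frame_stream(source_high, rng=rs + 3)
        world = World(cfg, n_agents=1, seed=rs)
        base = world.run(baseline_min * 60.0, stimulus=low,
                         record_stride=record_stride, label="baseline")
        nn_before = _segment_nn(base)

        b_stat = world.clone(reseed=rs + 300)
        seg_stat = b_stat.run(exposure_min * 60.0, stimulus=stat,
                              record_stride=record_stride, label="stationary")
        after = b_stat.run(after_min * 60.0, stimulus=low,
                           record_stride=record_stride, label="after")
        dnn_stat[rep] = _segment_nn(after) - nn_before
        s_start_stat[rep] = seg_stat.s[0, 0]
        s_end_stat[rep] = seg_stat.s[-1, 0]
        loom_sum[rep] = float(seg_stat.loom_input.sum())

        b_move = world.clone(reseed=rs + 301)
        b_move.run(exposure_min * 60.0, stimulus=high,
                   record_stride=record_stride, label="moving")
        after_m = b_move.run(after_min * 60.0, stimulus=low,
                             record_stride=record_stride, label="after")
        dnn_move[rep] = _segment_nn(after_m) - nn_before
    return {
        "delta_nn_stationary": dnn_stat,
        "delta_nn_moving": dnn_move,
        "s_start": s_start_stat,
        "s_end": s_end_stat,
        "loom_sum": loom_sum,
        "exposure_min": exposure_min,
    }


def group_split_merge(
    seed: int,
    n_reps: int = 24,
    acclimate_min: float = 20.0,
    measure_min: float = 10.0,
    low_n: int = 5,
    high_n: int = 20,
    config: SimulationConfig | None = None,
    record_stride: int = 5,
) -> dict:
    """Density split/merge with fully interacting agents.

    Four arms per repetition: stay-low, high->low (split), stay-high and
    low->high (merge).  Pre-exposure to the opposite density should
    shift NN toward the previously experienced density: split groups
    swim closer than naive low groups, merged groups farther apart than
    naive high groups.
    """
    cfg = config if config is not None else SimulationConfig.group_defaults()

    def measure(world: World) -> float:
        seg = world.run(measure_min * 60.0, record_stride=record_stride,
                        label="measure")
        n = seg.x.shape[1]
        diffx = seg.x[:, :, None] - seg.x[:, None, :]
        diffy = seg.y[:, :, None] - seg.y[:, None, :]
        d = np.hypot(diffx, diffy)
        d[:, np.arange(n), np.arange(n)] = np.inf
        return float(d.min(axis=2).mean())

    out = {k: np.empty(n_reps) for k in
           ("nn_low", "nn_high_to_low", "nn_high", "nn_low_to_high")}
    for rep in range(n_reps):
        rs = repetition_seed(seed, rep)
        w_low = World(cfg, n_agents=low_n, seed=rs + 1)
        w_low.run(acclimate_min * 60.0, record_stride=50)
        out["nn_low"][rep] = measure(w_low)

        w_split = World(cfg, n_agents=high_n, seed=rs + 2)
        w_split.run(acclimate_min * 60.0, record_stride=50)
        resize_group(w_split, low_n)
        out["nn_high_to_low"][rep] = measure(w_split)

        w_high = World(cfg, n_agents=high_n, seed=rs + 3)
        w_high.run(acclimate_min * 60.0, record_stride=50)
        out["nn_high"][rep] = measure(w_high)

        w_merge = World(cfg, n_agents=low_n, seed=rs + 4)
        w_merge.run(acclimate_min * 60.0, record_stride=50)
        resize_group(w_merge, high_n)
        out["nn_low_to_high"][rep] = measure(w_merge)
    return out
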