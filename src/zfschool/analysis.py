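"""Trajectory-derived statistics and protocol summaries.

Operates on tidy trajectory tables (time_s, animal_id, x_cm, y_cm,
heading_deg): kinematics by central differences, bout detection from
speed, nearest-neighbor (NN) distance series with 60 s block averages,
shuffled (non-interacting) controls, turn-probability maps feeding the
slope estimator, before/after protocol summaries with exponential
recovery fits, and the cohort exclusion filters (immobility, low bout
rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .policy import estimate_slope
from .retina import wrap_angle

__all__ = [
    "kinematics",
    "detect_bouts",
    "NNSeries",
    "nn_series",
    "shuffled_control",
    "turn_probability_map",
    "delta_nn",
    "RecoveryFit",
    "fit_recovery",
    "protocol_summary",
    "apply_filters",
    "single_dot_blocks",
]


def _positions(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    id_col = next(
        (c for c in ("animal_id", "fish_id", "agent_id") if c in table.columns), None
    )
    if id_col is None or "time_s" not in table.columns:
        raise ValueError("trajectory table needs time_s and an animal id column")
    px = table.pivot_table(index="time_s", columns=id_col, values="x_cm")
    py = table.pivot_table(index="time_s", columns=id_col, values="y_cm")
    pos = np.stack([px.to_numpy(), py.to_numpy()], axis=2)
    return px.index.to_numpy(dtype=float), pos, list(px.columns)


def _check_uniform(times: np.ndarray) -> float:
    if times.size < 3:
        raise ValueError("need at least 3 frames")
    dt = np.diff(times)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        raise ValueError("irregular frame spacing")
    return float(dt[0])


def kinematics(table: pd.DataFrame) -> pd.DataFrame:
    """Central-difference velocities, speeds and motion directions.

    ``v(t) = [x(t+dt) - x(t-dt)] / 2dt``; endpoint frames are dropped.
    """
    times, pos, ids = _positions(table)
    dt = _check_uniform(times)
    v = (pos[2:] - pos[:-2]) / (2.0 * dt)
    speed = np.sqrt((v**2).sum(axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.degrees(np.arctan2(v[:, :, 1], v[:, :, 0]))
    n_t, n_a = speed.shape
    return pd.DataFrame(
        {
            "time_s": np.repeat(times[1:-1], n_a),
            "animal_id": np.tile(ids, n_t),
            "vx_cm_s": v[:, :, 0].ravel(),
            "vy_cm_s": v[:, :, 1].ravel(),
            "speed_cm_s": speed.ravel(),
            "direction_deg": direction.ravel(),
        }
    )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + x.size]
    return out


def detect_bouts(
    table: pd.DataFrame,
    speed_threshold_cm_s: float = 0.15,
    refractory_s: float = 0.04,
    smooth_frames: int = 3,
    arena_diameter_cm: float | None = None,
    fish_length_cm: float = 0.4,
) -> pd.DataFrame:
    """Detect bouts as supra-threshold speed intervals.

    Speed is boxcar-smoothed over ``smooth_frames``; maximal intervals
    above threshold separated by less than ``refractory_s`` are merged.
    The heading change of a bout is the wrapped difference of the
    heading column (if present, else the motion direction) between
    offset and onset.  Per-animal bout rates are in ``attrs``.
    """
    times, pos, ids = _positions(table)
    dt = _check_uniform(times)
    kin = kinematics(table)
    refractory = max(1, int(round(refractory_s / dt)))
    has_heading = "heading_deg" in table.columns
    id_col = next(c for c in ("animal_id", "fish_id", "agent_id") if c in table.columns)
    rows = []
    rates = {}
    for j, aid in enumerate(ids):
        sp = kin[kin["animal_id"] == aid]["speed_cm_s"].to_numpy()
        t_axis = times[1:-1]
        sps = _smooth(sp, smooth_frames)
        above = sps > speed_threshold_cm_s
        # maximal runs of True
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        starts, stops = edges[::2], edges[1::2]
        # merge runs separated by < refractory frames
        merged = []
        for s0, s1 in zip(starts, stops):
            if merged and s0 - merged[-1][1] < refractory:
                merged[-1] = (merged[-1][0], s1)
            else:
                merged.append((s0, s1))
        if has_heading:
            hcol = (
                table[table[id_col] == aid]
                .sort_values("time_s")["heading_deg"].to_numpy()[1:-1]
            )
        else:
            hcol = kin[kin["animal_id"] == aid]["direction_deg"].to_numpy()
        for s0, s1 in merged:
            stop = min(s1 - 1, t_axis.size - 1)
            onset_t, offset_t = t_axis[s0], t_axis[stop]
            dd = float(wrap_angle(hcol[min(stop, hcol.size - 1)] - hcol[s0]))
            x0 = pos[1 + s0, j, 0]
            y0 = pos[1 + s0, j, 1]
            row = {
                "animal_id": aid,
                "onset_time_s": onset_t,
                "offset_time_s": offset_t,
                "heading_change_deg": dd,
                "pre_x_cm": x0,
                "pre_y_cm": y0,
            }
            if arena_diameter_cm is not None:
                wall = (arena_diameter_cm / 2.0 - np.hypot(x0, y0)) / fish_length_cm
                row["wall_dist_bl"] = wall
            rows.append(row)
        duration = times[-1] - times[0]
        rates[aid] = len(merged) / duration if duration > 0 else np.nan
    out = pd.DataFrame(
        rows,
        columns=["animal_id", "onset_time_s", "offset_time_s",
                 "heading_change_deg", "pre_x_cm", "pre_y_cm"]
        + (["wall_dist_bl"] if arena_diameter_cm is not None else []),
    )
    out.attrs["bout_rate_hz"] = rates
    return out


@dataclass
class NNSeries:
    """Per-frame nearest-neighbor distances and their block averages."""

    times_s: np.ndarray
    per_animal: np.ndarray       # (n_frames, n_animals), cm
    animal_ids: list
    block_s: float
    block_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    block_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    condition: str = ""

    @property
    def group_mean(self) -> np.ndarray:
        return self.per_animal.mean(axis=1)

    def overall_mean(self) -> float:
        return float(self.per_animal.mean())


def nn_series(table: pd.DataFrame, block_s: float = 60.0, condition: str = "") -> NNSeries:
    """Nearest-neighbor distance of every animal at every frame.

    Requires at least two animals; block means are over non-overlapping
    ``block_s`` windows of the group-mean NN.
    """
    times, pos, ids = _positions(table)
    n = pos.shape[1]
    if n < 2:
        raise ValueError("nearest-neighbor series needs at least 2 animals")
    nn = np.empty((pos.shape[0], n))
    chunk = max(1, int(2e6 // (n * n)))
    for a in range(0, pos.shape[0], chunk):
        b = min(pos.shape[0], a + chunk)
        diff = pos[a:b, :, None, :] - pos[a:b, None, :, :]
        d = np.sqrt((diff**2).sum(axis=3))
        d[:, np.arange(n), np.arange(n)] = np.inf
        nn[a:b] = d.min(axis=2)
    series = NNSeries(times_s=times, per_animal=nn, animal_ids=ids,
                      block_s=block_s, condition=condition)
    t0 = times[0]
    idx = np.floor((times - t0) / block_s).astype(int)
    blocks = np.unique(idx)
    gm = series.group_mean
    series.block_times_s = np.array([t0 + (b + 0.5) * block_s for b in blocks])
    series.block_means = np.array([gm[idx == b].mean() for b in blocks])
    return series


def shuffled_control(
    tables: Sequence[pd.DataFrame],
    n_shuffles: int = 20,
    rng: np.random.Generator | int | None = None,
    group_size: int | None = None,
) -> np.ndarray:
    """NN baseline from pseudo-groups with interactions destroyed.

    Composite groups draw each member from a *different* source group
    where possible, filling remaining slots from already-used groups;
    every drawn animal receives an independent random circular time
    shift, removing temporal correlations.  Returns the mean NN of each
    shuffle.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(tables) < 2:
        raise ValueError("need at least 2 source groups")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    groups = []
    for tb in tables:
        _, pos, _ = _positions(tb)
        groups.append(pos)
    n_frames = min(g.shape[0] for g in groups)
    groups = [g[:n_frames] for g in groups]
    if group_size is None:
        group_size = groups[0].shape[1]
    pool = [(gi, ai) for gi, g in enumerate(groups) for ai in range(g.shape[1])]
    out = np.empty(n_shuffles)
    for srep in range(n_shuffles):
        chosen: list[tuple[int, int]] = []
        used_groups: set[int] = set()
        order = rng.permutation(len(pool))
        # pass 1: distinct source groups; pass 2: fill from anywhere
        for idx in order:
            gi, ai = pool[idx]
            if gi not in used_groups and len(chosen) < group_size:
                chosen.append((gi, ai))
                used_groups.add(gi)
        for idx in order:
            if len(chosen) >= group_size:
                break
            if pool[idx] not in chosen:
                chosen.append(pool[idx])
        members = np.empty((n_frames, len(chosen), 2))
        for k, (gi, ai) in enumerate(chosen):
            shift = int(rng.integers(0, n_frames))
            members[:, k, :] = np.roll(groups[gi][:, ai, :], shift, axis=0)
        diff = members[:, :, None, :] - members[:, None, :, :]
        d = np.sqrt((diff**2).sum(axis=3))
        m = len(chosen)
        d[:, np.arange(m), np.arange(m)] = np.inf
        out[srep] = d.min(axis=2).mean()
    return out


def turn_probability_map(
    bouts: pd.DataFrame,
    bin_width_deg: float = 5.0,
    wall_exclusion_bl: float = 1.25,
):
    """Binned P(turn away | occupancy difference) and the fitted slope.

    ``bouts`` must carry ``docc_deg``, ``turned_away`` (1/0; -1 marks
    symmetric scenes, which are dropped) and ``wall_dist_bl``.  Events
    nearer than ``wall_exclusion_bl`` body lengths to the wall are
    discarded before binning (5 deg bins at low density, 10 deg at high).
    """
    df = bouts[bouts["turned_away"] >= 0][["docc_deg", "turned_away", "wall_dist_bl"]]
    curve, table = estimate_slope(
        df, bin_width_deg=bin_width_deg, wall_exclusion_bl=wall_exclusion_bl
    )
    return curve, table


def delta_nn(nn_before: NNSeries | float, nn_after: NNSeries | float) -> float:
    """Mean change (after - before) in nearest-neighbor distance (cm)."""
    before = nn_before.overall_mean() if isinstance(nn_before, NNSeries) else float(nn_before)
    after = nn_after.overall_mean() if isinstance(nn_after, NNSeries) else float(nn_after)
    return after - before


@dataclass(frozen=True)
class RecoveryFit:
    """Single-exponential recovery of NN distance toward baseline."""

    n_inf: float
    n_0: float
    lambda_s: float
    r_squared: float
    time_to_baseline_s: float | None


def fit_recovery(
    times_s: np.ndarray,
    nn_values: np.ndarray,
    baseline: float,
    band: float = 0.05,
) -> RecoveryFit:
    """Fit ``N(t) = N_inf + (N_0 - N_inf) exp(-t/lambda)`` to a recovery series.

    ``time_to_baseline_s`` is the first sample time whose NN lies within
    ``band`` (fractional) of ``baseline``; None if never reached.
    Requires at least 4 samples.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(nn_values, dtype=float)
    if t.size < 4:
        raise ValueError("recovery fit needs at least 4 blocks")

    def model(tt, n_inf, n_0, lam):
        return n_inf + (n_0 - n_inf) * np.exp(-tt / lam)

    span = max(t[-1] - t[0], 1.0)
    p0 = [y[-1], y[0], span / 3.0]
    popt, _ = curve_fit(
        model, t, y, p0=p0,
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    inside = np.abs(y - baseline) <= band * abs(baseline)
    ttb = float(t[np.argmax(inside)]) if inside.any() else None
    return RecoveryFit(
        n_inf=float(popt[0]), n_0=float(popt[1]), lambda_s=float(popt[2]),
        r_squared=r2, time_to_baseline_s=ttb,
    )


def protocol_summary(
    nn_before: NNSeries,
    nn_after: NNSeries,
    fit_recovery_curve: bool = False,
    baseline: float | None = None,
) -> dict:
    """Before/after ΔNN and, optionally, the exponential recovery fit on
    the after-segment block means."""
    out = {"delta_nn_cm": delta_nn(nn_before, nn_after)}
    if fit_recovery_curve:
        base = baseline if baseline is not None else nn_before.overall_mean()
        t = nn_after.block_times_s - nn_after.block_times_s[0]
        fit = fit_recovery(t, nn_after.block_means, base)
        out["recovery"] = fit
    return out


def apply_filters(
    tables: Sequence[pd.DataFrame],
    mode: str = "group",
    immobility_speed_cm_s: float = 0.05,
    immobility_fraction: float = 0.5,
    min_bout_rate_hz: float = 0.25,
    smooth_frames: int = 5,
    bout_kwargs: dict | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Cohort exclusion rules.

    ``group`` mode drops a whole group when any member is immobile
    (smoothed speed below ``immobility_speed_cm_s``) for more than half
    of the experiment.  ``single`` mode drops animals with bout rates
    below 0.25 Hz.  Returns (retained tables, exclusion log).
    """
    retained = []
    log_rows = []
    for gi, tb in enumerate(tables):
        kin = kinematics(tb)
        excluded = False
        if mode == "group":
            for aid, sub in kin.groupby("animal_id"):
                frac = float(
                    (_smooth(sub["speed_cm_s"].to_numpy(), smooth_frames)
                     < immobility_speed_cm_s).mean()
                )
                if frac > immobility_fraction:
                    log_rows.append(
                        {"group": gi, "animal_id": aid, "reason": "immobile",
                         "value": frac}
                    )
                    excluded = True
        elif mode == "single":
            bouts = detect_bouts(tb, **(bout_kwargs or {}))
            for aid, rate in bouts.attrs["bout_rate_hz"].items():
                if rate < min_bout_rate_hz:
                    log_rows.append(
                        {"group": gi, "animal_id": aid, "reason": "low_bout_rate",
                         "value": rate}
                    )
                    excluded = True
        else:
            raise ValueError("mode must be 'group' or 'single'")
        if not excluded:
            retained.append(tb)
    return retained, pd.DataFrame(log_rows, columns=["group", "animal_id", "reason", "value"])


def single_dot_blocks(
    trials: pd.DataFrame, block_trials: int = 60
) -> tuple[np.ndarray, pd.DataFrame]:
    """Blockwise probability of turning away from the presented side.

    ``trials`` needs columns ``side`` (+1 left / -1 right), ``n_left``
    and ``n_right`` (turn counts within the trial).  Per-trial P(away)
    is the fraction of turns away from the presented side among
    left/right turns; trials with zero turns are skipped and logged.
    Blocks are consecutive runs of ``block_trials`` trials (partial
    trailing blocks are reported separately in the log).
    """
    df = trials.copy()
    total = df["n_left"] + df["n_right"]
    skipped = df[total == 0]
    df = df[total > 0]
    away = np.where(df["side"] > 0, df["n_right"], df["n_left"])
    p_away = away / (df["n_left"] + df["n_right"])
    n_full = len(df) // block_trials
    blocks = np.array(
        [p_away.iloc[b * block_trials:(b + 1) * block_trials].mean()
         for b in range(n_full)]
    )
    log = pd.DataFrame(
        {
            "skipped_trials": [len(skipped)],
            "remainder_trials": [len(df) - n_full * block_trials],
        }
    )
    return blocks, log
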