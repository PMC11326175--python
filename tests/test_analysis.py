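"""Trajectory statistics: kinematics, bouts, NN metrics, summaries."""

import numpy as np
import pandas as pd
import pytest

from zfschool import SimulationConfig, World, surrogate_trajectories
from zfschool.analysis import (
    apply_filters,
    delta_nn,
    detect_bouts,
    fit_recovery,
    kinematics,
    nn_series,
    protocol_summary,
    shuffled_control,
    single_dot_blocks,
    turn_probability_map,
)


def make_table(times, positions, headings=None):
    """positions: dict animal_id -> (n, 2) array."""
    rows = []
    for aid, pos in positions.items():
        for k, t in enumerate(times):
            rows.append(
                {
                    "time_s": t,
                    "animal_id": aid,
                    "x_cm": pos[k, 0],
                    "y_cm": pos[k, 1],
                    "heading_deg": 0.0 if headings is None else headings[k],
                }
            )
    return pd.DataFrame(rows)


class TestKinematics:
    def test_linear_motion_speed(self):
        t = np.arange(0, 2, 0.02)
        pos = np.stack([t * 1.0, np.zeros_like(t)], axis=1)
        kin = kinematics(make_table(t, {0: pos}))
        assert np.allclose(kin["speed_cm_s"], 1.0, atol=1e-9)

    def test_stationary_speed_zero(self):
        t = np.arange(0, 1, 0.02)
        pos = np.full((t.size, 2), 1.3)
        kin = kinematics(make_table(t, {0: pos}))
        assert np.allclose(kin["speed_cm_s"], 0.0)

    def test_circular_motion_second_order_accurate(self):
        R, omega, dt = 1.0, 1.0, 1.0 / 50.0
        t = np.arange(0, 5, dt)
        pos = np.stack([R * np.cos(omega * t), R * np.sin(omega * t)], axis=1)
        kin = kinematics(make_table(t, {0: pos}))
        # central difference: speed = R*omega*sinc(omega*dt), error O(dt^2)
        assert np.allclose(kin["speed_cm_s"], R * omega, rtol=1e-4)

    def test_irregular_spacing_rejected(self):
        t = np.array([0.0, 0.02, 0.05, 0.06])
        pos = np.zeros((4, 2))
        with pytest.raises(ValueError, match="irregular"):
            kinematics(make_table(t, {0: pos}))


class TestDetectBouts:
    def test_stationary_no_bouts(self):
        t = np.arange(0, 5, 0.02)
        bouts = detect_bouts(make_table(t, {0: np.zeros((t.size, 2))}))
        assert len(bouts) == 0

    def test_ground_truth_recovery_sparse_bouts(self):
        # at a low bout rate, bouts are well separated and the detector
        # must find each one
        cfg = SimulationConfig(bout_rate_hz=0.2)
        w = World(cfg, 1, seed=31)
        seg = w.run(240.0, record_stride=1)
        table = seg.trajectory_table().rename(columns={"agent_id": "animal_id"})
        bouts = detect_bouts(table)
        assert abs(len(bouts) - len(seg.bouts)) <= max(1, 0.05 * len(seg.bouts))

    def test_default_rate_approximately_recovered(self):
        # at 1.64 Hz some inter-bout gaps fall below the detector's
        # temporal resolution, so a modest undercount is expected
        w = World(SimulationConfig(), 1, seed=32)
        seg = w.run(300.0, record_stride=1)
        table = seg.trajectory_table().rename(columns={"agent_id": "animal_id"})
        bouts = detect_bouts(table)
        rate = list(bouts.attrs["bout_rate_hz"].values())[0]
        true_rate = len(seg.bouts) / 300.0
        assert rate <= true_rate + 0.05
        assert rate >= 0.8 * true_rate


class TestNNSeries:
    def test_constant_pair(self):
        t = np.arange(0, 120, 0.1)
        a = np.zeros((t.size, 2))
        b = np.stack([np.ones(t.size), np.zeros(t.size)], axis=1)
        nn = nn_series(make_table(t, {0: a, 1: b}))
        assert np.allclose(nn.per_animal, 1.0)
        assert np.allclose(nn.block_means, 1.0)

    def test_collinear_triplet(self):
        t = np.arange(0, 1, 0.1)
        pos = {
            0: np.tile([0.0, 0.0], (t.size, 1)),
            1: np.tile([1.0, 0.0], (t.size, 1)),
            2: np.tile([3.0, 0.0], (t.size, 1)),
        }
        nn = nn_series(make_table(t, pos))
        assert np.allclose(nn.per_animal[0], [1.0, 1.0, 2.0])

    def test_rigid_transform_invariance(self, rng):
        t = np.arange(0, 2, 0.02)
        pos = {i: rng.uniform(-2, 2, (t.size, 2)) for i in range(4)}
        nn1 = nn_series(make_table(t, pos))
        ang = 0.83
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = {i: p @ rot.T + [1.2, -0.7] for i, p in pos.items()}
        nn2 = nn_series(make_table(t, moved))
        assert np.allclose(nn1.per_animal, nn2.per_animal, atol=1e-9)

    def test_dilation_scales_monotonically(self, rng):
        t = np.arange(0, 1, 0.02)
        pos = {i: rng.uniform(-2, 2, (t.size, 2)) for i in range(3)}
        nn1 = nn_series(make_table(t, pos))
        nn2 = nn_series(make_table(t, {i: 2.0 * p for i, p in pos.items()}))
        assert np.allclose(nn2.per_animal, 2.0 * nn1.per_animal)

    def test_single_animal_rejected(self):
        t = np.arange(0, 1, 0.02)
        with pytest.raises(ValueError):
            nn_series(make_table(t, {0: np.zeros((t.size, 2))}))


class TestShuffledControl:
    def test_noninteracting_walkers_are_null(self):
        # for independent walkers, shuffling destroys nothing: observed
        # NN is within the Monte-Carlo spread of the shuffled NN
        tables = [surrogate_trajectories(5, 120.0, seed=200 + k,
                                         record_stride=5)
                  for k in range(4)]
        obs = np.mean([nn_series(tb).overall_mean() for tb in tables])
        sh = shuffled_control(tables, n_shuffles=30, rng=7)
        assert abs(obs - sh.mean()) < 3 * sh.std() + 0.02

    def test_repulsive_agents_overdispersed(self):
        # interacting (repulsive) groups keep larger NN than shuffled
        cfg = SimulationConfig.group_defaults()
        tables = []
        for k in range(3):
            w = World(cfg, 5, seed=300 + k)
            seg = w.run(300.0, record_stride=5)
            tables.append(
                seg.trajectory_table().rename(columns={"agent_id": "animal_id"})
            )
        obs = np.mean([nn_series(tb).overall_mean() for tb in tables])
        sh = shuffled_control(tables, n_shuffles=20, rng=8)
        assert obs > sh.mean()

    def test_zero_shuffles_rejected(self):
        tables = [surrogate_trajectories(2, 5.0, seed=1),
                  surrogate_trajectories(2, 5.0, seed=2)]
        with pytest.raises(ValueError):
            shuffled_control(tables, n_shuffles=0)


class TestTurnProbabilityMap:
    def test_bin_count(self):
        rng = np.random.default_rng(0)
        docc = rng.uniform(0, 59.999, 5000)
        df = pd.DataFrame(
            {
                "docc_deg": docc,
                "turned_away": (rng.random(5000) < 0.6).astype(int),
                "wall_dist_bl": 5.0,
            }
        )
        _, table = turn_probability_map(df, bin_width_deg=5.0)
        assert len(table) == 12

    def test_all_wall_events_error(self):
        df = pd.DataFrame(
            {"docc_deg": [5.0] * 10, "turned_away": [1] * 10,
             "wall_dist_bl": [0.3] * 10}
        )
        with pytest.raises(ValueError, match="no analyzable"):
            turn_probability_map(df)

    def test_simulated_events_recover_slope(self, vr_config):
        # end-to-end: bouts logged by the simulator under a frozen
        # internal state recover the generating slope
        from dataclasses import replace
        from zfschool.experiments import make_replay
        cfg = replace(vr_config, integrator_enabled=False)
        w = World(cfg, 1, seed=33)
        seg = w.run(3600.0, stimulus=make_replay(19, 34), record_stride=0)
        # restrict to the linear (unclamped) range and push the wall
        # exclusion out past the logistic wall-policy tail, whose
        # wall-driven turns would otherwise dilute the social slope
        bouts = seg.bouts[seg.bouts["docc_deg"] < 40.0]
        curve, table = turn_probability_map(
            bouts, bin_width_deg=10.0, wall_exclusion_bl=2.5
        )
        se = table.attrs["slope_se"]
        assert abs(curve.slope - cfg.a) < max(2 * se, 0.1 * cfg.a)


class TestProtocolSummary:
    def test_identical_series_zero_delta(self):
        t = np.arange(0, 120, 0.1)
        a = np.zeros((t.size, 2))
        b = np.stack([np.ones(t.size), np.zeros(t.size)], axis=1)
        nn = nn_series(make_table(t, {0: a, 1: b}))
        assert delta_nn(nn, nn) == 0.0

    def test_exact_exponential_recovered(self):
        lam = 900.0
        t = np.arange(0, 3600, 60.0)
        y = 1.6 + (1.2 - 1.6) * np.exp(-t / lam)
        fit = fit_recovery(t, y, baseline=1.6)
        assert fit.lambda_s == pytest.approx(lam, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        # analytic band crossing: |y - 1.6| <= 5% of 1.6
        expected = t[np.abs(y - 1.6) <= 0.08][0]
        assert fit.time_to_baseline_s == expected

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            fit_recovery([0, 60, 120], [1.0, 1.1, 1.2], baseline=1.2)


class TestApplyFilters:
    def _moving_table(self, speed, duration=30.0, dt=0.02):
        t = np.arange(0, duration, dt)
        pos = np.stack([speed * t, np.zeros_like(t)], axis=1)
        return t, pos

    def test_immobile_group_excluded(self):
        t, moving = self._moving_table(1.0)
        frozen = np.zeros((t.size, 2))
        bad = make_table(t, {0: moving, 1: frozen})
        good = make_table(t, {0: moving, 1: moving + 1.0})
        kept, log = apply_filters([bad, good], mode="group")
        assert len(kept) == 1
        assert (log["reason"] == "immobile").all()

    def test_low_bout_rate_excluded(self):
        cfg_slow = SimulationConfig(bout_rate_hz=0.1)
        slow = surrogate_trajectories(1, 120.0, config=cfg_slow, seed=40)
        active = surrogate_trajectories(1, 120.0, seed=41)
        kept, log = apply_filters([slow, active], mode="single")
        assert len(kept) == 1
        assert (log["reason"] == "low_bout_rate").all()

    def test_all_active_retained(self):
        tables = [surrogate_trajectories(2, 60.0, seed=50 + k) for k in range(2)]
        kept, log = apply_filters(tables, mode="group")
        assert len(kept) == 2 and len(log) == 0


class TestSingleDotBlocks:
    def test_all_away(self):
        trials = pd.DataFrame(
            {"side": [1] * 120, "n_left": [0] * 120, "n_right": [3] * 120}
        )
        blocks, log = single_dot_blocks(trials, block_trials=60)
        assert np.allclose(blocks, 1.0)
        assert log["remainder_trials"].iloc[0] == 0

    def test_random_turning_near_half(self, rng):
        n = 600
        nl = rng.binomial(6, 0.5, n)
        trials = pd.DataFrame(
            {"side": rng.choice([-1, 1], n), "n_left": nl, "n_right": 6 - nl}
        )
        blocks, _ = single_dot_blocks(trials, block_trials=60)
        assert np.allclose(blocks, 0.5, atol=0.1)

    def test_remainder_logged(self):
        trials = pd.DataFrame(
            {"side": [1] * 150, "n_left": [1] * 150, "n_right": [1] * 150}
        )
        blocks, log = single_dot_blocks(trials, block_trials=60)
        assert blocks.size == 2
        assert log["remainder_trials"].iloc[0] == 30

    def test_zero_turn_trials_skipped(self):
        trials = pd.DataFrame(
            {"side": [1, 1], "n_left": [0, 1], "n_right": [0, 1]}
        )
        _, log = single_dot_blocks(trials, block_trials=1)
        assert log["skipped_trials"].iloc[0] == 1
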