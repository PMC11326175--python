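"""Visual-field geometry: bearings, occupancy, occlusion, looming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfschool import (
    BodyPose,
    VisualObject,
    looming_input,
    occupancy_profile,
    relative_bearing,
    vertical_occupancy,
    wrap_angle,
)
from conftest import random_scene


class TestBearing:
    def test_dead_ahead(self, origin_pose):
        assert relative_bearing(origin_pose, (1.0, 0.0)) == pytest.approx(0.0)

    def test_left_orthogonal(self, origin_pose):
        assert relative_bearing(origin_pose, (0.0, 1.0)) == pytest.approx(90.0)

    def test_rotated_frame_oracle(self, rng):
        # bearing in the fish frame must equal the angle of the target
        # after rotating the world by -heading (2-D rotation matrix)
        for _ in range(200):
            focal = BodyPose(*rng.uniform(-2, 2, 2), rng.uniform(-180, 180))
            target = rng.uniform(-3, 3, 2)
            if np.hypot(*(target - focal.xy)) < 1e-3:
                continue
            c, s = np.cos(np.radians(-focal.heading_deg)), np.sin(
                np.radians(-focal.heading_deg)
            )
            rel = target - focal.xy
            rot = np.array([c * rel[0] - s * rel[1], s * rel[0] + c * rel[1]])
            expected = np.degrees(np.arctan2(rot[1], rot[0]))
            assert relative_bearing(focal, target) == pytest.approx(expected, abs=1e-9)
        assert relative_bearing(BodyPose(0, 0, 90), (1.0, 0.0)) == pytest.approx(-90.0)

    def test_coincident_raises(self, origin_pose):
        with pytest.raises(ValueError):
            relative_bearing(origin_pose, (0.0, 0.0))

    @given(st.floats(-1e4, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_wrap_angle_range(self, a):
        w = float(wrap_angle(a))
        assert -180.0 < w <= 180.0
        assert abs((a - w) % 360.0) < 1e-6 or abs((a - w) % 360.0 - 360.0) < 1e-6


class TestVerticalOccupancy:
    def test_printed_dot_sizes(self):
        # single-dot stimulus geometry: ~40 deg and ~9 deg
        assert vertical_occupancy(0.15, 0.42) == pytest.approx(39.31, abs=0.05)
        assert vertical_occupancy(0.075, 0.92) == pytest.approx(9.33, abs=0.05)

    def test_zero_extent(self):
        assert vertical_occupancy(0.0, 1.7) == 0.0

    def test_monotone_in_distance(self):
        d = np.linspace(0.1, 5, 200)
        v = vertical_occupancy(0.2, d)
        assert np.all(np.diff(v) < 0)

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            vertical_occupancy(0.1, 0.0)

    def test_brute_force_subtense_oracle(self, rng):
        # sample 1e5 points on the vertical extent [-H, H] at distance d
        # and measure the spanned elevation angle directly
        for _ in range(5):
            h = rng.uniform(0.05, 1.0)
            d = rng.uniform(0.2, 4.0)
            ys = np.linspace(-h, h, 100_000)
            angles = np.degrees(np.arctan2(ys, d))
            assert vertical_occupancy(h, d) == pytest.approx(
                angles.max() - angles.min(), abs=0.01
            )


class TestOccupancyProfile:
    def test_empty_scene(self, origin_pose):
        left, right = occupancy_profile(origin_pose, [])
        assert left.is_empty and right.is_empty
        assert left.total_vertical() == 0.0

    def test_zero_bearing_tiebreak_right_eye(self, origin_pose):
        left, right = occupancy_profile(
            origin_pose, [VisualObject(1.0, 0.0, 0.1, obj_id=7)]
        )
        assert left.is_empty
        assert list(right.object_ids) == [7]

    def test_blind_zone_excluded(self, origin_pose):
        # object directly behind (bearing 180) is invisible
        left, right = occupancy_profile(origin_pose, [VisualObject(-1.0, 0.0, 0.1)])
        assert left.is_empty and right.is_empty

    def test_mirror_symmetry_swaps_eyes(self, rng, origin_pose):
        objs = random_scene(rng, 6)
        mirrored = [
            VisualObject(o.x, -o.y, o.half_extent, obj_id=o.obj_id) for o in objs
        ]
        for mode in ("per_object", "rasterized"):
            l1, r1 = occupancy_profile(origin_pose, objs, mode=mode)
            l2, r2 = occupancy_profile(origin_pose, mirrored, mode=mode)
            assert np.allclose(np.sort(l1.occupancy_deg), np.sort(r2.occupancy_deg))
            assert np.allclose(np.sort(r1.occupancy_deg), np.sort(l2.occupancy_deg))
            assert np.allclose(np.sort(l1.bearings_deg), np.sort(-r2.bearings_deg))

    def test_rasterized_total_bounded(self, rng, origin_pose):
        objs = random_scene(rng, 12, spread=1.0)
        left, right = occupancy_profile(origin_pose, objs, mode="rasterized")
        assert left.total_horizontal() <= 165.0
        assert right.total_horizontal() <= 165.0

    def test_occlusion_nearer_object_wins(self, origin_pose):
        near = VisualObject(1.0, 0.0, 0.1, obj_id=1)
        far = VisualObject(2.0, 0.0, 0.1, obj_id=2)
        _, right = occupancy_profile(origin_pose, [far, near], mode="rasterized")
        covered_by_near = right.object_ids == 1
        assert covered_by_near.all()
        assert np.allclose(
            right.occupancy_deg, vertical_occupancy(0.1, 1.0), atol=1e-9
        )

    def test_rasterized_matches_ray_casting(self, rng, origin_pose):
        # 0.01-deg ray casting oracle; interior cells must agree exactly,
        # cells straddling a coverage boundary may differ by one cell
        for _ in range(5):
            objs = random_scene(rng, 5, spread=1.5)
            # the blind-zone rule applies to object centers
            objs = [
                o for o in objs
                if abs(np.degrees(np.arctan2(o.y, o.x))) <= 165.0
            ]
            left, right = occupancy_profile(origin_pose, objs, mode="rasterized")
            got = {}
            for prof in (left, right):
                for b, v in zip(prof.bearings_deg, prof.occupancy_deg):
                    got[round(b * 2) / 2] = v
            rays = np.arange(-165.0, 165.0, 0.01)
            theta = np.array(
                [np.degrees(np.arctan2(o.y, o.x)) for o in objs]
            )
            dist = np.array([np.hypot(o.x, o.y) for o in objs])
            half_w = np.degrees(np.arcsin(np.minimum(1.0, [o.half_extent for o in objs] / dist)))
            occ = np.array([vertical_occupancy(o.half_extent, d) for o, d in zip(objs, dist)])
            for center in np.arange(-164.5, 165.0, 1.0):
                sel = np.abs(rays - center) <= 0.5
                vals = []
                for ray in rays[sel]:
                    covering = np.abs(wrap_angle(theta - ray)) <= half_w if len(objs) else np.zeros(0, bool)
                    if covering.any():
                        vals.append(occ[np.argmin(np.where(covering, dist, np.inf))])
                    else:
                        vals.append(0.0)
                vals = np.asarray(vals)
                if np.all(vals == vals[0]):  # interior cell: unambiguous
                    expected = vals[0]
                    actual = got.get(round(center * 2) / 2, 0.0)
                    assert actual == pytest.approx(expected, abs=1e-9)


class TestLooming:
    def test_static_scene_static_focal_is_zero(self, origin_pose, rng):
        objs = random_scene(rng, 4)
        sig = looming_input(origin_pose, objs, objs)
        assert sig.value == 0.0

    def test_approach_arithmetic(self, origin_pose):
        # half-extent 0.2 approaching from 1.0 to 0.9 cm
        prev = [VisualObject(1.0, 0.0, 0.2, obj_id=1)]
        now = [VisualObject(0.9, 0.0, 0.2, obj_id=1)]
        expected = vertical_occupancy(0.2, 0.9) - vertical_occupancy(0.2, 1.0)
        sig = looming_input(origin_pose, now, prev)
        assert sig.value == pytest.approx(expected, abs=1e-9)
        assert sig.value == pytest.approx(2.44, abs=0.01)

    def test_max_over_objects(self, origin_pose):
        prev = [
            VisualObject(1.0, 0.5, 0.2, obj_id=1),
            VisualObject(1.0, -0.5, 0.2, obj_id=2),
        ]
        now = [
            VisualObject(0.97, 0.5, 0.2, obj_id=1),   # small increase
            VisualObject(0.80, -0.5, 0.2, obj_id=2),  # larger increase
        ]
        sig = looming_input(origin_pose, now, prev)
        assert sig.object_id == 2

    def test_receding_floored_at_zero(self, origin_pose):
        prev = [VisualObject(1.0, 0.0, 0.2, obj_id=1)]
        now = [VisualObject(2.0, 0.0, 0.2, obj_id=1)]
        assert looming_input(origin_pose, now, prev).value == 0.0

    def test_self_motion_contributes_nothing(self, rng):
        # neighbor-induced mode: any focal displacement through a static
        # scene yields exactly zero loom
        objs = random_scene(rng, 5)
        for _ in range(50):
            pose_now = BodyPose(*rng.uniform(-0.5, 0.5, 2), rng.uniform(-180, 180))
            sig = looming_input(pose_now, objs, objs, mode="neighbor_induced")
            assert sig.value == 0.0

    def test_raw_mode_sees_self_motion(self):
        objs = [VisualObject(2.0, 0.0, 0.2, obj_id=1)]
        far = BodyPose(-1.0, 0.0, 0.0)
        near = BodyPose(0.0, 0.0, 0.0)
        sig = looming_input(near, objs, objs, focal_prev=far, mode="raw")
        assert sig.value > 0.0

    def test_appearing_object_counts_full_occupancy(self, origin_pose):
        now = [VisualObject(1.0, 0.0, 0.2, obj_id=3)]
        sig = looming_input(origin_pose, now, [])
        assert sig.value == pytest.approx(vertical_occupancy(0.2, 1.0))
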