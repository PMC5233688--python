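"""Task scenarios: references, target layouts, scheduling, execution."""

import numpy as np
import pytest

from reachmpc import (NmpcConfig, TaskSpec, UnreachableTargetError,
                      build_center_out_targets, min_jerk_profile,
                      min_jerk_reference, moving_target_schedule,
                      path_deviation_from_line, run_task)


class TestMinJerkReference:
    def test_boundary_and_midpoint(self):
        tau = np.array([0.0, 0.5, 1.0])
        assert np.allclose(min_jerk_profile(tau), [0.0, 0.5, 1.0])

    def test_endpoint_derivatives_vanish(self):
        h = 1e-4
        for tau in (0.0, 1.0):
            grid = np.clip([tau - h, tau, tau + h], 0.0, 1.0)
            s = min_jerk_profile(np.array(grid))
            vel = (s[2] - s[0]) / (grid[2] - grid[0])
            assert abs(vel) < 1e-7

    def test_reference_interpolates_endpoints(self):
        ref = min_jerk_reference([0.0, 0.0], [1.0, -2.0], 2.0)
        assert np.allclose(ref(0.0), [0.0, 0.0])
        assert np.allclose(ref(2.0), [1.0, -2.0])
        assert np.allclose(ref(5.0), [1.0, -2.0])   # holds the endpoint
        assert np.allclose(ref(1.0), [0.5, -1.0])   # symmetry

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            min_jerk_reference([0, 0], [1, 0], 0.0)

    def test_peak_speed_is_fifteen_eighths(self):
        """max s'(tau) = 15/8 at tau = 1/2 for the quintic."""
        tau = np.array([0.5 - 1e-6, 0.5 + 1e-6])
        s = min_jerk_profile(tau)
        peak = (s[1] - s[0]) / 2e-6
        assert peak == pytest.approx(15.0 / 8.0, abs=1e-9)


class TestCenterOutTargets:
    def test_ring_radius_and_gaps(self):
        ring = build_center_out_targets(0.2, 8, center=(0.1, 0.5))
        d = np.linalg.norm(ring - np.array([0.1, 0.5]), axis=1)
        assert np.allclose(d, 0.2, atol=1e-12)
        ang = np.arctan2(ring[:, 1] - 0.5, ring[:, 0] - 0.1)
        gaps = np.diff(np.unwrap(ang))
        assert np.allclose(gaps, np.pi / 4, atol=1e-12)

    def test_single_target(self):
        ring = build_center_out_targets(0.1, 1, center=(0.0, 0.0))
        assert np.allclose(ring, [[0.1, 0.0]])

    def test_validation(self):
        with pytest.raises(ValueError):
            build_center_out_targets(-1.0, 8)
        with pytest.raises(ValueError):
            build_center_out_targets(0.1, 0)


class TestMovingSchedule:
    def test_piecewise_values(self):
        sched = moving_target_schedule([0, 0], [1, 1], 1.0)
        assert np.allclose(sched(0.999), [0, 0])
        assert np.allclose(sched(1.0), [1, 1])

    def test_equal_points_reduce_to_fixed(self):
        sched = moving_target_schedule([0.3, 0.2], [0.3, 0.2], 1.0)
        assert np.allclose(sched(0.0), sched(2.0))


class TestTaskSpecs:
    def test_yaml_round_trip(self, tmp_path):
        spec = TaskSpec(kind="tracking", circle_radius=0.1,
                        direction_index=5, reference_duration=0.8,
                        nmpc=NmpcConfig(horizon=0.4))
        path = tmp_path / "task.yaml"
        spec.to_yaml(path)
        loaded = TaskSpec.from_yaml(path)
        assert loaded.kind == "tracking"
        assert loaded.circle_radius == 0.1
        assert loaded.direction_index == 5
        assert loaded.nmpc.horizon == 0.4

    def test_moving_do_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec(kind="moving", use_do=True)

    def test_out_of_workspace_target_rejected(self, arm, muscles):
        """With the published segment lengths, the +X point of the default
        20 cm center-out ring lies beyond the arm's reach."""
        spec = TaskSpec(kind="tracking", direction_index=0)
        with pytest.raises(UnreachableTargetError):
            run_task(spec, arm, muscles)


def test_tracking_task_follows_straight_reference(arm, muscles):
    """A center-out tracking reach stays close to the straight reference and
    finishes within the stop threshold."""
    spec = TaskSpec(kind="tracking", circle_radius=0.10, direction_index=5,
                    reference_duration=0.8,
                    nmpc=NmpcConfig(horizon=0.4, max_time=1.5))
    rec = run_task(spec, arm, muscles)
    target = np.asarray(rec.metadata["target"])
    assert np.linalg.norm(rec.hand[-1] - target) < spec.nmpc.stop_threshold
    assert path_deviation_from_line(rec, rec.hand[0], target) < 0.02
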