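"""Metrics, signal processing and synthetic fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachmpc import (EmgProcessingSpec, FixtureSpec, SimulationRecord,
                      TimeSeries, count_direction_changes, generate_fixtures,
                      min_jerk_reference, pearson_correlation, process_emg,
                      reaching_error, speed_profile)


def _record_from_path(t, hand):
    """Build a minimal kinematic record around a hand path."""
    n = t.size
    return SimulationRecord(
        t=t, states=np.zeros((n, 10)), excitations=np.zeros((n, 6)),
        hand=hand, speed=np.zeros(n))


def _reach_record(frac_final, n=301, duration=1.5):
    """A straight reach that covers ``frac_final`` of the way to the target."""
    t = np.linspace(0, duration, n)
    start = np.array([0.15, 0.50])
    target = start + np.array([-0.20, 0.0])
    s = frac_final * min_jerk_profile_like(t / duration)
    hand = start + s[:, None] * (target - start)
    return _record_from_path(t, hand), target


def min_jerk_profile_like(tau):
    tau = np.clip(tau, 0, 1)
    return tau ** 3 * (10 - 15 * tau + 6 * tau ** 2)


class TestReachingError:
    def test_on_target_is_zero(self):
        rec, target = _reach_record(1.0)
        assert reaching_error(rec, target, 1.5) == pytest.approx(0.0,
                                                                 abs=1e-9)

    def test_unmoved_hand_is_hundred(self):
        rec, target = _reach_record(0.0)
        assert reaching_error(rec, target, 1.5) == pytest.approx(100.0)

    def test_halfway_is_fifty(self):
        rec, target = _reach_record(0.5)
        assert reaching_error(rec, target, 1.5) == pytest.approx(50.0,
                                                                 abs=1e-9)

    def test_translation_invariance(self):
        rec, target = _reach_record(0.73)
        shifted = _record_from_path(rec.t, rec.hand + np.array([1.0, -2.0]))
        assert reaching_error(shifted, target + np.array([1.0, -2.0]), 1.5) \
            == pytest.approx(reaching_error(rec, target, 1.5), abs=1e-9)

    def test_zero_reach_rejected(self):
        rec, target = _reach_record(1.0)
        with pytest.raises(ValueError):
            reaching_error(rec, rec.hand[0], 1.5)


class TestPearson:
    def test_identity_and_reversal(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pearson_correlation(a, a) == pytest.approx(1.0)
        assert pearson_correlation(a, a[::-1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # r = 8 / sqrt((42/9) * 14) for these triples
        assert pearson_correlation(np.array([1.0, 2.0, 4.0]),
                                   np.array([2.0, 3.0, 7.0])) == \
            pytest.approx(0.98974331861, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5),
           seed=st.integers(0, 100))
    def test_scale_shift_invariance_and_symmetry(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson_correlation(x, y)
        assert -1.0 <= r <= 1.0
        assert pearson_correlation(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_correlation(scale * x + shift, y) == \
            pytest.approx(r, abs=1e-9)


class TestEmgProcessing:
    def test_zero_in_zero_out(self):
        t = np.arange(0, 1.0, 1 / 2000)
        env = process_emg(TimeSeries("z", t, np.zeros(t.size)),
                          EmgProcessingSpec())
        assert np.allclose(env.values, 0.0)
        assert env.rate == pytest.approx(100.0, rel=1e-6)

    def test_tone_envelope_matches_rectified_mean(self):
        """A pure in-band tone yields a flat envelope at 2A/pi."""
        t = np.arange(0, 2.0, 1 / 4000)
        amp = 0.7
        tone = amp * np.sin(2 * np.pi * 300 * t)   # inside the 5-800 Hz band
        env = process_emg(TimeSeries("tone", t, tone), EmgProcessingSpec())
        # ignore filter edge transients
        core = env.values[(env.t > 0.4) & (env.t < 1.6)]
        assert np.median(core) == pytest.approx(2 * amp / np.pi, rel=0.05)

    def test_corner_above_nyquist_rejected(self):
        t = np.arange(0, 1.0, 1 / 1000)
        with pytest.raises(ValueError):
            process_emg(TimeSeries("x", t, np.ones(t.size)),
                        EmgProcessingSpec())

    def test_gain_equivariance(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 1.0, 1 / 2000)
        x = rng.normal(size=t.size)
        spec = EmgProcessingSpec()
        e1 = process_emg(TimeSeries("x", t, x), spec)
        e2 = process_emg(TimeSeries("x2", t, 2 * x), spec)
        core = slice(20, -20)
        assert np.allclose(e2.values[core], 2 * e1.values[core], rtol=1e-6)


class TestSpeedProfile:
    def test_stationary_record(self):
        t = np.linspace(0, 1, 100)
        rec = _record_from_path(t, np.tile([0.1, 0.2], (100, 1)))
        prof = speed_profile(rec)
        assert prof.peak_value < 1e-12
        assert np.allclose(prof.series.values, 0.0, atol=1e-12)

    def test_min_jerk_peak(self):
        """Peak speed of a fed-through quintic reach: 15/8 * d / T at T/2."""
        t = np.linspace(0, 1.5, 1501)
        ref = min_jerk_reference([0.15, 0.5], [-0.05, 0.5], 1.5)
        rec = _record_from_path(t, ref(t))
        prof = speed_profile(rec)
        assert prof.peak_value == pytest.approx(1.875 * 0.2 / 1.5, rel=1e-4)
        assert prof.peak_time == pytest.approx(0.75, abs=2e-3)
        assert prof.unimodal

    def test_direction_change_counts(self):
        t = np.linspace(0, 2, 2001)
        straight = _record_from_path(
            t, np.stack([0.2 * min_jerk_profile_like(t / 2), np.zeros_like(t)],
                        axis=-1))
        assert count_direction_changes(straight) == 0
        # an L-shaped path: go +X then +Y with a dwell in between
        s1 = min_jerk_profile_like(np.clip(t / 0.9, 0, 1))
        s2 = min_jerk_profile_like(np.clip((t - 1.1) / 0.9, 0, 1))
        hand = np.stack([0.2 * s1, 0.15 * s2], axis=-1)
        elbow = _record_from_path(t, hand)
        assert count_direction_changes(elbow) == 1


class TestFixtures:
    def test_reproducibility(self):
        b1 = generate_fixtures(42)
        b2 = generate_fixtures(42)
        assert np.array_equal(b1.trajectory.values, b2.trajectory.values)
        assert np.array_equal(b1.emg[0].values, b2.emg[0].values)

    def test_noise_free_trajectory_is_exact_quintic(self):
        spec = FixtureSpec(noise_std=0.0)
        bundle = generate_fixtures(7, spec)
        ref = min_jerk_reference(np.array(spec.start), np.array(spec.end),
                                 spec.duration)
        assert np.allclose(bundle.trajectory.values,
                           ref(bundle.trajectory.t), atol=1e-12)

    def test_envelope_recovery(self):
        """process_emg recovers each channel's ground-truth envelope."""
        bundle = generate_fixtures(11)
        for raw, truth in zip(bundle.emg, bundle.emg_envelopes):
            env = process_emg(raw, EmgProcessingSpec())
            r = pearson_correlation(env, truth)
            assert r > 0.9

    def test_csv_export(self, tmp_path):
        bundle = generate_fixtures(3, FixtureSpec(duration=0.5,
                                                  emg_channels=1))
        bundle.write_csv(tmp_path)
        assert (tmp_path / "trajectory.csv").exists()
        assert (tmp_path / "emg_ch1.csv").exists()
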