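"""Synthetic kinematic and EMG-like signal fixtures.

The analysis utilities were designed for motion-capture trajectories and
surface EMG, which this package cannot ship.  This module generates
statistically similar stand-ins with known ground truth so every analysis
path is testable: minimum-jerk hand trajectories with additive noise, and
EMG-like signals built as band-limited carrier noise amplitude-modulated by
a known envelope.  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .analysis import TimeSeries
from .tasks import min_jerk_reference


@dataclass
class FixtureSpec:
    """What to synthesize.

    Trajectory: a ``duration``-second minimum-jerk reach from ``start`` to
    ``end`` sampled at ``capture_rate`` with isotropic Gaussian position
    noise ``noise_std`` (motion-capture-like).  EMG: ``emg_channels``
    channels at ``emg_rate``, carrier band ``emg_band``, modulated by a
    minimum-jerk-speed-shaped envelope (plus a small tonic level).
    """

    duration: float = 1.5
    start: tuple[float, float] = (0.146, 0.495)
    end: tuple[float, float] = (-0.054, 0.495)
    capture_rate: float = 30.0
    noise_std: float = 0.002
    emg_channels: int = 3
    emg_rate: float = 2000.0
    emg_band: tuple[float, float] = (20.0, 450.0)
    emg_tonic: float = 0.1


@dataclass
class FixtureBundle:
    trajectory: TimeSeries
    trajectory_clean: TimeSeries
    emg: list[TimeSeries]
    emg_envelopes: list[TimeSeries]     # ground truth, one per channel
    spec: FixtureSpec
    seed: int

    def write_csv(self, directory) -> None:
        """Write the bundle in the same schemas as real exports."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        traj = pd.DataFrame({
            "t": self.trajectory.t,
            "zeta_x": self.trajectory.values[:, 0],
            "zeta_z": self.trajectory.values[:, 1]})
        traj.to_csv(directory / "trajectory.csv", index=False)
        for i, (raw, env) in enumerate(zip(self.emg, self.emg_envelopes)):
            pd.DataFrame({"t": raw.t, "emg": raw.values}).to_csv(
                directory / f"emg_ch{i + 1}.csv", index=False)
            pd.DataFrame({"t": env.t, "envelope": env.values}).to_csv(
                directory / f"emg_ch{i + 1}_envelope.csv", index=False)


def generate_fixtures(seed: int,
                      spec: FixtureSpec | None = None) -> FixtureBundle:
    """Build the synthetic bundle; identical seeds give identical data."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)

    # trajectory: min-jerk reach + capture noise
    n = int(round(spec.duration * spec.capture_rate)) + 1
    t = np.arange(n) / spec.capture_rate
    ref = min_jerk_reference(np.asarray(spec.start), np.asarray(spec.end),
                             spec.duration)
    clean = ref(t)
    noisy = clean + rng.normal(0.0, spec.noise_std, clean.shape)
    trajectory = TimeSeries("hand_trajectory", t, noisy, "m")
    trajectory_clean = TimeSeries("hand_trajectory_clean", t, clean, "m")

    # EMG: band-limited carrier noise modulated by a known envelope
    m = int(round(spec.duration * spec.emg_rate)) + 1
    te = np.arange(m) / spec.emg_rate
    tau = np.clip(te / spec.duration, 0.0, 1.0)
    bell = 30.0 * tau ** 2 - 60.0 * tau ** 3 + 30.0 * tau ** 4
    bell = bell / bell.max()
    sos = sps.butter(4, spec.emg_band, btype="bandpass",
                     fs=spec.emg_rate, output="sos")
    emg, envelopes = [], []
    for ch in range(spec.emg_channels):
        # each channel peaks at a different movement phase
        shift = 0.15 * (ch - (spec.emg_channels - 1) / 2)
        tau_s = np.clip(tau - shift, 0.0, 1.0)
        env = 30.0 * tau_s ** 2 - 60.0 * tau_s ** 3 + 30.0 * tau_s ** 4
        env = spec.emg_tonic + (1.0 - spec.emg_tonic) * env / max(env.max(),
                                                                  1e-12)
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(m))
        carrier = carrier / np.std(carrier)
        emg.append(TimeSeries(f"emg_ch{ch + 1}", te, env * carrier, "a.u."))
        envelopes.append(TimeSeries(f"emg_ch{ch + 1}_true_envelope",
                                    te, env, "a.u."))
    return FixtureBundle(trajectory=trajectory,
                         trajectory_clean=trajectory_clean,
                         emg=emg, emg_envelopes=envelopes,
                         spec=spec, seed=seed)
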