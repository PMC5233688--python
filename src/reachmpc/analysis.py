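"""Metrics and signal processing for reaching records and EMG-like signals.

Covers the reaching-error metric read from closed-loop records, hand speed
profiles (bell-shape diagnostics), Pearson correlation between trajectories
or envelopes, and the standard surface-EMG conditioning chain: band-pass,
full-wave rectification, low-pass envelope, MVC normalization and
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import pearsonr

from .nmpc import SimulationRecord


@dataclass
class TimeSeries:
    """A named, strictly increasing time series; values may be a vector
    channel (2-D array, time on the first axis)."""

    name: str
    t: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.values.shape[0] != self.t.size:
            raise ValueError("times and values must align on the first axis")
        if np.any(~np.isfinite(self.t)) or np.any(~np.isfinite(self.values)):
            raise ValueError("time series must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def rate(self) -> float:
        """Mean sampling rate (Hz)."""
        return (self.t.size - 1) / (self.t[-1] - self.t[0])

    def resampled(self, rate: float) -> "TimeSeries":
        """Linear-interpolation resampling onto a uniform grid at ``rate``."""
        n = int(np.floor((self.t[-1] - self.t[0]) * rate)) + 1
        t_new = self.t[0] + np.arange(n) / rate
        if self.values.ndim == 1:
            v = np.interp(t_new, self.t, self.values)
        else:
            v = np.stack([np.interp(t_new, self.t, col)
                          for col in self.values.T], axis=-1)
        return TimeSeries(self.name, t_new, v, self.units)


@dataclass
class EmgProcessingSpec:
    """Parameters of the EMG conditioning chain.

    Defaults follow common surface-EMG practice: 5–800 Hz band-pass,
    rectification, 4 Hz low-pass envelope, normalization to the maximum
    voluntary contraction (MVC) level, resampling to 100 Hz.  Filters are
    4th-order Butterworth applied forward-backward (zero phase).
    """

    band_low: float = 5.0
    band_high: float = 800.0
    envelope_cutoff: float = 4.0
    mvc: float | np.ndarray = 1.0
    resample_rate: float = 100.0
    filter_order: int = 4

    def validate(self, input_rate: float) -> None:
        nyq = input_rate / 2.0
        if not 0 < self.band_low < self.band_high:
            raise ValueError("band-pass corners must satisfy 0 < low < high")
        if self.band_high >= nyq:
            raise ValueError(
                f"band-pass corner {self.band_high} Hz is at or above the "
                f"Nyquist frequency {nyq:.0f} Hz of the input")
        if self.envelope_cutoff <= 0 or self.envelope_cutoff >= nyq:
            raise ValueError("envelope corner must lie inside (0, Nyquist)")
        if self.resample_rate <= 2 * self.envelope_cutoff:
            raise ValueError("resample rate must exceed twice the envelope "
                             "corner frequency")


def process_emg(raw: TimeSeries, spec: EmgProcessingSpec) -> TimeSeries:
    """Condition a raw EMG-like signal into a normalized envelope.

    Zero-phase band-pass, full-wave rectify, zero-phase low-pass, divide by
    the MVC constant, then resample to the spec rate.  Output values are
    non-negative and, for physiological inputs, of order one.
    """
    rate = raw.rate
    spec.validate(rate)
    x = raw.values
    sos_bp = sps.butter(spec.filter_order,
                        [spec.band_low, spec.band_high],
                        btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos_bp, x, axis=0)
    x = np.abs(x)
    sos_lp = sps.butter(spec.filter_order, spec.envelope_cutoff,
                        btype="lowpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos_lp, x, axis=0)
    x = np.clip(x, 0.0, None) / np.asarray(spec.mvc)
    env = TimeSeries(f"{raw.name}_envelope", raw.t, x, "mvc")
    return env.resampled(spec.resample_rate)


def reaching_error(record: SimulationRecord, target, at_time: float) -> float:
    """Residual hand distance at ``at_time`` as a percentage of the reach.

    ``100 * ||hand(at_time) - target|| / ||target - hand(0)||``.
    """
    target = np.asarray(target, dtype=float)
    if not record.t[0] <= at_time <= record.t[-1] + 1e-12:
        raise ValueError("at_time outside the record span")
    reach = float(np.linalg.norm(target - record.hand[0]))
    if reach <= 0:
        raise ValueError("zero reach distance: the record starts on target")
    residual = float(np.linalg.norm(record.hand_at(at_time) - target))
    return 100.0 * residual / reach


def pearson_correlation(a: TimeSeries | np.ndarray,
                        b: TimeSeries | np.ndarray,
                        rate: float = 100.0) -> float:
    """Product-moment correlation between two signals.

    TimeSeries inputs are resampled onto a common uniform grid (their
    overlapping span, default 100 Hz); planar/vector channels are compared
    on concatenated components.  Raises on fewer than 3 samples or zero
    variance.
    """
    if isinstance(a, TimeSeries) and isinstance(b, TimeSeries):
        t_lo = max(a.t[0], b.t[0])
        t_hi = min(a.t[-1], b.t[-1])
        if t_hi <= t_lo:
            raise ValueError("time series do not overlap")
        n = int(np.floor((t_hi - t_lo) * rate)) + 1
        grid = t_lo + np.arange(n) / rate

        def on_grid(ts: TimeSeries) -> np.ndarray:
            if ts.values.ndim == 1:
                return np.interp(grid, ts.t, ts.values)
            return np.concatenate([np.interp(grid, ts.t, col)
                                   for col in ts.values.T])

        x, y = on_grid(a), on_grid(b)
    else:
        x = np.asarray(a, dtype=float).reshape(-1, order="F")
        y = np.asarray(b, dtype=float).reshape(-1, order="F")
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(pearsonr(x, y).statistic)


@dataclass
class SpeedProfile:
    series: TimeSeries
    peak_value: float
    peak_time: float
    unimodal: bool
    n_peaks: int = 1


def speed_profile(record: SimulationRecord,
                  peak_floor: float = 0.01) -> SpeedProfile:
    """Tangential hand-speed profile with peak and unimodality diagnosis.

    Speed is the central-difference derivative of the hand path on the
    record's output grid.  The profile is unimodal when exactly one local
    maximum exceeds ``peak_floor`` (default 1 %) of the global peak.
    """
    t = record.t
    if t.size < 3:
        ts = TimeSeries("hand_speed", t, np.zeros(t.size), "m/s")
        return SpeedProfile(ts, 0.0, float(t[0]), True, 0)
    v = np.gradient(record.hand, t, axis=0)
    speed = np.linalg.norm(v, axis=1)
    peak = float(speed.max())
    i_peak = int(np.argmax(speed))
    if peak <= 0:
        ts = TimeSeries("hand_speed", t, speed, "m/s")
        return SpeedProfile(ts, 0.0, float(t[0]), True, 0)
    floor = peak_floor * peak
    idx, _ = sps.find_peaks(speed, height=floor, prominence=floor)
    n_peaks = int(len(idx))
    if n_peaks == 0:   # peak at a boundary sample
        n_peaks = 1
    ts = TimeSeries("hand_speed", t, speed, "m/s")
    return SpeedProfile(ts, peak, float(t[i_peak]), n_peaks == 1, n_peaks)


def count_direction_changes(record: SimulationRecord,
                            min_turn_deg: float = 45.0,
                            dwell_speed_frac: float = 0.1,
                            min_segment_length: float = 0.01,
                            ds: float = 0.005,
                            window: float = 0.03) -> int:
    """Number of major direction changes of the hand path.

    The movement is segmented at dwells (hand speed below
    ``dwell_speed_frac`` of its peak); a direction change is counted when
    the net displacement directions of consecutive segments differ by more
    than ``min_turn_deg``, or when a segment's interior (outer 20 % of its
    arclength excluded, so arrival hooks and launch transients carry no
    weight) turns by more than ``min_turn_deg`` within a ``window`` of path
    length.  A straight reach reports 0; a reach with one correction toward
    a relocated target reports 1.
    """
    t = record.t
    v = np.gradient(record.hand, t, axis=0)
    speed = np.linalg.norm(v, axis=1)
    peak = speed.max()
    if peak <= 0:
        return 0
    moving = speed > dwell_speed_frac * peak
    # contiguous moving spans with enough travel
    segments = []
    i, n = 0, t.size
    while i < n:
        if moving[i]:
            j = i
            while j + 1 < n and moving[j + 1]:
                j += 1
            path = record.hand[i:j + 1]
            seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
            if seg_len >= min_segment_length:
                segments.append(path)
            i = j + 1
        else:
            i += 1
    if not segments:
        return 0
    count = 0
    # inter-segment net-direction changes
    dirs = []
    for path in segments:
        d = path[-1] - path[0]
        if np.linalg.norm(d) >= min_segment_length:
            dirs.append(np.arctan2(d[1], d[0]))
    for a, b in zip(dirs[:-1], dirs[1:]):
        diff = np.abs((b - a + np.pi) % (2 * np.pi) - np.pi)
        if diff >= np.deg2rad(min_turn_deg):
            count += 1
    # sustained turns inside a single segment (outer 20 % excluded)
    for path in segments:
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        s = np.concatenate(([0.0], np.cumsum(seg)))
        total = s[-1]
        lo, hi = 0.2 * total, 0.8 * total
        if hi - lo < 2 * window:
            continue
        grid = np.arange(lo, hi, ds)
        px = np.interp(grid, s, path[:, 0])
        py = np.interp(grid, s, path[:, 1])
        phi = np.unwrap(np.arctan2(np.diff(py), np.diff(px)))
        w = max(1, int(round(window / ds)))
        if phi.size <= w:
            continue
        turn = np.abs(phi[w:] - phi[:-w])
        marked = turn >= np.deg2rad(min_turn_deg)
        edges = np.diff(marked.astype(int))
        count += int((edges == 1).sum() + (1 if marked[0] else 0))
    return count


def path_deviation_from_line(record: SimulationRecord, start, end) -> float:
    """Maximum perpendicular distance (m) of the hand path from the straight
    segment between ``start`` and ``end``."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    d = end - start
    L = np.linalg.norm(d)
    if L == 0:
        return float(np.linalg.norm(record.hand - start, axis=1).max())
    n_hat = np.array([-d[1], d[0]]) / L
    return float(np.abs((record.hand - start) @ n_hat).max())
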