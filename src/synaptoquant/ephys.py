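"""Miniature postsynaptic current statistics and evoked-train depression.

Recordings are body-wall-muscle voltage-clamp currents (holding −60 mV,
1 kHz digitization).  Spontaneous single-vesicle fusion events (minis)
appear as inward, i.e. negative-going, deflections; they are analyzed as
positive magnitudes.  Evoked responses to a five-pulse 20 Hz train
(50 ms interpulse interval) are normalized to the first pulse, and
synaptic depression is summarized by the last normalized amplitude.

Mini detection
--------------
The detector subtracts a running-median baseline, rectifies to the
configured polarity, and thresholds at ``k_mad`` times the robust noise
SD (1.4826 × median absolute deviation).  Detection runs on a short
boxcar-smoothed copy of the deviation trace and requires the threshold
to be exceeded for a minimum width, which suppresses single-sample noise
excursions; amplitudes are read from the unsmoothed deviation so they
are not attenuated by the smoothing.  Events closer than the refractory
interval merge into one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "MiniEventSeries",
    "EvokedTrain",
    "detect_minis",
    "mini_stats",
    "normalize_train",
    "depression_index",
    "evoked_from_trace",
]

#: Stimulus-train defaults: five pulses at 20 Hz.
DEFAULT_N_PULSES = 5
DEFAULT_INTERPULSE_S = 0.05


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled membrane current (pA) over time (s)."""

    times: np.ndarray
    current: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        t = np.asarray(self.times, float)
        c = np.asarray(self.current, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "current", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and current must be 1D and equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
            raise ValueError("trace values must be finite")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled at sampling_rate")

    @property
    def duration(self) -> float:
        return self.times.size / self.sampling_rate


@dataclass(frozen=True)
class MiniEventSeries:
    """Detected (or generated) spontaneous events over a recording window."""

    event_times: np.ndarray
    amplitudes: np.ndarray
    duration: float

    def __post_init__(self):
        t = np.asarray(self.event_times, float)
        a = np.asarray(self.amplitudes, float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.shape != a.shape:
            raise ValueError("event_times and amplitudes must match in length")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("amplitudes must be positive magnitudes")

    @property
    def n_events(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class EvokedTrain:
    """Ordered evoked-response amplitudes from a fixed-interval train."""

    amplitudes: np.ndarray
    interpulse_interval: float = DEFAULT_INTERPULSE_S

    def __post_init__(self):
        a = np.asarray(self.amplitudes, float)
        object.__setattr__(self, "amplitudes", a)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("train must contain at least one amplitude")
        if np.any(a < 0):
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_pulses(self) -> int:
        return self.amplitudes.size


def _running_median(x: np.ndarray, size: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(size, center=True, min_periods=1).median().to_numpy()
    )


def detect_minis(
    trace: CurrentTrace,
    k_mad: float = 3.5,
    baseline_window: float = 0.5,
    refractory: float = 0.005,
    polarity: str = "negative",
    smooth_ms: float = 3.0,
    min_above_ms: float = 3.0,
) -> MiniEventSeries:
    """Detect miniature postsynaptic currents in a raw trace.

    Parameters
    ----------
    k_mad : float
        Detection threshold in units of the robust noise SD.
    baseline_window : float
        Running-median window for baseline tracking, seconds.
    refractory : float
        Minimum separation between event onsets, seconds.
    polarity : {'negative', 'positive'}
        Direction of the synaptic deflection; minis at −60 mV are inward
        (negative).
    smooth_ms, min_above_ms : float
        Boxcar width of the detection copy and the minimum time the
        smoothed deviation must stay above threshold, milliseconds.
    """
    fs = trace.sampling_rate
    if fs <= 0:
        raise ValueError("sampling_rate must be > 0")
    if trace.duration <= baseline_window:
        raise ValueError("trace must be longer than the baseline window")
    x = trace.current
    base = _running_median(x, max(1, int(round(baseline_window * fs))))
    dev = (base - x) if polarity == "negative" else (x - base)

    k_smooth = max(1, int(round(smooth_ms * fs / 1000.0)))
    smooth = np.convolve(dev, np.ones(k_smooth) / k_smooth, mode="same")
    mad = np.median(np.abs(smooth - np.median(smooth)))
    sigma = 1.4826 * mad
    if sigma == 0:
        return MiniEventSeries(np.array([]), np.array([]), trace.duration)
    thr = k_mad * sigma

    above = smooth > thr
    min_run = max(1, int(round(min_above_ms * fs / 1000.0)))
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]

    refr = int(round(refractory * fs))
    onsets, amps = [], []
    last_onset = -np.inf
    for s, e in zip(starts, ends):
        if e - s < min_run:
            continue
        if s - last_onset < refr:
            # within refractory of the previous event: fold into it
            amps[-1] = max(amps[-1], float(dev[s:e].max()))
            continue
        onsets.append(s)
        amps.append(float(dev[s:e].max()))
        last_onset = s
    times = trace.times[np.array(onsets, dtype=int)] if onsets else np.array([])
    return MiniEventSeries(times, np.array(amps), trace.duration)


def mini_stats(events: MiniEventSeries) -> dict:
    """Event frequency (Hz) and mean amplitude (pA) of a mini series.

    With zero events the frequency is 0 and the amplitude is NaN
    (flagged absent).
    """
    if events.duration <= 0:
        raise ValueError("recording duration must be > 0")
    n = events.n_events
    return {
        "n_events": n,
        "frequency_hz": n / events.duration,
        "mean_amplitude_pa": float(np.mean(events.amplitudes)) if n else float("nan"),
    }


def normalize_train(train: EvokedTrain) -> np.ndarray:
    """Divide each evoked amplitude by the first; first element is exactly 1."""
    a = train.amplitudes
    if a[0] <= 0:
        raise ValueError("first evoked amplitude must be > 0")
    out = a / a[0]
    out[0] = 1.0
    return out


def depression_index(train: EvokedTrain) -> float:
    """Last normalized amplitude of the train; lower means more depression."""
    if train.n_pulses < 2:
        raise ValueError("depression requires at least 2 pulses")
    return float(normalize_train(train)[-1])


def evoked_from_trace(
    trace: CurrentTrace,
    stim_times: np.ndarray,
    window: float = 0.025,
    polarity: str = "negative",
    interpulse_interval: float = DEFAULT_INTERPULSE_S,
) -> EvokedTrain:
    """Measure evoked amplitudes as peak deviation after each stimulus.

    The baseline is re-anchored per pulse to the sample preceding the
    stimulus; the amplitude is the peak deviation within ``window``
    seconds (half the interpulse interval by default) after it.
    """
    fs = trace.sampling_rate
    x = trace.current
    amps = []
    for t0 in np.asarray(stim_times, float):
        i0 = int(round(t0 * fs))
        i1 = min(x.size, i0 + int(round(window * fs)))
        if i0 >= x.size:
            raise ValueError(f"stimulus at {t0} s falls outside the trace")
        base = x[max(0, i0 - 1)]
        seg = (base - x[i0:i1]) if polarity == "negative" else (x[i0:i1] - base)
        amps.append(max(float(seg.max()), 0.0))
    return EvokedTrain(np.array(amps), interpulse_interval=interpulse_interval)
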