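"""Auditory sEMG-biofeedback simulation.

Simulates the real-time leg of the system: a strictly causal envelope
(full-wave rectification + trailing weighted moving average), threshold
calibration by the 5% rule (rest level plus 5% of the rest-to-pedaling-max
range), beep on/off event detection with debouncing, beep-overlap metrics
between the two fed-back muscles, and audio rendering of the beeps (pure
tones, 400 Hz for VL and 800 Hz for ST, with raised-cosine on/off ramps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .processing import EnvelopeTrace

BEEP_FREQ_HZ = {"VL": 400.0, "ST": 800.0}


@dataclass
class ThresholdCalibration:
    muscle: str
    rest_amplitude: float
    pedaling_max: float
    threshold: float

    def __post_init__(self) -> None:
        if not (self.rest_amplitude <= self.threshold <= self.pedaling_max):
            raise ValueError(
                f"threshold {self.threshold:g} outside "
                f"[rest {self.rest_amplitude:g}, max {self.pedaling_max:g}]"
            )


@dataclass
class BeepEventLog:
    muscle: str
    freq_hz: float
    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for onset, offset in self.events:
            if onset >= offset:
                raise ValueError(f"event ({onset}, {offset}) has onset >= offset")
            if onset < prev_end:
                raise ValueError("events must be ordered and non-overlapping")
            prev_end = offset

    @property
    def total_on_s(self) -> float:
        return float(sum(b - a for a, b in self.events))


def causal_envelope(
    x: np.ndarray,
    fs_hz: float = 1000.0,
    window_ms: float = 100.0,
    weights: str = "linear",
) -> EnvelopeTrace:
    """Strictly causal envelope: rectify, then trailing weighted moving average.

    The output at sample t depends only on samples <= t.  "linear" weights
    rise linearly toward the most recent sample (low latency); "uniform" is a
    plain trailing mean.  Weights are normalized to sum to 1, so a constant
    input c yields steady-state output c.
    """
    x = np.asarray(x, dtype=float)
    win = max(1, int(round(window_ms * fs_hz / 1000.0)))
    if win > x.size:
        raise ValueError(
            f"window of {win} samples exceeds recording length {x.size}"
        )
    if weights == "linear":
        w = np.arange(win, 0, -1, dtype=float)  # w[0]: current sample, heaviest
    elif weights == "uniform":
        w = np.ones(win)
    else:
        raise ValueError(f"unknown weight profile {weights!r}")
    w /= w.sum()
    env = lfilter(w, 1.0, np.abs(x))
    np.clip(env, 0.0, None, out=env)
    return EnvelopeTrace(fs_hz=fs_hz, values=env)


def calibrate_threshold(
    rest_env: EnvelopeTrace,
    pedaling_env: EnvelopeTrace,
    muscle: str = "",
    fraction: float = 0.05,
    rule: str = "relative",
) -> ThresholdCalibration:
    """Beep threshold from a rest trace and ~1 min of calibration pedaling.

    rule "relative" (default): threshold = rest + fraction * (max - rest),
    i.e. the activation must exceed 5% of the rest-to-pedaling-max range
    above the resting level.  rule "absolute": threshold = fraction * max,
    ignoring the rest level (the alternative reading of the 5% rule).
    """
    if rest_env.values.size == 0 or pedaling_env.values.size == 0:
        raise ValueError("calibration traces must be non-empty")
    rest = float(rest_env.values.mean())
    peak = float(pedaling_env.values.max())
    if peak <= rest:
        raise ValueError(
            f"uncalibratable channel {muscle!r}: pedaling max {peak:g} "
            f"does not exceed rest level {rest:g}"
        )
    if rule == "relative":
        thr = rest + fraction * (peak - rest)
    elif rule == "absolute":
        thr = fraction * peak
        thr = min(max(thr, rest), peak)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return ThresholdCalibration(muscle=muscle, rest_amplitude=rest,
                                pedaling_max=peak, threshold=thr)


def detect_beep_events(
    env: EnvelopeTrace,
    calib: ThresholdCalibration,
    freq_hz: float | None = None,
    debounce_ms: float = 50.0,
) -> BeepEventLog:
    """Beep on/off events: maximal runs where the envelope exceeds threshold.

    Gaps shorter than ``debounce_ms`` are bridged and remaining events
    shorter than ``debounce_ms`` dropped (prevents audible chatter near the
    threshold); set debounce_ms=0 to disable.
    """
    if freq_hz is None:
        freq_hz = BEEP_FREQ_HZ.get(calib.muscle, 440.0)
    above = env.values > calib.threshold
    if not above.any():
        return BeepEventLog(muscle=calib.muscle, freq_hz=freq_hz, events=[])
    edges = np.diff(above.astype(np.int8))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(above.size)
    fs = env.fs_hz
    events = [(env.t0 + a / fs, env.t0 + b / fs) for a, b in zip(onsets, offsets)]
    if debounce_ms > 0:
        min_s = debounce_ms / 1000.0
        merged: list[tuple[float, float]] = []
        for a, b in events:
            if merged and a - merged[-1][1] < min_s:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        events = [(a, b) for a, b in merged if b - a >= min_s]
    return BeepEventLog(muscle=calib.muscle, freq_hz=freq_hz, events=events)


def overlap_metrics(log_a: BeepEventLog, log_b: BeepEventLog) -> tuple[float, float]:
    """Total simultaneous beep-on time (s) and its fraction of the shorter log.

    overlap_s is the measure of the intersection of the two event-interval
    unions; overlap_fraction = overlap_s / min(total_on_a, total_on_b), and 0
    when either log is empty.
    """
    overlap = 0.0
    for a0, a1 in log_a.events:
        for b0, b1 in log_b.events:
            overlap += max(0.0, min(a1, b1) - max(a0, b0))
    tot_a, tot_b = log_a.total_on_s, log_b.total_on_s
    if tot_a == 0.0 or tot_b == 0.0:
        return 0.0, 0.0
    return overlap, overlap / min(tot_a, tot_b)


def render_audio(
    logs: list[BeepEventLog],
    audio_fs_hz: float = 44100.0,
    duration_s: float | None = None,
    ramp_ms: float = 10.0,
    peak: float = 0.9,
) -> np.ndarray:
    """Render beep logs to audio: gated pure sine tones, summed.

    Each event is a sine at the log's pitch with raised-cosine on/off ramps
    of ``ramp_ms`` (shortened for very brief events); the mix is
    peak-normalized to ``peak`` full scale.  Silent (all-zero) where no
    events occur.
    """
    max_f = max((lg.freq_hz for lg in logs), default=0.0)
    if logs and audio_fs_hz < 4 * max_f:
        raise ValueError(
            f"audio_fs_hz={audio_fs_hz:g} < 4x max beep frequency {max_f:g}"
        )
    if duration_s is None:
        duration_s = max((e[1] for lg in logs for e in lg.events), default=0.0)
    n = int(round(duration_s * audio_fs_hz))
    out = np.zeros(n)
    t = np.arange(n) / audio_fs_hz
    for lg in logs:
        gate = np.zeros(n)
        for onset, offset in lg.events:
            if offset > duration_s + 1e-9:
                raise ValueError(
                    f"event ({onset:g}, {offset:g}) extends beyond "
                    f"duration {duration_s:g} s"
                )
            i0 = int(round(onset * audio_fs_hz))
            i1 = min(int(round(offset * audio_fs_hz)), n)
            seg = i1 - i0
            if seg <= 0:
                continue
            ramp = min(int(round(ramp_ms / 1000.0 * audio_fs_hz)), seg // 2)
            g = np.ones(seg)
            if ramp > 0:
                edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
                g[:ramp] = edge
                g[seg - ramp:] = edge[::-1]
            gate[i0:i1] = np.maximum(gate[i0:i1], g)
        out += gate * np.sin(2 * np.pi * lg.freq_hz * t)
    m = np.abs(out).max()
    if m > 0:
        out *= peak / m
    return out
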