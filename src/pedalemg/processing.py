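"""Offline sEMG conditioning: linear envelopes, cycle cutting, normalization.

The conditioning chain is the classic biomechanics envelope recipe: zero-phase
4th-order Butterworth high-pass at 20 Hz (motion-artifact removal), demean,
full-wave rectification, zero-phase 4th-order Butterworth low-pass at 15 Hz.
Cycles are then linearly resampled to a 200-point base spanning one crank
revolution and normalized to each muscle's peak across all conditions of a
participant.

"Zero-phase 4th-order" means a 4th-order design run forward and backward
(filtfilt), i.e. an 8th-order magnitude response with no phase delay; the
cutoffs are not corrected for the double pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

N_POINTS = 200  #: points of the normalized cycle time base


@dataclass
class EnvelopeTrace:
    """Non-negative envelope amplitudes (mV) over a full recording."""

    fs_hz: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs_hz


@dataclass
class CycleEnvelopeSet:
    """Per-cycle envelopes of one muscle on the 200-point cycle base."""

    muscle: str
    cycles: np.ndarray  # (n_cycles, N_POINTS)
    participant: str = ""
    condition: str = ""
    normalization_peak: float | None = None
    cycle_bounds: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cycles = np.atleast_2d(np.asarray(self.cycles, dtype=float))

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]


def offline_envelope(
    x: np.ndarray,
    fs_hz: float = 1000.0,
    highpass_hz: float = 20.0,
    lowpass_hz: float = 15.0,
    order: int = 4,
) -> EnvelopeTrace:
    """Linear envelope of one raw sEMG channel.

    Stage order: zero-phase Butterworth high-pass -> subtract mean ->
    full-wave rectification -> zero-phase Butterworth low-pass; residual
    negative ripple from the final filter is clipped to zero.  Output length
    equals input length.
    """
    x = np.asarray(x, dtype=float)
    min_len = int(0.1 * fs_hz) + 3 * (order + 1)
    if x.size < min_len:
        raise ValueError(
            f"need at least {min_len} samples for stable zero-phase "
            f"filtering at fs={fs_hz:g} Hz, got {x.size}"
        )
    b_hp, a_hp = butter(order, highpass_hz, btype="highpass", fs=fs_hz)
    y = filtfilt(b_hp, a_hp, x, padtype="even")
    y = y - y.mean()
    y = np.abs(y)
    b_lp, a_lp = butter(order, lowpass_hz, btype="lowpass", fs=fs_hz)
    env = filtfilt(b_lp, a_lp, y, padtype="even")
    np.clip(env, 0.0, None, out=env)
    return EnvelopeTrace(fs_hz=fs_hz, values=env)


def cut_and_resample(
    env: EnvelopeTrace,
    bounds: list[tuple[float, float]],
    n_points: int = N_POINTS,
    muscle: str = "",
    participant: str = "",
    condition: str = "",
) -> CycleEnvelopeSet:
    """Cut the envelope at cycle bounds and resample each cycle to 200 points.

    Each cycle is linearly interpolated onto points at fractions k/n_points,
    k = 0..n_points-1, of the cycle (half-open grid: the shared boundary
    sample belongs to the next cycle).
    """
    if not bounds:
        raise ValueError("no cycle bounds supplied")
    t_env = env.t
    rows = np.empty((len(bounds), n_points))
    frac = np.arange(n_points) / n_points
    for i, (t0, t1) in enumerate(bounds):
        if t1 <= t0:
            raise ValueError(f"cycle {i} has non-positive duration")
        if (t1 - t0) * env.fs_hz < 20:
            raise ValueError(f"cycle {i} has fewer than 20 samples")
        if t0 < t_env[0] - 1e-9 or t1 > t_env[-1] + 1e-9:
            raise ValueError(f"cycle {i} bounds [{t0:g}, {t1:g}] outside "
                             "the recording")
        rows[i] = np.interp(t0 + frac * (t1 - t0), t_env, env.values)
    return CycleEnvelopeSet(muscle=muscle, cycles=rows,
                            participant=participant, condition=condition,
                            cycle_bounds=list(bounds))


def normalize_to_peak(sets: list[CycleEnvelopeSet]) -> list[CycleEnvelopeSet]:
    """Normalize all cycle sets of one participant-muscle to a common peak.

    The divisor is the single maximum over every cycle of every supplied set
    (i.e. across all conditions), so after normalization the global maximum
    is exactly 1; the peak is recorded on each returned set.  Idempotent.
    """
    if not sets:
        raise ValueError("no cycle sets supplied")
    muscles = {s.muscle for s in sets}
    participants = {s.participant for s in sets}
    if len(muscles) > 1 or len(participants) > 1:
        raise ValueError(
            "normalization spans one participant-muscle; got muscles "
            f"{sorted(muscles)}, participants {sorted(participants)}"
        )
    peak = max(float(s.cycles.max()) for s in sets)
    if peak <= 0:
        raise ValueError(
            f"dead channel: global peak is 0 for muscle "
            f"{next(iter(muscles))!r}"
        )
    out = []
    for s in sets:
        out.append(CycleEnvelopeSet(
            muscle=s.muscle, cycles=s.cycles / peak,
            participant=s.participant, condition=s.condition,
            normalization_peak=peak, cycle_bounds=list(s.cycle_bounds)))
    return out


def ensemble_average(cycle_set: CycleEnvelopeSet) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation across cycles."""
    if cycle_set.n_cycles < 1:
        raise ValueError("need at least one cycle")
    mean = cycle_set.cycles.mean(axis=0)
    sd = cycle_set.cycles.std(axis=0)
    return mean, sd
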