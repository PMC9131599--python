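"""Common-area co-contraction index (COI) of agonist-antagonist envelopes.

COI = 2 * CommonArea / (area_1 + area_2) * 100, where CommonArea is the
integral of the pointwise minimum of the two rectified envelopes (Winter's
common-area convention) and the areas are integrals of each envelope, all by
the trapezoidal rule on the shared 200-point cycle base with unit spacing
(the spacing cancels in the ratio).  The cycle base is periodic — the point
after the last grid point is the first of the next revolution — so the
trapezoid is taken over the periodic closure, which for a uniform grid
reduces to the plain sum of the grid values.  100% means identical
envelopes; 0% means disjoint activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processing import CycleEnvelopeSet

PAIRS = {"VL-ST": ("VL", "ST"), "RF-BF": ("RF", "BF")}


@dataclass
class CoiResult:
    participant: str
    condition: str
    pair: str
    coi_percent: float
    basis: str  # "ensemble" or "per_cycle_mean"
    n_cycles: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.coi_percent <= 100.0 + 1e-9):
            raise ValueError(f"COI {self.coi_percent} outside [0, 100]")


def _validate_pair(e1: np.ndarray, e2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1 or e1.size < 2:
        raise ValueError("envelopes must be 1-D, equal length >= 2")
    if np.any(e1 < 0) or np.any(e2 < 0):
        raise ValueError("envelopes must be non-negative (rectified)")
    return e1, e2


def _area(v: np.ndarray) -> float:
    # trapezoid over the periodic closure (v[n] := v[0]) on a unit grid;
    # every value enters with weight (1/2 + 1/2) = 1, i.e. the plain sum
    return float(v.sum())


def common_area(e1: np.ndarray, e2: np.ndarray) -> float:
    """Periodic trapezoidal integral of the pointwise minimum (unit spacing)."""
    e1, e2 = _validate_pair(e1, e2)
    return _area(np.minimum(e1, e2))


def coi(e1: np.ndarray, e2: np.ndarray) -> float:
    """Co-contraction index (%) of two non-negative envelopes."""
    e1, e2 = _validate_pair(e1, e2)
    a1 = _area(e1)
    a2 = _area(e2)
    if a1 + a2 <= 0:
        raise ValueError("both envelopes are identically zero; COI undefined")
    return 2.0 * common_area(e1, e2) / (a1 + a2) * 100.0


def coi_for_trial(
    set1: CycleEnvelopeSet,
    set2: CycleEnvelopeSet,
    basis: str = "ensemble",
) -> CoiResult:
    """COI of one trial from two muscles' cycle-envelope sets.

    basis "ensemble": COI of the two ensemble-averaged waveforms (default,
    matching how cycle-normalized sEMG is conventionally reported);
    basis "per_cycle_mean": COI computed cycle by cycle, then averaged.
    """
    if (set1.participant, set1.condition) != (set2.participant, set2.condition):
        raise ValueError(
            f"trial metadata mismatch: {set1.participant}/{set1.condition} "
            f"vs {set2.participant}/{set2.condition}"
        )
    pair = f"{set1.muscle}-{set2.muscle}"
    if basis == "ensemble":
        m1 = set1.cycles.mean(axis=0)
        m2 = set2.cycles.mean(axis=0)
        value = coi(m1, m2)
        n = set1.n_cycles
    elif basis == "per_cycle_mean":
        if set1.n_cycles != set2.n_cycles:
            raise ValueError(
                f"per_cycle_mean needs equal cycle counts, got "
                f"{set1.n_cycles} vs {set2.n_cycles}"
            )
        per_cycle = [coi(set1.cycles[i], set2.cycles[i])
                     for i in range(set1.n_cycles)]
        value = float(np.mean(per_cycle))
        n = set1.n_cycles
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return CoiResult(participant=set1.participant, condition=set1.condition,
                     pair=pair, coi_percent=float(value), basis=basis,
                     n_cycles=n)
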