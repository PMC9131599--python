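"""Crank-angle computation and cycle segmentation.

The upper (top) dead center — pedal directly above the crank axis — defines
crank angle zero; one pedaling cycle runs from one upper dead center to the
next.  The crank plane is recovered from the marker data itself (plane of
maximal pedal-marker variance), oriented by the lab vertical, and the sign
convention follows the direction of net rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synth import MarkerTrajectory

#: a 360-degree boundary within this tolerance beyond the recorded angle
#: range is snapped to the recording edge; absorbs marker noise when a trial
#: starts/ends exactly at the dead center (~2 ms at 80 rpm).
BOUNDARY_TOL_DEG = 1.0


@dataclass
class CrankTrace:
    """Unwrapped crank angle versus time, optionally with cycle bounds.

    ``angle_deg`` is 0 at the upper dead center and increases in the
    direction of rotation; ``cycle_bounds`` lists (start_s, end_s) of each
    complete 360-degree cycle.
    """

    t: np.ndarray
    angle_deg: np.ndarray
    cycle_bounds: list[tuple[float, float]] | None = None

    @property
    def n_cycles(self) -> int:
        return 0 if self.cycle_bounds is None else len(self.cycle_bounds)


def compute_crank_angle(markers: MarkerTrajectory,
                        vertical: int = 1) -> CrankTrace:
    """Convert pedal/axis marker positions to an unwrapped crank angle.

    The crank plane is the plane of maximal variance of the pedal-minus-axis
    vector (principal components); angles are measured from the projection of
    the lab vertical (``vertical`` = coordinate index, default y) so that the
    pedal straight above the axis reads 0 degrees, and the sign is chosen so
    the unwrapped angle increases with net rotation.
    """
    v = np.asarray(markers.pedal, float) - np.asarray(markers.axis, float)
    norms = np.linalg.norm(v, axis=1)
    bad = np.flatnonzero(norms <= 0)
    if bad.size:
        raise ValueError(f"pedal and axis markers coincide at frame {bad[0]}")

    centered = v - v.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    e1, e2 = vt[0], vt[1]  # crank-plane basis

    up_world = np.zeros(3)
    up_world[vertical] = 1.0
    up = up_world - (up_world @ np.cross(e1, e2)) * np.cross(e1, e2) / max(
        np.linalg.norm(np.cross(e1, e2)) ** 2, 1e-12)
    if np.linalg.norm(up) < 1e-9:
        raise ValueError("crank plane is horizontal; cannot orient the "
                         "upper dead center from the vertical axis")
    up /= np.linalg.norm(up)
    fwd = np.cross(np.cross(e1, e2), up)
    fwd /= np.linalg.norm(fwd)

    raw = np.arctan2(v @ fwd, v @ up)
    angle = np.rad2deg(np.unwrap(raw))
    if angle[-1] < angle[0]:  # net backward: flip the in-plane handedness
        angle = -angle
    return CrankTrace(t=np.asarray(markers.t, float), angle_deg=angle)


def segment_cycles(trace: CrankTrace,
                   boundary_tol_deg: float = BOUNDARY_TOL_DEG) -> CrankTrace:
    """Locate cycle boundaries at upward crossings of 360-degree multiples.

    Crossing times are linearly interpolated between the bracketing mocap
    frames; incomplete leading/trailing partial cycles are discarded.  A
    dead-center passage within ``boundary_tol_deg`` beyond the recorded
    range is snapped to the recording edge (marker noise at the edges).
    """
    angle = np.asarray(trace.angle_deg, float)
    t = np.asarray(trace.t, float)
    span = angle[-1] - angle[0]
    if span < 720.0 - 2 * boundary_tol_deg:
        raise ValueError(
            f"unwrapped angle spans {span:.1f} deg; need >= 720 deg "
            "(at least two dead-center crossings)"
        )
    # monotone envelope guards against noise-induced local reversals
    mono = np.maximum.accumulate(angle)
    lo = mono[0] - boundary_tol_deg
    hi = mono[-1] + boundary_tol_deg
    k0 = int(np.ceil(lo / 360.0))
    k1 = int(np.floor(hi / 360.0))
    levels = 360.0 * np.arange(k0, k1 + 1)
    if levels.size < 2:
        raise ValueError("fewer than 2 dead-center crossings; cannot segment")
    times = np.interp(levels, mono, t)  # clips snapped levels to the edges
    bounds = [(float(times[i]), float(times[i + 1]))
              for i in range(len(times) - 1)]
    return replace(trace, cycle_bounds=bounds)


def fit_angular_speed(trace: CrankTrace) -> float:
    """Least-squares angular speed (deg/s) of the unwrapped angle."""
    slope = np.polyfit(trace.t, trace.angle_deg, 1)[0]
    return float(slope)
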