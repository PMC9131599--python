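"""Synthetic pedaling sEMG and crank-kinematics generation.

Every downstream stage of the package is testable against this module's
known ground truth: crank-phase-locked activation templates (raised-cosine
bursts), raw sEMG as band-limited Gaussian noise amplitude-modulated by the
templates, circular pedal-marker trajectories, and full multi-participant
study datasets with a controllable designed co-contraction level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

MUSCLES = ("VL", "ST", "RF", "BF")
CONDITIONS = ("NFB", "VLFB", "STFB", "VL-STFB")

#: Default burst parameterization (center_deg, width_deg, amplitude) encoding
#: the qualitative crank-phase activity of each muscle during seated pedaling:
#: VL (knee extensor) fires around top dead center; ST (knee flexor) over the
#: downstroke 0-180 deg and again approaching top dead center; RF (hip
#: flexor / knee extensor) is active except over 90-180 deg; BF (hip
#: extensor) over the downstroke 0-180 deg.  Width is the full support of a
#: raised-cosine burst, so a burst (c, w, a) is nonzero only on [c-w/2, c+w/2]
#: (circularly).
DEFAULT_BURSTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "VL": ((350.0, 90.0, 1.0),),
    "ST": ((90.0, 180.0, 1.0), (315.0, 90.0, 1.0)),
    "RF": ((240.0, 100.0, 0.8), (0.0, 180.0, 1.0)),
    "BF": ((90.0, 180.0, 1.0),),
}

_TEMPLATE_GRID = np.arange(360.0)  # 1-degree grid on [0, 360)


def _circular_distance_deg(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(np.asarray(a, dtype=float) - b) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class ActivationTemplate:
    """Crank-phase-locked muscle activation profile, periodic on [0, 360)."""

    muscle: str
    burst_params: tuple[tuple[float, float, float], ...]
    profile: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.profile is None:
            object.__setattr__(self, "profile", self(_TEMPLATE_GRID))

    def __call__(self, angle_deg: np.ndarray | float) -> np.ndarray:
        """Evaluate the template at arbitrary crank angles (degrees)."""
        angle = np.asarray(angle_deg, dtype=float)
        out = np.zeros_like(angle)
        for center, width, amp in self.burst_params:
            d = _circular_distance_deg(angle, center)
            half = width / 2.0
            mask = d <= half
            out[mask] += amp * 0.5 * (1.0 + np.cos(np.pi * d[mask] / half))
        return out

    def shifted(self, delta_deg: float) -> "ActivationTemplate":
        """Template with every burst center translated by ``delta_deg``."""
        bursts = tuple(
            ((c + delta_deg) % 360.0, w, a) for c, w, a in self.burst_params
        )
        return ActivationTemplate(self.muscle, bursts)


def build_template(
    muscle: str,
    burst_params: Sequence[tuple[float, float, float]],
) -> ActivationTemplate:
    """Build an activation template from raised-cosine burst parameters.

    Each burst ``(center_deg, width_deg, amplitude)`` contributes
    ``amplitude * 0.5 * (1 + cos(pi * d / (width/2)))`` for circular distance
    ``d <= width/2`` from the center, so ``width_deg`` is the full support of
    the burst and bursts wrap across 0/360.  The profile is the pointwise sum.
    """
    if len(burst_params) == 0:
        raise ValueError(
            f"template for {muscle!r} has no bursts; use a null template "
            "explicitly if an inactive muscle is intended"
        )
    bursts = []
    for center, width, amp in burst_params:
        if width <= 0:
            raise ValueError(f"burst width must be positive, got {width}")
        bursts.append((float(center) % 360.0, float(width), float(amp)))
    return ActivationTemplate(muscle, tuple(bursts))


def null_template(muscle: str = "null") -> ActivationTemplate:
    """All-zero template (rest / dead channel)."""
    return ActivationTemplate(muscle, (), profile=np.zeros(360))


def default_template(muscle: str) -> ActivationTemplate:
    if muscle not in DEFAULT_BURSTS:
        raise KeyError(f"unknown muscle {muscle!r}; expected one of {MUSCLES}")
    return build_template(muscle, DEFAULT_BURSTS[muscle])


def template_coi(t1: ActivationTemplate, t2: ActivationTemplate,
                 n_points: int = 3600) -> float:
    """Analytic (dense-grid) co-contraction index of two noise-free templates.

    Serves as the designed ground truth against which pipeline-recovered COIs
    are compared; uses the same common-area definition as
    :func:`pedalemg.cocontraction.coi` on a dense angle grid.
    """
    from .cocontraction import coi

    grid = np.linspace(0.0, 360.0, n_points, endpoint=False)
    return coi(t1(grid), t2(grid))


def designed_envelope_coi(t1: ActivationTemplate, t2: ActivationTemplate,
                          snr: float, n_points: int = 3600) -> float:
    """Analytic COI of the noise-free, peak-normalized surrogate envelopes.

    The surrogate's rectified-and-smoothed trace tracks
    ``noise_floor * (1 + snr * template)``, and the offline pipeline divides
    each muscle's envelope by its own peak before the COI, so the analytic
    expectation of the pipeline-recovered COI is the COI of
    ``(1 + snr*T) / max(1 + snr*T)`` per muscle — not the bare template COI
    (the constant noise-floor pedestal contributes common area everywhere).
    """
    from .cocontraction import coi

    grid = np.linspace(0.0, 360.0, n_points, endpoint=False)
    e1 = 1.0 + snr * t1(grid)
    e2 = 1.0 + snr * t2(grid)
    return coi(e1 / e1.max(), e2 / e2.max())


class SyntheticStudyConfig(BaseModel):
    """Configuration of a simulated multi-participant biofeedback study.

    Defaults reproduce the study conditions: 13 participants, four feedback
    conditions, 90 s of pedaling at 80 rpm, 1000 Hz sEMG, 100 Hz motion
    capture.
    """

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=13, ge=1)
    conditions: tuple[str, ...] = CONDITIONS
    cadence_rpm: float = Field(default=80.0, gt=0)
    duration_s: float = Field(default=90.0, gt=0)
    emg_fs_hz: float = Field(default=1000.0, gt=0)
    mocap_fs_hz: float = Field(default=100.0, gt=0)
    noise_floor: float = Field(default=0.01, gt=0)  # mV
    snr: float = Field(default=10.0, gt=0)
    #: per-condition translation of the ST burst centers (degrees); positive
    #: values move ST activity toward the VL burst, raising the designed
    #: VL-ST overlap.  Keys must be condition labels.
    condition_overlap_shift: dict[str, float] = Field(default_factory=dict)
    crank_length_m: float = Field(default=0.17, gt=0)
    marker_noise_m: float = Field(default=0.0005, ge=0)
    #: between-participant variability of burst centers (deg) and of the
    #: multiplicative amplitude gain (lognormal sigma).
    participant_phase_jitter_deg: float = Field(default=5.0, ge=0)
    participant_gain_sigma: float = Field(default=0.2, ge=0)
    master_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticStudyConfig":
        n_cycles = self.duration_s * self.cadence_rpm / 60.0
        if n_cycles < 2:
            raise ValueError(
                f"duration_s x cadence_rpm yields {n_cycles:.2f} cycles; "
                "need at least 2 complete cycles"
            )
        unknown = set(self.condition_overlap_shift) - set(self.conditions)
        if unknown:
            raise ValueError(
                f"condition_overlap_shift refers to unknown conditions {sorted(unknown)}"
            )
        return self


@dataclass
class RawEmgRecording:
    """Multi-channel raw sEMG samples (mV) with sampling rate and labels."""

    fs_hz: float
    channels: tuple[str, ...]
    samples: np.ndarray  # (n_channels, n_samples), mV
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but "
                f"{self.samples.shape[0]} sample rows"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channels.index(label)]


@dataclass
class MarkerTrajectory:
    """Pedal and crank-axis marker positions (m) per mocap frame."""

    fs_hz: float
    t: np.ndarray           # (n,)
    pedal: np.ndarray       # (n, 3), columns x (forward), y (up), z (lateral)
    axis: np.ndarray        # (n, 3)


def _band_limited_noise(n: int, fs_hz: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian noise band-limited to ``band`` Hz."""
    from scipy.signal import butter, sosfilt

    lo, hi = band
    if fs_hz <= 2 * hi:
        raise ValueError(
            f"fs_hz={fs_hz} is too low for the {lo}-{hi} Hz noise band "
            f"(need fs_hz > {2 * hi})"
        )
    white = rng.standard_normal(n)
    sos = butter(4, (lo, hi), btype="bandpass", fs=fs_hz, output="sos")
    w = sosfilt(sos, white)
    w -= w.mean()
    std = w.std()
    return w / std if std > 0 else w


def simulate_raw_semg(
    template: ActivationTemplate,
    crank_angle_deg: np.ndarray,
    fs_hz: float = 1000.0,
    noise_floor: float = 0.01,
    snr: float = 10.0,
    seed: int | np.random.SeedSequence = 0,
    band: tuple[float, float] = (20.0, 450.0),
) -> RawEmgRecording:
    """Simulate one raw sEMG channel as amplitude-modulated band-limited noise.

    Sample t is ``(noise_floor + snr*noise_floor*template(angle_t)) * w_t``
    with ``w`` zero-mean unit-variance noise in ``band``; the rectified and
    smoothed trace therefore follows the template with envelope-to-floor
    ratio ``snr`` at the template peak.  Identical seed gives identical output.
    """
    angle = np.asarray(crank_angle_deg, dtype=float)
    unwrapped = np.unwrap(np.deg2rad(angle))
    if np.any(np.diff(unwrapped) < 0):
        raise ValueError("crank angle must be monotonically increasing "
                         "after unwrapping (forward pedaling)")
    rng = np.random.default_rng(seed)
    w = _band_limited_noise(angle.size, fs_hz, band, rng)
    gain = snr * noise_floor
    samples = (noise_floor + gain * template(angle)) * w
    return RawEmgRecording(fs_hz=fs_hz, channels=(template.muscle,),
                           samples=samples[None, :])


def simulate_crank_markers(
    cadence_rpm: float,
    duration_s: float,
    mocap_fs_hz: float = 100.0,
    crank_length_m: float = 0.17,
    seed: int | np.random.SeedSequence | None = None,
    marker_noise_m: float = 0.0,
) -> MarkerTrajectory:
    """Pedal marker on a circle about the crank axis at constant cadence.

    Frames span [0, duration_s] inclusive (n = round(duration*fs) + 1) so the
    final top-dead-center passage of a whole number of revolutions is
    recorded.  Frame 0 places the pedal directly above the axis (upper dead
    center); the crank angle grows as ``6 * cadence_rpm * t`` degrees with
    positive rotation carrying the pedal forward (+x).
    """
    if min(cadence_rpm, duration_s, mocap_fs_hz, crank_length_m) <= 0:
        raise ValueError("all simulate_crank_markers arguments must be positive")
    n = int(round(duration_s * mocap_fs_hz)) + 1
    t = np.arange(n) / mocap_fs_hz
    theta = np.deg2rad(360.0 * cadence_rpm / 60.0 * t)
    axis = np.zeros((n, 3))
    pedal = np.column_stack([
        crank_length_m * np.sin(theta),   # forward
        crank_length_m * np.cos(theta),   # up
        np.zeros(n),                      # lateral
    ])
    if marker_noise_m > 0:
        rng = np.random.default_rng(seed)
        pedal = pedal + rng.normal(0.0, marker_noise_m, size=pedal.shape)
        axis = axis + rng.normal(0.0, marker_noise_m, size=axis.shape)
    return MarkerTrajectory(fs_hz=mocap_fs_hz, t=t, pedal=pedal, axis=axis)


@dataclass
class Trial:
    participant: str
    condition: str
    emg: RawEmgRecording
    markers: MarkerTrajectory
    metadata: dict


@dataclass
class StudyDataset:
    """Simulated study: trials plus ground truth for every designed quantity."""

    config: SyntheticStudyConfig
    trials: list[Trial]
    #: rest (no-pedaling) recording per participant, for threshold calibration
    rest_recordings: dict[str, RawEmgRecording]
    #: templates actually used, keyed (participant, condition, muscle)
    templates: dict[tuple[str, str, str], ActivationTemplate]
    #: designed (noise-free, participant-template) COI per
    #: (participant, condition, pair) with pair in {"VL-ST", "RF-BF"}
    designed_coi: dict[tuple[str, str, str], float]
    #: designed COI of the noise-free *envelopes* the surrogate model
    #: produces, i.e. of (1 + snr * template); this is the analytic
    #: expectation of the pipeline-recovered COI, since the rectified and
    #: smoothed surrogate tracks noise_floor + snr*noise_floor*template
    designed_envelope_coi: dict[tuple[str, str, str], float]
    #: per-trial integer seeds, keyed (participant, condition)
    trial_seeds: dict[tuple[str, str], int]


def _trial_seed(master_seed: int, p_idx: int, c_idx: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(p_idx, c_idx, stream))
    return int(ss.generate_state(1)[0])


def simulate_study(config: SyntheticStudyConfig) -> StudyDataset:
    """Simulate the full study: participants x conditions pedaling trials.

    Per-trial seeds are derived deterministically from ``master_seed`` so the
    whole dataset is bitwise reproducible.  ``condition_overlap_shift``
    translates the ST burst centers in the affected conditions; the designed
    (template-level) COI is recorded in the ground truth for every trial.
    """
    cfg = config
    for cond in cfg.condition_overlap_shift:
        if cond not in cfg.conditions:  # re-checked for dict mutation
            raise ValueError(f"unknown condition {cond!r}")

    trials: list[Trial] = []
    rest: dict[str, RawEmgRecording] = {}
    templates: dict[tuple[str, str, str], ActivationTemplate] = {}
    designed: dict[tuple[str, str, str], float] = {}
    designed_env: dict[tuple[str, str, str], float] = {}
    seeds: dict[tuple[str, str], int] = {}

    for p_idx in range(cfg.n_participants):
        pid = f"P{p_idx + 1:02d}"
        prng = np.random.default_rng(_trial_seed(cfg.master_seed, p_idx, 999, 0))
        # participant-specific activation anatomy: jittered burst centers and
        # a multiplicative gain shared across that participant's trials
        p_bursts: dict[str, tuple[tuple[float, float, float], ...]] = {}
        for m in MUSCLES:
            gain = float(np.exp(prng.normal(0.0, cfg.participant_gain_sigma)))
            jittered = tuple(
                ((c + prng.normal(0.0, cfg.participant_phase_jitter_deg)) % 360.0,
                 w, a * gain)
                for c, w, a in DEFAULT_BURSTS[m]
            )
            p_bursts[m] = jittered

        # rest recording (noise floor only) for biofeedback calibration
        rest_n = int(round(5.0 * cfg.emg_fs_hz)) + 1
        rest_angle = np.zeros(rest_n)
        rest_channels = []
        for ch_idx, m in enumerate(MUSCLES):
            seed = _trial_seed(cfg.master_seed, p_idx, 998, ch_idx)
            rec = simulate_raw_semg(null_template(m), rest_angle,
                                    fs_hz=cfg.emg_fs_hz,
                                    noise_floor=cfg.noise_floor,
                                    snr=cfg.snr, seed=seed)
            rest_channels.append(rec.samples[0])
        rest[pid] = RawEmgRecording(cfg.emg_fs_hz, MUSCLES,
                                    np.vstack(rest_channels))

        for c_idx, cond in enumerate(cfg.conditions):
            shift = cfg.condition_overlap_shift.get(cond, 0.0)
            cond_templates: dict[str, ActivationTemplate] = {}
            for m in MUSCLES:
                bursts = p_bursts[m]
                if m == "ST" and shift != 0.0:
                    bursts = tuple(((c + shift) % 360.0, w, a)
                                   for c, w, a in bursts)
                cond_templates[m] = build_template(m, bursts)
                templates[(pid, cond, m)] = cond_templates[m]

            designed[(pid, cond, "VL-ST")] = template_coi(
                cond_templates["VL"], cond_templates["ST"])
            designed[(pid, cond, "RF-BF")] = template_coi(
                cond_templates["RF"], cond_templates["BF"])
            designed_env[(pid, cond, "VL-ST")] = designed_envelope_coi(
                cond_templates["VL"], cond_templates["ST"], cfg.snr)
            designed_env[(pid, cond, "RF-BF")] = designed_envelope_coi(
                cond_templates["RF"], cond_templates["BF"], cfg.snr)

            marker_seed = _trial_seed(cfg.master_seed, p_idx, c_idx, 100)
            markers = simulate_crank_markers(
                cfg.cadence_rpm, cfg.duration_s, cfg.mocap_fs_hz,
                cfg.crank_length_m, seed=marker_seed,
                marker_noise_m=cfg.marker_noise_m)

            n_emg = int(round(cfg.duration_s * cfg.emg_fs_hz)) + 1
            t_emg = np.arange(n_emg) / cfg.emg_fs_hz
            angle = 360.0 * cfg.cadence_rpm / 60.0 * t_emg

            chans = []
            for ch_idx, m in enumerate(MUSCLES):
                seed = _trial_seed(cfg.master_seed, p_idx, c_idx, ch_idx)
                rec = simulate_raw_semg(cond_templates[m], angle,
                                        fs_hz=cfg.emg_fs_hz,
                                        noise_floor=cfg.noise_floor,
                                        snr=cfg.snr, seed=seed)
                chans.append(rec.samples[0])
            emg = RawEmgRecording(cfg.emg_fs_hz, MUSCLES, np.vstack(chans))
            seeds[(pid, cond)] = _trial_seed(cfg.master_seed, p_idx, c_idx, 0)
            trials.append(Trial(
                participant=pid, condition=cond, emg=emg, markers=markers,
                metadata={
                    "participant": pid,
                    "condition": cond,
                    "cadence_rpm": cfg.cadence_rpm,
                    "duration_s": cfg.duration_s,
                    "emg_fs_hz": cfg.emg_fs_hz,
                    "mocap_fs_hz": cfg.mocap_fs_hz,
                    "overlap_shift_deg": shift,
                }))
    return StudyDataset(config=cfg, trials=trials, rest_recordings=rest,
                        templates=templates, designed_coi=designed,
                        designed_envelope_coi=designed_env,
                        trial_seeds=seeds)
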