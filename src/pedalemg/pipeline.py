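"""End-to-end pipeline: simulate/load trials, process, COI, feedback, stats.

Ties the stages together with validated configuration, per-stage logging,
deterministic delimited-text outputs shaped like the study's result tables
(per-trial COIs; condition means with SD, p and partial eta^2; ensemble
waveforms; beep event logs), plus a JSON manifest of every parameter used.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .biofeedback import (BEEP_FREQ_HZ, calibrate_threshold, causal_envelope,
                          detect_beep_events, overlap_metrics)
from .cocontraction import PAIRS, coi_for_trial
from .io import read_trial
from .kinematics import compute_crank_angle, segment_cycles
from .processing import (CycleEnvelopeSet, cut_and_resample, ensemble_average,
                         normalize_to_peak, offline_envelope)
from .stats import rm_anova, shapiro_wilk
from .synth import MUSCLES, SyntheticStudyConfig, Trial, simulate_study

#: muscles sonified in each feedback condition
FEEDBACK_MUSCLES = {"NFB": (), "VLFB": ("VL",), "STFB": ("ST",),
                    "VL-STFB": ("VL", "ST")}


class PipelineConfig(BaseModel):
    """Validated configuration; defaults are the study's parameter values."""

    model_config = ConfigDict(extra="forbid")

    simulation: SyntheticStudyConfig = Field(default_factory=SyntheticStudyConfig)
    #: read trials from this directory instead of simulating (layout
    #: <participant>/<condition>/{emg.csv,markers.csv,metadata.json})
    data_dir: str | None = None

    highpass_hz: float = 20.0
    lowpass_hz: float = 15.0
    filter_order: int = 4
    n_points: int = 200
    coi_basis: str = "ensemble"

    window_ms: float = 100.0
    threshold_rule: str = "relative"
    threshold_fraction: float = 0.05
    debounce_ms: float = 50.0

    alpha: float = 0.05
    seed: int | None = None  #: overrides simulation.master_seed when set


@dataclass
class PipelineResult:
    trial_coi: pd.DataFrame
    summary: pd.DataFrame
    anova: pd.DataFrame
    normality: pd.DataFrame
    ensembles: pd.DataFrame
    beep_events: pd.DataFrame
    beep_overlap: pd.DataFrame
    manifest: dict
    log: list[str] = field(default_factory=list)


def _load_trials(cfg: PipelineConfig, log: list[str]) -> tuple[list[Trial], dict]:
    if cfg.data_dir is not None:
        trials = []
        root = Path(cfg.data_dir)
        for meta_path in sorted(root.glob("*/*/metadata.json")):
            d = meta_path.parent
            trials.append(read_trial(d / "emg.csv", d / "markers.csv", meta_path))
            log.append(f"read trial={d.parent.name}/{d.name}")
        if not trials:
            raise FileNotFoundError(f"no trials found under {root}")
        return trials, {}
    sim_cfg = cfg.simulation
    if cfg.seed is not None:
        sim_cfg = sim_cfg.model_copy(update={"master_seed": cfg.seed})
    study = simulate_study(sim_cfg)
    log.append(f"simulated study: {len(study.trials)} trials, "
               f"master_seed={sim_cfg.master_seed}")
    rests = {pid: rec for pid, rec in study.rest_recordings.items()}
    return study.trials, {"study": study, "rests": rests}


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis and optionally write result tables to out_dir."""
    cfg = config
    log: list[str] = []
    trials, extra = _load_trials(cfg, log)

    participants = sorted({t.participant for t in trials})
    conditions = list(dict.fromkeys(t.condition for t in trials))
    by_key = {(t.participant, t.condition): t for t in trials}
    for pid in participants:
        for cond in conditions:
            if (pid, cond) not in by_key:
                raise ValueError(f"missing trial {pid}/{cond}; the design "
                                 "must be complete")

    # --- envelopes + cycles -------------------------------------------------
    raw_sets: dict[tuple[str, str, str], CycleEnvelopeSet] = {}
    n_cycles: dict[tuple[str, str], int] = {}
    for t in trials:
        trace = segment_cycles(compute_crank_angle(t.markers))
        n_cycles[(t.participant, t.condition)] = trace.n_cycles
        log.append(f"segment trial={t.participant}/{t.condition} "
                   f"cycles={trace.n_cycles}")
        for m in MUSCLES:
            env = offline_envelope(t.emg.channel(m), fs_hz=t.emg.fs_hz,
                                   highpass_hz=cfg.highpass_hz,
                                   lowpass_hz=cfg.lowpass_hz,
                                   order=cfg.filter_order)
            raw_sets[(t.participant, t.condition, m)] = cut_and_resample(
                env, trace.cycle_bounds, n_points=cfg.n_points, muscle=m,
                participant=t.participant, condition=t.condition)

    # --- peak normalization across conditions, per participant-muscle -------
    norm_sets: dict[tuple[str, str, str], CycleEnvelopeSet] = {}
    for pid in participants:
        for m in MUSCLES:
            group = [raw_sets[(pid, c, m)] for c in conditions]
            for s in normalize_to_peak(group):
                norm_sets[(pid, s.condition, m)] = s

    # --- COI -----------------------------------------------------------------
    coi_rows = []
    for pid in participants:
        for cond in conditions:
            for pair, (m1, m2) in PAIRS.items():
                for basis in ("ensemble", "per_cycle_mean"):
                    r = coi_for_trial(norm_sets[(pid, cond, m1)],
                                      norm_sets[(pid, cond, m2)], basis=basis)
                    coi_rows.append({
                        "participant": pid, "condition": cond, "pair": pair,
                        "basis": basis, "coi_percent": r.coi_percent,
                        "n_cycles": r.n_cycles})
    trial_coi = pd.DataFrame(coi_rows)

    # --- statistics ----------------------------------------------------------
    anova_rows, norm_rows, summary_rows = [], [], []
    for pair in PAIRS:
        sub = trial_coi[(trial_coi["pair"] == pair)
                        & (trial_coi["basis"] == cfg.coi_basis)]
        table = (sub.pivot(index="participant", columns="condition",
                           values="coi_percent")[conditions]).to_numpy()
        for j, cond in enumerate(conditions):
            col = table[:, j]
            if len(col) >= 3 and np.ptp(col) > 0:
                w, p_sw = shapiro_wilk(col)
            else:
                w, p_sw = np.nan, np.nan
            norm_rows.append({"pair": pair, "condition": cond,
                              "shapiro_w": w, "shapiro_p": p_sw})
            summary_rows.append({
                "pair": pair, "condition": cond,
                "mean_coi_percent": float(col.mean()),
                "sd_coi_percent": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                "n": len(col)})
        if table.shape[0] >= 2:
            res = rm_anova(table)
            anova_rows.append({
                "pair": pair, "f_value": res.f_value,
                "df_effect": res.df_effect, "df_error": res.df_error,
                "p_value": res.p_value, "partial_eta_sq": res.partial_eta_sq,
                "gg_epsilon": res.gg_epsilon, "p_value_gg": res.p_value_gg,
                "significant": bool(res.p_value < cfg.alpha)})
            log.append(f"rm_anova pair={pair} F={res.f_value:.3f} "
                       f"p={res.p_value:.3f} peta2={res.partial_eta_sq:.3f}")
    anova = pd.DataFrame(anova_rows)
    normality = pd.DataFrame(norm_rows)
    summary = pd.DataFrame(summary_rows)
    if not anova.empty:
        summary = summary.merge(
            anova[["pair", "p_value", "partial_eta_sq"]], on="pair")

    # --- ensemble waveforms (participant-averaged, per muscle x condition) --
    ens_rows = []
    for m in MUSCLES:
        for cond in conditions:
            means = [ensemble_average(norm_sets[(pid, cond, m)])[0]
                     for pid in participants]
            grand = np.mean(means, axis=0)
            for k, v in enumerate(grand):
                ens_rows.append({"muscle": m, "condition": cond,
                                 "cycle_percent": 100.0 * k / cfg.n_points,
                                 "amplitude": v})
    ensembles = pd.DataFrame(ens_rows)

    # --- biofeedback simulation ---------------------------------------------
    beep_rows, overlap_rows = [], []
    rests = extra.get("rests", {})
    for t in trials:
        fed = FEEDBACK_MUSCLES.get(t.condition, ())
        logs = {}
        for m in fed:
            env = causal_envelope(t.emg.channel(m), fs_hz=t.emg.fs_hz,
                                  window_ms=cfg.window_ms)
            if t.participant in rests:
                rest_env = causal_envelope(
                    rests[t.participant].channel(m),
                    fs_hz=rests[t.participant].fs_hz,
                    window_ms=cfg.window_ms)
            else:  # no rest recording on disk: low quantile stands in
                from .processing import EnvelopeTrace
                rest_level = np.quantile(env.values, 0.05)
                rest_env = EnvelopeTrace(fs_hz=env.fs_hz,
                                         values=np.full(100, rest_level))
            calib = calibrate_threshold(rest_env, env, muscle=m,
                                        fraction=cfg.threshold_fraction,
                                        rule=cfg.threshold_rule)
            blog = detect_beep_events(env, calib,
                                      freq_hz=BEEP_FREQ_HZ[m],
                                      debounce_ms=cfg.debounce_ms)
            logs[m] = blog
            for onset, offset in blog.events:
                beep_rows.append({
                    "participant": t.participant, "condition": t.condition,
                    "muscle": m, "freq_hz": blog.freq_hz,
                    "onset_s": onset, "offset_s": offset})
        if len(fed) == 2:
            ov_s, ov_frac = overlap_metrics(logs[fed[0]], logs[fed[1]])
            overlap_rows.append({
                "participant": t.participant, "condition": t.condition,
                "overlap_s": ov_s, "overlap_fraction": ov_frac})
            log.append(f"feedback trial={t.participant}/{t.condition} "
                       f"overlap_s={ov_s:.3f}")
    beep_events = pd.DataFrame(
        beep_rows, columns=["participant", "condition", "muscle", "freq_hz",
                            "onset_s", "offset_s"])
    beep_overlap = pd.DataFrame(
        overlap_rows, columns=["participant", "condition", "overlap_s",
                               "overlap_fraction"])

    manifest = {
        "pedalemg_version": __version__,
        "python_version": platform.python_version(),
        "config": json.loads(cfg.model_dump_json()),
        "n_trials": len(trials),
        "participants": participants,
        "conditions": conditions,
        "cycles_per_trial": {f"{p}/{c}": n_cycles[(p, c)]
                             for p, c in sorted(n_cycles)},
    }

    result = PipelineResult(trial_coi=trial_coi, summary=summary, anova=anova,
                            normality=normality, ensembles=ensembles,
                            beep_events=beep_events, beep_overlap=beep_overlap,
                            manifest=manifest, log=log)
    if out_dir is not None:
        _write_results(result, Path(out_dir))
    return result


def _write_results(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.9g"
    res.trial_coi.to_csv(out / "trial_coi.csv", index=False, float_format=ff)
    res.summary.to_csv(out / "coi_summary.csv", index=False, float_format=ff)
    res.anova.to_csv(out / "anova.csv", index=False, float_format=ff)
    res.normality.to_csv(out / "normality.csv", index=False, float_format=ff)
    res.ensembles.to_csv(out / "ensemble_waveforms.csv", index=False,
                         float_format=ff)
    res.beep_events.to_csv(out / "beep_events.csv", index=False,
                           float_format=ff)
    res.beep_overlap.to_csv(out / "beep_overlap.csv", index=False,
                            float_format=ff)
    (out / "manifest.json").write_text(
        json.dumps(res.manifest, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(res.log) + "\n")
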