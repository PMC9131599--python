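"""Delimited-text I/O for trials: raw sEMG CSV, marker CSV, metadata JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import MUSCLES, MarkerTrajectory, RawEmgRecording, Trial

EMG_COLUMNS = ("time_s",) + MUSCLES
MARKER_COLUMNS = ("time_s", "pedal_x", "pedal_y", "pedal_z",
                  "axis_x", "axis_y", "axis_z")


class SchemaError(ValueError):
    """A trial file violates the expected column/consistency schema."""


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_time(t: np.ndarray, path: Path) -> None:
    dt = np.diff(t)
    if np.any(dt < 0):
        raise SchemaError(f"{path}: time_s is not monotonically increasing")
    if np.any(dt == 0):
        raise SchemaError(f"{path}: duplicated timestamp in time_s")


def _check_rate(t: np.ndarray, fs_hz: float, path: Path) -> None:
    if t.size < 2:
        raise SchemaError(f"{path}: fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    if abs(dt * fs_hz - 1.0) > 0.01:
        raise SchemaError(
            f"{path}: sample spacing {dt:g} s inconsistent with declared "
            f"rate {fs_hz:g} Hz"
        )


def write_trial(trial: Trial, out_dir: str | Path) -> dict[str, Path]:
    """Write one trial as emg.csv + markers.csv + metadata.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    emg_path = out / "emg.csv"
    emg = pd.DataFrame({"time_s": trial.emg.t})
    for i, ch in enumerate(trial.emg.channels):
        emg[ch] = trial.emg.samples[i]
    emg.to_csv(emg_path, index=False, float_format="%.9g")

    mk_path = out / "markers.csv"
    mk = pd.DataFrame({
        "time_s": trial.markers.t,
        "pedal_x": trial.markers.pedal[:, 0],
        "pedal_y": trial.markers.pedal[:, 1],
        "pedal_z": trial.markers.pedal[:, 2],
        "axis_x": trial.markers.axis[:, 0],
        "axis_y": trial.markers.axis[:, 1],
        "axis_z": trial.markers.axis[:, 2],
    })
    mk.to_csv(mk_path, index=False, float_format="%.9g")

    meta_path = out / "metadata.json"
    meta = dict(trial.metadata)
    meta.setdefault("emg_fs_hz", trial.emg.fs_hz)
    meta.setdefault("mocap_fs_hz", trial.markers.fs_hz)
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {"emg": emg_path, "markers": mk_path, "metadata": meta_path}


def read_trial(
    emg_csv: str | Path,
    markers_csv: str | Path,
    metadata_json: str | Path,
) -> Trial:
    """Read and validate one trial from delimited text files.

    Raises :class:`SchemaError` naming the offending field on missing
    columns, non-monotone or duplicated timestamps, or a declared-rate
    mismatch.
    """
    emg_csv, markers_csv, metadata_json = map(Path, (emg_csv, markers_csv,
                                                     metadata_json))
    meta = json.loads(metadata_json.read_text())
    for key in ("participant", "condition", "emg_fs_hz", "mocap_fs_hz"):
        if key not in meta:
            raise SchemaError(f"{metadata_json}: missing metadata field {key!r}")

    emg_df = pd.read_csv(emg_csv)
    _check_columns(emg_df, EMG_COLUMNS, emg_csv)
    t_emg = emg_df["time_s"].to_numpy(float)
    _check_time(t_emg, emg_csv)
    _check_rate(t_emg, float(meta["emg_fs_hz"]), emg_csv)
    emg = RawEmgRecording(
        fs_hz=float(meta["emg_fs_hz"]), channels=MUSCLES,
        samples=np.vstack([emg_df[m].to_numpy(float) for m in MUSCLES]),
        t0=float(t_emg[0]))

    mk_df = pd.read_csv(markers_csv)
    _check_columns(mk_df, MARKER_COLUMNS, markers_csv)
    t_mk = mk_df["time_s"].to_numpy(float)
    _check_time(t_mk, markers_csv)
    _check_rate(t_mk, float(meta["mocap_fs_hz"]), markers_csv)
    markers = MarkerTrajectory(
        fs_hz=float(meta["mocap_fs_hz"]), t=t_mk,
        pedal=mk_df[["pedal_x", "pedal_y", "pedal_z"]].to_numpy(float),
        axis=mk_df[["axis_x", "axis_y", "axis_z"]].to_numpy(float))

    return Trial(participant=str(meta["participant"]),
                 condition=str(meta["condition"]),
                 emg=emg, markers=markers, metadata=meta)


def write_wav(path: str | Path, audio: np.ndarray, fs_hz: int = 44100) -> None:
    """Write mono float audio in [-1, 1] as 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(audio, -1.0, 1.0)
    wavfile.write(str(path), int(fs_hz), (pcm * 32767).astype(np.int16))
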