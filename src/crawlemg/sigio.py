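"""Readers and writers for trials, feature datasets, manifests and results.

HDF5 is the primary trial container (signals + metadata + ground-truth timing
in one file); a plain CSV export (T rows × 31 columns: pressure then the 30
EMG channels) is provided as a language-neutral alternative.  Feature datasets
are HDF5; manifests are CSV; evaluation results are JSON plus a confusion CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import EnvelopeCycle
from .gait import LIMBS, GaitTiming
from .synth import N_CHANNELS, Trial

__all__ = ["write_trial", "read_trial", "write_trial_csv", "read_trial_csv",
           "write_features", "read_features", "write_manifest", "read_manifest",
           "write_result_json", "write_confusion_csv"]

_SPEEDS = {"low", "medium", "fast"}
_MODES = {f"M{i}" for i in range(1, 9)} | {"self"}


def write_trial(trial: Trial, path) -> None:
    """Write one trial to an HDF5 file (lossless, float64)."""
    if trial.emg.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} EMG channels, got {trial.emg.shape[0]}")
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=trial.emg)
        f.create_dataset("pressure", data=trial.pressure)
        f.attrs["sample_rate"] = trial.sample_rate
        f.attrs["participant"] = trial.participant_id
        f.attrs["speed"] = trial.speed
        f.attrs["mode"] = trial.mode
        f.attrs["ilcm"] = trial.ilcm
        if trial.timing is not None:
            g = f.create_group("timing")
            for limb in LIMBS:
                g.create_dataset(limb, data=trial.timing.events[limb])
            if trial.timing.cycle_duration_s is not None:
                g.attrs["cycle_duration_s"] = trial.timing.cycle_duration_s


def read_trial(path) -> Trial:
    with h5py.File(path, "r") as f:
        if "emg" not in f or "pressure" not in f:
            raise ValueError(f"{path}: not a trial file (missing emg/pressure)")
        if "sample_rate" not in f.attrs:
            raise ValueError(f"{path}: missing sample_rate attribute")
        emg = f["emg"][...]
        if emg.shape[0] != N_CHANNELS:
            raise ValueError(f"{path}: expected {N_CHANNELS} channels, got {emg.shape[0]}")
        timing = None
        if "timing" in f:
            g = f["timing"]
            events = {limb: g[limb][...] for limb in LIMBS}
            timing = GaitTiming(events,
                                cycle_duration_s=g.attrs.get("cycle_duration_s"))
        return Trial(
            emg,
            f["pressure"][...],
            float(f.attrs["sample_rate"]),
            str(f.attrs["participant"]),
            str(f.attrs["speed"]),
            str(f.attrs["mode"]),
            str(f.attrs.get("ilcm", f.attrs["mode"])),
            timing,
        )


def write_trial_csv(trial: Trial, path) -> None:
    """CSV alternative: T rows × 31 columns (pressure, ch01..ch30); metadata in
    a ``# key=value`` comment header.  Ground-truth timing is not exported."""
    if trial.emg.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} EMG channels, got {trial.emg.shape[0]}")
    cols = {"pressure": trial.pressure}
    for c in range(N_CHANNELS):
        cols[f"ch{c + 1:02d}"] = trial.emg[c]
    frame = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate={trial.sample_rate}\n")
        fh.write(f"# participant={trial.participant_id}\n")
        fh.write(f"# speed={trial.speed}\n# mode={trial.mode}\n# ilcm={trial.ilcm}\n")
        frame.to_csv(fh, index=False)


def read_trial_csv(path) -> Trial:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        frame = pd.read_csv(fh)
    if "sample_rate" not in meta:
        raise ValueError(f"{path}: missing sample_rate header")
    emg_cols = [c for c in frame.columns if c.startswith("ch")]
    if len(emg_cols) != N_CHANNELS:
        raise ValueError(f"{path}: expected {N_CHANNELS} channels, got {len(emg_cols)}")
    return Trial(
        frame[emg_cols].to_numpy().T,
        frame["pressure"].to_numpy(),
        float(meta["sample_rate"]),
        meta.get("participant", "?"),
        meta.get("speed", "?"),
        meta.get("mode", "?"),
        meta.get("ilcm", meta.get("mode", "?")),
        None,
    )


def write_features(samples: list[EnvelopeCycle], path) -> None:
    """Feature dataset as HDF5: X (N, n_points, 30) + per-sample labels."""
    if samples:
        shapes = {s.values.shape for s in samples}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent sample shapes: {shapes}")
        X = np.stack([s.values for s in samples])
    else:
        X = np.empty((0, 0, 0))
    enc = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X)
        f.create_dataset("mode", data=[s.mode for s in samples], dtype=enc)
        f.create_dataset("participant", data=[s.participant_id for s in samples],
                         dtype=enc)
        f.create_dataset("speed", data=[s.speed for s in samples], dtype=enc)


def read_features(path) -> list[EnvelopeCycle]:
    with h5py.File(path, "r") as f:
        X = f["X"][...]
        modes = [m.decode() for m in f["mode"][...]]
        parts = [p.decode() for p in f["participant"][...]]
        speeds = [s.decode() for s in f["speed"][...]]
    return [EnvelopeCycle(X[i], modes[i], parts[i], speeds[i])
            for i in range(len(modes))]


def write_manifest(rows: list[dict], path) -> None:
    """Cohort manifest CSV: path, participant_id, speed, mode, n_cycles."""
    frame = pd.DataFrame(rows, columns=["path", "participant_id", "speed",
                                        "mode", "n_cycles"])
    _validate_manifest(frame)
    frame.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _validate_manifest(frame)
    return frame


def _validate_manifest(frame: pd.DataFrame) -> None:
    if frame["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    bad_speed = set(frame["speed"]) - _SPEEDS
    if bad_speed:
        raise ValueError(f"unknown speeds in manifest: {bad_speed}")
    bad_mode = set(frame["mode"]) - _MODES
    if bad_mode:
        raise ValueError(f"unknown modes in manifest: {bad_mode}")


def write_result_json(result, path) -> None:
    """Evaluation result as JSON (per-fold accuracies + metadata)."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def write_confusion_csv(confusion: np.ndarray, labels: list[str], path) -> None:
    """Confusion matrix CSV; rows are true classes, columns predicted."""
    frame = pd.DataFrame(confusion, index=labels, columns=labels)
    frame.rename_axis("true").to_csv(path)
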