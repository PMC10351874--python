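"""Trial interchange format: long CSV plus a JSON sidecar.

One CSV per trial in long format with columns {t_s, channel, value}, where
channel is one of emg_TA .. emg_GMax, angle_deg or moment_Nm_per_kg, and a
sidecar JSON carrying {subject_id, trial_id, speed_mps, fs_emg, fs_mech,
events_idx}.  The same schema serves as the reader contract for real
recordings exported from any acquisition system.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .combinations import MUSCLES
from .errors import SchemaError, ValidationError
from .synthetic_gait import GaitTrial

__all__ = ["write_trial", "read_trial", "write_dataset", "read_dataset"]

_EMG_CHANNELS = [f"emg_{m}" for m in MUSCLES]
_MECH_CHANNELS = ["angle_deg", "moment_Nm_per_kg"]
_SIDECAR_FIELDS = ["subject_id", "trial_id", "speed_mps", "fs_emg", "fs_mech", "events_idx"]


def write_trial(trial: GaitTrial, csv_path: str | Path, sidecar_json_path: str | Path) -> None:
    """Write one trial; values at 17 significant digits for lossless round-trip."""
    frames = []
    t_emg = np.arange(trial.emg.shape[0]) / trial.fs_emg
    for j, ch in enumerate(_EMG_CHANNELS):
        frames.append(pd.DataFrame({"t_s": t_emg, "channel": ch, "value": trial.emg[:, j]}))
    t_mech = np.arange(len(trial.angle)) / trial.fs_mech
    frames.append(pd.DataFrame({"t_s": t_mech, "channel": "angle_deg", "value": trial.angle}))
    frames.append(
        pd.DataFrame({"t_s": t_mech, "channel": "moment_Nm_per_kg", "value": trial.moment})
    )
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "subject_id": trial.subject_id,
        "trial_id": trial.trial_id,
        "speed_mps": trial.speed,
        "fs_emg": trial.fs_emg,
        "fs_mech": trial.fs_mech,
        "events_idx": [int(e) for e in trial.events],
    }
    Path(sidecar_json_path).write_text(json.dumps(sidecar, indent=1))


def read_trial(csv_path: str | Path, sidecar_json_path: str | Path) -> GaitTrial:
    """Read and validate one trial; every GaitTrial invariant is enforced on load."""
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("t_s", "channel", "value"):
        if col not in df.columns:
            raise SchemaError(col)
    try:
        sidecar = json.loads(Path(sidecar_json_path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError("sidecar", f"sidecar JSON unreadable: {exc}") from exc
    for f in _SIDECAR_FIELDS:
        if f not in sidecar:
            raise SchemaError(f)

    groups = {ch: g.sort_values("t_s") for ch, g in df.groupby("channel")}
    for ch in _EMG_CHANNELS + _MECH_CHANNELS:
        if ch not in groups:
            raise SchemaError(ch, f"trial CSV lacks channel {ch!r}")
    emg = np.column_stack([groups[ch]["value"].to_numpy() for ch in _EMG_CHANNELS])
    angle = groups["angle_deg"]["value"].to_numpy()
    moment = groups["moment_Nm_per_kg"]["value"].to_numpy()
    if len({len(groups[ch]) for ch in _EMG_CHANNELS}) != 1:
        raise ValidationError("EMG channels have unequal lengths")

    return GaitTrial(
        emg=emg,
        angle=angle,
        moment=moment,
        events=np.asarray(sidecar["events_idx"], dtype=int),
        speed=float(sidecar["speed_mps"]),
        subject_id=str(sidecar["subject_id"]),
        trial_id=str(sidecar["trial_id"]),
        fs_emg=float(sidecar["fs_emg"]),
        fs_mech=float(sidecar["fs_mech"]),
    )


def write_dataset(trials: list[GaitTrial], out_dir: str | Path) -> list[tuple[Path, Path]]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in trials:
        csv_path = out_dir / f"{t.trial_id}.csv"
        json_path = out_dir / f"{t.trial_id}.json"
        write_trial(t, csv_path, json_path)
        paths.append((csv_path, json_path))
    return paths


def read_dataset(data_dir: str | Path) -> list[GaitTrial]:
    data_dir = Path(data_dir)
    trials = []
    for csv_path in sorted(data_dir.glob("*.csv")):
        json_path = csv_path.with_suffix(".json")
        if not json_path.exists():
            raise SchemaError("sidecar", f"no sidecar JSON for {csv_path.name}")
        trials.append(read_trial(csv_path, json_path))
    if not trials:
        raise ValidationError(f"no trial CSVs found in {data_dir}")
    return trials
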