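"""File formats: WAV audio, torque-sweep CSV, ground-truth JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .micromotion import TorqueSweep
from .synthetic import ImpactRecording

__all__ = [
    "write_wav",
    "read_wav",
    "write_ground_truth",
    "read_ground_truth",
    "sweeps_to_frame",
    "write_sweeps_csv",
    "read_sweeps_csv",
]

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): None}


def write_wav(path: str | Path, recording: ImpactRecording) -> None:
    """Write a recording as float32 WAV (sample rate from the recording)."""
    wavfile.write(str(path), int(round(recording.sample_rate)), recording.samples.astype(np.float32))


def read_wav(path: str | Path, condition: str = "", specimen_id: str = "") -> ImpactRecording:
    """Read a WAV file into an ImpactRecording.

    Integer PCM is rescaled to [-1, 1]; stereo is collapsed by channel
    averaging.
    """
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        if data.dtype == np.dtype("uint8"):
            data = (data.astype(float) - 128.0) / 128.0
        else:
            data = data.astype(float) / _PCM_SCALE[data.dtype]
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    data = np.clip(data, -1.0, 1.0)
    return ImpactRecording(samples=data, sample_rate=float(rate), condition=condition, specimen_id=specimen_id)


def write_ground_truth(path: str | Path, recording: ImpactRecording) -> None:
    """JSON sidecar with the simulated blow times and labels."""
    payload = {
        "condition": recording.condition,
        "specimen_id": recording.specimen_id,
        "sample_rate": recording.sample_rate,
        "blow_times_s": [] if recording.blow_times is None else list(map(float, recording.blow_times)),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sweeps_to_frame(sweeps: Iterable[TorqueSweep], n_steps_per_cycle: int | None = None) -> pd.DataFrame:
    """Flatten torque sweeps into a tidy table.

    Columns: series, cycle, step, torque_Nm, angle_mdeg, point_label.  The
    cycle/step decomposition assumes equal-length cycles; when
    ``n_steps_per_cycle`` is None the whole series counts as cycle 1.
    """
    rows = []
    for sw in sweeps:
        n = sw.torques.size
        per_cycle = n_steps_per_cycle or n
        for i in range(n):
            rows.append(
                {
                    "series": sw.series_id,
                    "cycle": i // per_cycle + 1,
                    "step": i % per_cycle + 1,
                    "torque_Nm": sw.torques[i],
                    "angle_mdeg": sw.angles[i],
                    "point_label": sw.point_label,
                }
            )
    return pd.DataFrame(rows)


def write_sweeps_csv(path: str | Path, sweeps: Sequence[TorqueSweep], n_steps_per_cycle: int | None = None) -> None:
    sweeps_to_frame(sweeps, n_steps_per_cycle).to_csv(path, index=False)


def read_sweeps_csv(path: str | Path) -> list[TorqueSweep]:
    """Rebuild TorqueSweep objects from a tidy CSV (one per point x series)."""
    df = pd.read_csv(path)
    out = []
    for (label, series), grp in df.groupby(["point_label", "series"], sort=False):
        out.append(
            TorqueSweep(
                torques=grp["torque_Nm"].to_numpy(),
                angles=grp["angle_mdeg"].to_numpy(),
                point_label=str(label),
                series_id=int(series),
            )
        )
    return out
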