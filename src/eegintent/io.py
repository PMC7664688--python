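"""Plain-text interchange for recordings and designs.

A recording is stored as a whitespace-delimited float matrix
(samples x channels) plus a JSON sidecar carrying channel names, sampling
rate and trial metadata.  EDF files can be *read* through :mod:`mne` when it
is installed; all package output is text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from eegintent.synth import RawRecording


def recording_basename(rec: RawRecording) -> str:
    return f"{rec.subject or 'rec'}_q{rec.question:02d}"


def save_recording(rec: RawRecording, directory) -> Path:
    """Write ``<subject>_q<question>.txt`` + ``.json`` sidecar; return txt path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / recording_basename(rec)
    np.savetxt(base.with_suffix(".txt"), rec.signal.T, fmt="%.6f")
    meta = {
        "channel_names": list(rec.channel_names),
        "fs": rec.fs,
        "subject": rec.subject,
        "question": rec.question,
        "scenario_type": rec.scenario_type,
        "answer": rec.answer,
        "responded": rec.responded,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return base.with_suffix(".txt")


def load_recording(path) -> RawRecording:
    """Load a recording saved by :func:`save_recording` (or an EDF file)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    sig = np.loadtxt(path, ndmin=2).T
    return RawRecording(
        channel_names=tuple(meta["channel_names"]),
        signal=sig,
        fs=float(meta["fs"]),
        subject=meta.get("subject", ""),
        question=int(meta.get("question", 0)),
        scenario_type=meta.get("scenario_type", ""),
        answer=meta.get("answer", ""),
        responded=bool(meta.get("responded", True)),
    )


def _read_edf(path: Path) -> RawRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawRecording(
        channel_names=tuple(raw.ch_names),
        signal=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
    )


def save_design(design, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(path, index=False)
    return path


def load_design(path):
    from eegintent.design import ExperimentDesign

    return ExperimentDesign.from_frame(pd.read_csv(Path(path)))


def save_feature_table(table: pd.DataFrame, path) -> Path:
    """CSV + JSON schema sidecar; round-trips bit-exactly via full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    schema = {
        "columns": list(table.columns),
        "dtypes": {c: str(table[c].dtype) for c in table.columns},
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))
    return path


def load_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    schema_path = path.with_suffix(".schema.json")
    df = pd.read_csv(path)
    if schema_path.exists():
        schema = json.loads(schema_path.read_text())
        df = df[schema["columns"]]
    return df
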