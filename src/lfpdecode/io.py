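"""Reading and writing sessions, feature tables, and run manifests.

On-disk session format: a float32 ``.npy`` signal matrix (channels x
samples) with a JSON sidecar header (sampling rate, channel names),
an interval CSV (``start_s,end_s,label``; times in seconds, half-open),
and a JSON metadata file.  EDF recordings are read through ``mne``
when it is installed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SessionRecording
from .labeling import BehaviorIntervals
from .synth import SessionMeta, SyntheticSession

__all__ = [
    "write_session",
    "read_session",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "file_digest",
]


def file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_session(directory: Path, session: SyntheticSession) -> dict:
    """Write one session; returns the manifest entry (paths + digests)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = session.meta.session_id
    entry: dict = {"session_id": sid}
    if session.recording is not None:
        sig = directory / f"{sid}_signal.npy"
        np.save(sig, session.recording.data.astype(np.float32))
        header = directory / f"{sid}_signal.json"
        header.write_text(
            json.dumps(
                {
                    "sampling_rate_hz": session.recording.sampling_rate_hz,
                    "channel_names": list(session.recording.channel_names),
                    "n_samples": int(session.recording.data.shape[1]),
                }
            )
        )
        entry["signal"] = sig.name
        entry["signal_header"] = header.name
    if session.features is not None:
        feats = directory / f"{sid}_features.csv"
        session.features.to_csv(feats, index=False)
        entry["features"] = feats.name
    intervals = directory / f"{sid}_intervals.csv"
    session.intervals.to_csv(intervals)
    meta = directory / f"{sid}_meta.json"
    meta.write_text(json.dumps(dataclasses.asdict(session.meta), indent=1))
    entry["intervals"] = intervals.name
    entry["meta"] = meta.name
    entry["digests"] = {
        k: file_digest(directory / v) for k, v in entry.items() if isinstance(v, str) and k != "session_id"
    }
    return entry


def read_recording(path: Path) -> SessionRecording:
    """Read a continuous recording from .npy+JSON, CSV matrix+JSON, or EDF."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as e:  # pragma: no cover
            raise ImportError("reading EDF requires the optional mne dependency") from e
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return SessionRecording(raw.get_data(), raw.info["sfreq"], tuple(raw.ch_names))
    header = path.with_suffix(".json")
    meta = json.loads(header.read_text())
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter=",")
    return SessionRecording(
        np.asarray(data, dtype=float),
        meta["sampling_rate_hz"],
        tuple(meta["channel_names"]),
    )


def read_session(directory: Path, session_id: str) -> SyntheticSession:
    directory = Path(directory)
    meta = SessionMeta(**json.loads((directory / f"{session_id}_meta.json").read_text()))
    intervals = BehaviorIntervals.from_csv(
        directory / f"{session_id}_intervals.csv", meta.session_length_s
    )
    rec = None
    sig = directory / f"{session_id}_signal.npy"
    if sig.exists():
        rec = read_recording(sig)
    feats = None
    fpath = directory / f"{session_id}_features.csv"
    if fpath.exists():
        feats = pd.read_csv(fpath)
    return SyntheticSession(meta=meta, intervals=intervals, recording=rec, features=feats)


def write_cohort(directory: Path, sessions: list[SyntheticSession], config_info: dict | None = None) -> Path:
    """Write all sessions plus a cohort manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = [write_session(directory, s) for s in sessions]
    manifest = {"config": config_info or {}, "sessions": entries}
    path = directory / "cohort_manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(directory: Path) -> list[SyntheticSession]:
    directory = Path(directory)
    manifest = json.loads((directory / "cohort_manifest.json").read_text())
    return [read_session(directory, e["session_id"]) for e in manifest["sessions"]]
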