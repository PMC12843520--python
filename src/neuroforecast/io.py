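"""File formats: EDF (read-only), the internal EEG container, and CSV tables.

The internal container stores one recording as a pair of files sharing a
basename: ``<name>.json`` (subject id, channel labels, sampling rate, onset
events, dtype, optional provenance) and ``<name>.f32`` (little-endian
float32 voltages, channel-major). It round-trips bit-exactly and avoids any
dependency on binary EEG toolchains. EDF files are read through MNE and
channel labels are normalized onto canonical 10-20 names; video-onset
events are taken from annotations.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import normalize_label
from .recording import EEGRecording
from .tables import StudyTables

CONTAINER_VERSION = "1.0"


def write_container(recording: EEGRecording, basename: str | Path,
                    provenance: dict | None = None) -> tuple[Path, Path]:
    """Write a recording to ``<basename>.json`` + ``<basename>.f32``."""
    base = Path(basename)
    data = np.ascontiguousarray(recording.data, dtype="<f4")
    bin_path = base.with_suffix(".f32")
    bin_path.write_bytes(data.tobytes())
    sidecar = {
        "container_version": CONTAINER_VERSION,
        "subject_id": recording.subject_id,
        "channels": list(recording.channels),
        "fs": recording.fs,
        "n_samples": recording.n_samples,
        "dtype": "<f4",
        "order": "channel-major",
        "unit": "uV",
        "events": [{"video_id": v, "onset_sample": int(s)}
                   for v, s in recording.events],
    }
    if provenance:
        sidecar["provenance"] = provenance
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return json_path, bin_path


def read_container(basename: str | Path) -> EEGRecording:
    """Read a recording previously written by :func:`write_container`."""
    base = Path(basename)
    meta = json.loads(base.with_suffix(".json").read_text())
    raw = np.frombuffer(base.with_suffix(".f32").read_bytes(), dtype=meta["dtype"])
    n_ch = len(meta["channels"])
    data = raw.reshape(n_ch, meta["n_samples"])
    events = [(e["video_id"], int(e["onset_sample"])) for e in meta["events"]]
    return EEGRecording(subject_id=meta["subject_id"],
                        channels=tuple(meta["channels"]),
                        fs=float(meta["fs"]), data=data, events=events)


def _read_edf(path: Path) -> EEGRecording:
    from mne.io import read_raw_edf

    raw = read_raw_edf(str(path), preload=True, verbose=False)
    labels = []
    for ch in raw.ch_names:
        try:
            labels.append(normalize_label(ch))
        except ValueError as err:
            raise ValueError(f"EDF {path.name}: {err}") from None
    events = []
    for ann in raw.annotations:
        events.append((str(ann["description"]),
                       int(round(ann["onset"] * raw.info["sfreq"]))))
    if not events:
        raise ValueError(f"EDF {path.name}: no video onsets found in annotations")
    data = raw.get_data() * 1e6  # MNE volts -> microvolts
    return EEGRecording(subject_id=path.stem, channels=tuple(labels),
                        fs=float(raw.info["sfreq"]), data=data, events=events)


def read_eeg(path: str | Path) -> EEGRecording:
    """Read one recording from an EDF file or the internal container."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    elif path.suffix in (".json", ".f32", ""):
        rec = read_container(path.with_suffix(""))
    else:
        raise ValueError(f"unknown EEG format: {path.name!r} (expect .edf or container)")
    if not rec.events:
        raise ValueError(f"{path.name}: no video onsets")
    return rec


# ---------------------------------------------------------------------------
# behavioral tables
# ---------------------------------------------------------------------------

_TABLE_FILES = {"ratings": "ratings.csv", "population": "population.csv",
                "outcomes": "outcomes.csv", "sentiment": "sentiment.csv",
                "videos": "videos.csv"}


def write_tables(tables: StudyTables, directory: str | Path) -> dict[str, Path]:
    """Write the study tables as CSV files into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in _TABLE_FILES:
        df = getattr(tables, name)
        if df is None:
            continue
        p = directory / _TABLE_FILES[name]
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_tables(directory: str | Path | None = None, *,
                ratings: str | Path | None = None,
                population: str | Path | None = None,
                outcomes: str | Path | None = None,
                sentiment: str | Path | None = None,
                videos: str | Path | None = None) -> StudyTables:
    """Load and validate the study tables from CSV.

    Either pass a directory holding the conventional filenames or the
    individual paths. Validation (Likert ranges, video-id consistency,
    deal/amount coherence) happens in :class:`StudyTables`.
    """
    if directory is not None:
        directory = Path(directory)
        ratings = ratings or directory / _TABLE_FILES["ratings"]
        population = population or directory / _TABLE_FILES["population"]
        outcomes = outcomes or directory / _TABLE_FILES["outcomes"]
        s = directory / _TABLE_FILES["sentiment"]
        sentiment = sentiment or (s if s.exists() else None)
        v = directory / _TABLE_FILES["videos"]
        videos = videos or (v if v.exists() else None)
    if ratings is None or population is None or outcomes is None:
        raise ValueError("ratings, population and outcomes tables are required")
    return StudyTables(
        ratings=pd.read_csv(ratings),
        population=pd.read_csv(population),
        outcomes=pd.read_csv(outcomes),
        sentiment=pd.read_csv(sentiment) if sentiment is not None else None,
        videos=pd.read_csv(videos) if videos is not None else None,
    )
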