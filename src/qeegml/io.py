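"""Reading and writing recordings, manifests and feature tables.

Recordings are read from EDF (one subject per file, via MNE) or from plain
delimited channel x time matrices; cohorts are written as one delimited
matrix per subject plus a manifest CSV (subject_id, diagnosis,
amyloid_label, path).  Feature tables round-trip as CSV with the canonical
``channel.band`` header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CHANNELS, EEGRecording, validate_feature_table
from .synthetic import CohortSubject

_ALIASES = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}  # modern 10-20 names


def _canonical_channel(name: str) -> str | None:
    base = name.strip().replace("EEG", "").replace("eeg", "")
    base = base.split("-")[0].strip()  # e.g. "Fp1-REF"
    low = base.lower()
    for ch in CHANNELS:
        if low == ch.lower():
            return ch
    return _ALIASES.get(low)


def read_edf(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    """Load a 19-channel EDF recording into the canonical montage order.

    Channel labels are matched case-insensitively, tolerating reference
    suffixes (``Fp1-REF``) and the modern T7/T8/P7/P8 synonyms.  Voltages
    are converted to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    mapping: dict[str, str] = {}
    for name in raw.ch_names:
        canon = _canonical_channel(name)
        if canon is not None and canon not in mapping.values():
            mapping[name] = canon
    missing = set(CHANNELS) - set(mapping.values())
    if missing:
        raise ValueError(f"EDF file lacks required channels: {sorted(missing)}")
    picks = [name for name in raw.ch_names if name in mapping]
    data = raw.get_data(picks=picks) * 1e6  # Volt -> microvolt
    order = [ [mapping[p] for p in picks].index(ch) for ch in CHANNELS ]
    return EEGRecording(
        samples=data[order],
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id or Path(path).stem,
    )


def write_recording_tsv(rec: EEGRecording, path: str | Path) -> None:
    """Plain-text channel x time matrix with an ``# fs=`` header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs} reference={rec.reference}\n")
        fh.write("\t".join(rec.channels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.6f", delimiter="\t")


def read_recording_tsv(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=...' header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        cols = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if tuple(cols) != CHANNELS:
        raise ValueError(f"{path}: columns must be the canonical 19 channel labels")
    return EEGRecording(
        samples=data.T,
        fs=float(meta["fs"]),
        reference=meta.get("reference", "as-recorded"),
        subject_id=subject_id or path.stem,
    )


def write_cohort(
    cohort: Sequence[CohortSubject], out_dir: str | Path
) -> pd.DataFrame:
    """Write one matrix file per subject plus ``manifest.csv``; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.subject_id}.tsv"
        write_recording_tsv(s.recording, out_dir / fname)
        rows.append(
            {
                "subject_id": s.subject_id,
                "diagnosis": s.diagnosis,
                "amyloid_label": s.label,
                "path": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"subject_id", "path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return manifest


def load_recording(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    """Dispatch on file extension: ``.edf`` via MNE, anything else as TSV."""
    if str(path).lower().endswith(".edf"):
        return read_edf(path, subject_id=subject_id)
    return read_recording_tsv(path, subject_id=subject_id)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path, validate: bool = True) -> pd.DataFrame:
    table = pd.read_csv(path)
    if validate:
        validate_feature_table(table)
    return table
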