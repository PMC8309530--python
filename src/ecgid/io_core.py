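"""Readers, writers and manifests shared by all modules.

On-disk formats are plain text, pinned to a fixed CSV dialect (UTF-8,
comma separator, ``.`` decimal, mandatory header) so fixtures are
bit-stable across platforms:

* recording — ``<stem>.csv`` with columns ``sample_index,voltage`` plus a
  JSON sidecar ``<stem>.json`` holding the acquisition labels and sampling
  rate;
* symbol sequence — one line of symbols in a ``.seq`` text file;
* context model — JSON via :meth:`ecgid.fcm.ContextModel.to_dict`;
* metrics — JSON via :meth:`ecgid.identify.MetricsReport.to_dict`;
* manifest — CSV of every recording with its labels and SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ManifestError, ParseError
from .fcm import ContextModel
from .identify import MetricsReport
from .signal_prep import RawECG, SymbolSequence, default_alphabet
from .synthetic_ecg import CONDITIONS, PLACEMENTS, Cohort

__all__ = [
    "read_recording",
    "write_recording",
    "read_sequence",
    "write_sequence",
    "read_model",
    "write_model",
    "read_metrics",
    "write_metrics",
    "write_cohort",
    "read_manifest",
]

_SIDE_FIELDS = ("subject_id", "session", "placement", "condition", "fs")
SCHEMA_VERSION = 1


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: RawECG, csv_path) -> Path:
    """One CSV (sample_index, voltage) plus a JSON label sidecar."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {"sample_index": np.arange(rec.samples.size), "voltage": rec.samples}
    )
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "session": rec.session,
        "placement": rec.placement,
        "condition": rec.condition,
        "fs": rec.fs,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return csv_path


def read_recording(csv_path) -> RawECG:
    """Load a recording and its labels; typed errors on malformed files."""
    csv_path = Path(csv_path)
    side_path = _sidecar_path(csv_path)
    if not side_path.exists():
        raise ParseError(f"missing sidecar {side_path}")
    try:
        sidecar = json.loads(side_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed sidecar {side_path}: {exc}") from exc
    for name in _SIDE_FIELDS:
        if name not in sidecar:
            raise ParseError(f"sidecar {side_path} missing field {name!r}")
    if sidecar["placement"] not in PLACEMENTS:
        raise ParseError(f"placement {sidecar['placement']!r} outside vocabulary")
    if sidecar["condition"] not in CONDITIONS:
        raise ParseError(f"condition {sidecar['condition']!r} outside vocabulary")
    try:
        frame = pd.read_csv(csv_path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"malformed recording CSV {csv_path}: {exc}") from exc
    if "voltage" not in frame.columns:
        raise ParseError(f"recording CSV {csv_path} lacks a 'voltage' column")
    return RawECG(
        samples=frame["voltage"].to_numpy(dtype=float),
        fs=float(sidecar["fs"]),
        subject_id=str(sidecar["subject_id"]),
        session=int(sidecar["session"]),
        placement=sidecar["placement"],
        condition=sidecar["condition"],
    )


def write_sequence(seq: SymbolSequence, path) -> Path:
    path = Path(path)
    path.write_text(seq.symbols + "\n")
    return path


def read_sequence(path, alphabet_size: int = 20) -> SymbolSequence:
    text = Path(path).read_text().strip()
    if not text:
        raise ParseError(f"empty sequence file {path}")
    return SymbolSequence(symbols=text, alphabet=default_alphabet(alphabet_size))


def write_model(model: ContextModel, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), sort_keys=True) + "\n")
    return path


def read_model(path) -> ContextModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed model file {path}: {exc}") from exc
    return ContextModel.from_dict(data)


def write_metrics(report: MetricsReport, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return path


def read_metrics(path) -> MetricsReport:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed metrics file {path}: {exc}") from exc
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"unsupported metrics schema version in {path}")
    return MetricsReport.from_dict(data)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write every recording plus a checksummed manifest.csv; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.recordings:
        stem = f"{rec.subject_id}_s{rec.session}_{rec.placement}_{rec.condition}"
        path = write_recording(rec, out / f"{stem}.csv")
        rows.append(
            {
                "path": path.name,
                "subject_id": rec.subject_id,
                "session": rec.session,
                "placement": rec.placement,
                "condition": rec.condition,
                "fs": rec.fs,
                "duration": rec.duration,
                "sha256": _sha256(path),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.9g")
    return manifest


def read_manifest(manifest_path, verify: bool = True) -> pd.DataFrame:
    """Load a manifest; with ``verify``, re-checksum every referenced file."""
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path)
    required = {"path", "subject_id", "session", "placement", "condition", "fs", "sha256"}
    missing = required - set(frame.columns)
    if missing:
        raise ManifestError(f"manifest missing columns {sorted(missing)}")
    if frame["path"].duplicated().any():
        raise ManifestError("manifest contains duplicate paths")
    if verify:
        for _, row in frame.iterrows():
            target = manifest_path.parent / row["path"]
            if not target.exists():
                raise ManifestError(f"manifest references missing file {target}")
            if _sha256(target) != row["sha256"]:
                raise ManifestError(f"checksum mismatch for {target}")
    return frame
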