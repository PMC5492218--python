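"""Session-file I/O: delimited text sessions plus a JSON manifest.

A session file is CSV with a header row: 7 feature columns (``ch1`` ..
``ch7``, volts in [0, 5]) followed by an integer ``label`` column (1-8).
A manifest is a JSON sidecar listing session files in validating order
(the first entry initializes the classifier) together with the ordering
tag and generator/drift provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .drift import Session, SessionSequence

N_CHANNELS = 7
FEATURE_RANGE = (0.0, 5.0)
LABEL_RANGE = (1, 8)

CHANNEL_COLUMNS = [f"ch{i + 1}" for i in range(N_CHANNELS)]


class SessionFormatError(ValueError):
    """Malformed session file; the message names the offending row."""


def write_session(session: Session, path: str | Path) -> None:
    df = pd.DataFrame(session.features, columns=CHANNEL_COLUMNS)
    df["label"] = session.labels
    # default float formatting is the shortest exact repr: lossless round-trip
    df.to_csv(path, index=False)


def read_session(path: str | Path) -> Session:
    """Read and validate one session file; full-precision round-trip."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CHANNEL_COLUMNS + ["label"] if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")
    feats = df[CHANNEL_COLUMNS].to_numpy(dtype=float)
    labels = df["label"].to_numpy()

    bad = np.flatnonzero(
        (feats < FEATURE_RANGE[0]).any(axis=1)
        | (feats > FEATURE_RANGE[1]).any(axis=1)
        | ~np.isfinite(feats).all(axis=1)
    )
    if bad.size:
        # +2: header line and 1-based numbering
        raise SessionFormatError(
            f"{path}: feature out of range [0, 5] at line {bad[0] + 2}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        frac = labels != np.floor(labels)
        if frac.any():
            raise SessionFormatError(
                f"{path}: non-integer label at line {np.flatnonzero(frac)[0] + 2}"
            )
        labels = labels.astype(int)
    bad = np.flatnonzero((labels < LABEL_RANGE[0]) | (labels > LABEL_RANGE[1]))
    if bad.size:
        raise SessionFormatError(
            f"{path}: label outside 1..8 at line {bad[0] + 2}"
        )
    return Session(feats, labels)


def write_sequence(seq: SessionSequence, out_dir: str | Path,
                   prefix: str = "session") -> Path:
    """Write every session plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, session in enumerate(seq.sessions):
        name = f"{prefix}_{i:03d}.csv"
        write_session(session, out_dir / name)
        files.append(name)
    manifest = {
        "sessions": files,
        "initialization_session": files[0],
        "order_tag": seq.order_tag,
        "n": seq.n,
        "meta": seq.meta,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_sequence(manifest_path: str | Path) -> SessionSequence:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    sessions = [read_session(base / f) for f in manifest["sessions"]]
    return SessionSequence(
        sessions,
        order_tag=manifest.get("order_tag", "natural"),
        n=manifest.get("n"),
        meta=manifest.get("meta", {}),
    )
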