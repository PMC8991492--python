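"""Checked CSV input and checksum helpers for the pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


class SchemaError(ValueError):
    """An input file violates its expected schema."""


def read_csv_checked(path, required_columns=(), name: str | None = None) -> pd.DataFrame:
    path = Path(path)
    name = name or path.name
    if not path.exists():
        raise SchemaError(f"{name}: file not found at {path}")
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
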