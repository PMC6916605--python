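"""Delimited-text persistence for record streams and stage outputs.

Each dataset directory holds one CSV per stream plus ``manifest.json``
describing columns, row counts and the generating config hash.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

STREAM_FILES = {
    "patients": "patients.csv",
    "prescriptions": "prescriptions.csv",
    "bp": "bp_measurements.csv",
    "events": "clinical_events.csv",
}


def write_streams(streams: dict, directory, extra_manifest: dict | None = None):
    """Write the record streams as CSVs with a schema manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"streams": {}}
    for name, fname in STREAM_FILES.items():
        df = streams[name]
        df.to_csv(directory / fname, index=False)
        manifest["streams"][name] = {
            "file": fname, "rows": len(df),
            "columns": {c: str(df[c].dtype) for c in df.columns},
        }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return directory


def read_streams(directory) -> dict:
    directory = Path(directory)
    out = {}
    for name, fname in STREAM_FILES.items():
        df = pd.read_csv(directory / fname)
        if name == "patients":
            df["death_date"] = df["death_date"].astype("Int64")
        out[name] = df
    return out


def write_table(df: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
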