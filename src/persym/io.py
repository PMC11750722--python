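"""Readers, writers and run manifests for the CSV/JSON pipeline surface."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

MAIN_REQUIRED = ("participant_id", "visit_month")
OTHER_REQUIRED = ("participant_id", "visit_month", "symptom_label", "vas")
COHORT_REQUIRED = ("participant_id", "arm", "chosen_symptom", "sex", "age_band",
                   "ethnicity", "imd_band")


class SchemaError(ValueError):
    """An input table is missing required columns."""


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_main_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, MAIN_REQUIRED, path)
    return df


def read_other_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, OTHER_REQUIRED, path)
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COHORT_REQUIRED, path)
    return df


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_bundle(
    out_dir,
    frames: Mapping[str, pd.DataFrame],
    manifest: Dict,
    texts: Optional[Mapping[str, str]] = None,
) -> Path:
    """Atomically write a results bundle (CSVs + JSON manifest).

    Everything is staged in a temporary sibling directory and moved into
    place only once every file has been written, so a failure never leaves
    a partial bundle at ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    stage = Path(tempfile.mkdtemp(prefix=".persym-", dir=out_dir.parent))
    try:
        for name, df in frames.items():
            df.to_csv(stage / name, index=False)
        for name, text in (texts or {}).items():
            (stage / name).write_text(text)
        manifest = dict(manifest)
        manifest["config_hash"] = config_hash(manifest.get("config", {}))
        (stage / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        out_dir.mkdir(exist_ok=True)
        for f in stage.iterdir():
            os.replace(f, out_dir / f.name)
    finally:
        if stage.exists():
            for f in stage.iterdir():
                f.unlink()
            stage.rmdir()
    return out_dir
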