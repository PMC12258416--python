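"""Readers and writers for the package's table and report dialects.

Peak tables and 1D chelator tables travel as CSV with documented headers;
reports and truth sidecars are JSON.  Concentrations in files are μM and
dissociation constants in reports are nM.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from chelcomp.errors import ValidationError
from chelcomp.intensity import CHELATOR_COLUMNS, PEAK_COLUMNS, PeakTable
from chelcomp.synthetic import SyntheticConfig, SyntheticTruth


def read_peak_table(path: str | Path, control_conc: float) -> PeakTable:
    """Load a peak-table CSV (columns: peak_id, point_index, zn_added,
    time_h, intensity, noise, distinct)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"{path}: empty peak table")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    bad = df[df[["intensity", "noise"]].isna().any(axis=1)]
    if not bad.empty:
        lines = ", ".join(str(i + 2) for i in bad.index[:10])  # +2: header + 1-based
        raise ValidationError(f"{path}: malformed rows at lines {lines}")
    return PeakTable(df, control_conc=control_conc)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)


def read_chelator_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CHELATOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def write_chelator_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[CHELATOR_COLUMNS].to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "config": dataclasses.asdict(truth.config),
        "free_fractions": list(truth.free_fractions),
        "czn": list(truth.czn),
        "c_totals": list(truth.c_totals),
    }
    write_json(payload, path)


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = read_json(path)
    cfg = SyntheticConfig(**payload["config"])
    return SyntheticTruth(
        config=cfg,
        free_fractions=tuple(payload["free_fractions"]),
        czn=tuple(payload.get("czn", ())),
        c_totals=tuple(payload.get("c_totals", ())),
    )


def write_json(payload: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON ({exc})") from exc


def load_run_config(path: str | Path | None) -> dict:
    """Load the optional nested key-value run configuration (YAML)."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid config ({exc})") from exc
    if payload is None:
        return {}
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return payload
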