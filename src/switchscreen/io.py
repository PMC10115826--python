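"""Reading and writing the pipeline's table formats.

Event tables are CSV with the exact header
``event_id,fsc,ssc,reporter,reference``; sample sheets are CSV with header
``sample_id,switch_id,trigger_id,condition,replicate,role``; matrices and
summary tables are TSV.  Floats are serialized with 17 significant digits
so that read(write(x)) round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .simulate import (
    EVENT_COLUMNS,
    SAMPLE_SHEET_COLUMNS,
    EventTable,
    ScreenDataset,
)

__all__ = [
    "read_events", "write_events", "read_sample_sheet", "write_sample_sheet",
    "read_matrix", "write_matrix", "read_gate_measurements",
    "write_screen_dataset", "read_screen_dataset", "write_json",
]

FLOAT_FMT = "%.17g"


def read_events(path) -> pd.DataFrame:
    """Read one sample's event table from CSV."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: event table is missing columns {missing}")
    return df[EVENT_COLUMNS]


def write_events(events, path) -> None:
    df = events.events if isinstance(events, EventTable) else events
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: sample sheet is missing columns {missing}")
    for i, row in df.iterrows():
        if not str(row["sample_id"]).strip():
            raise SchemaError(f"{path}: row {i + 1} has an empty sample_id")
        if row["role"] not in ("measurement", "mock", "no_gRNA_control"):
            raise SchemaError(
                f"{path}: row {i + 1} (sample {row['sample_id']}) has "
                f"unknown role {row['role']!r}"
            )
    return df[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with row labels in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix, path) -> None:
    values = getattr(matrix, "values", None)
    df = values if isinstance(values, pd.DataFrame) else matrix
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_gate_measurements(path) -> pd.DataFrame:
    """Read a long-format gate table: ``circuit_id, state, ni`` (TSV)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("circuit_id", "state", "ni") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: gate measurement table is missing columns {missing}")
    return df


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_screen_dataset(dataset: ScreenDataset, outdir) -> Path:
    """Write every event table, the sample sheet and (if present) the
    ground-truth panel of a simulated dataset into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    events_dir = out / "events"
    events_dir.mkdir(exist_ok=True)
    for sid, tbl in dataset.tables.items():
        write_events(tbl, events_dir / f"{sid}.csv")
    write_sample_sheet(dataset.sample_sheet, out / "sample_sheet.csv")
    if dataset.panel is not None:
        (out / "ground_truth.json").write_text(dataset.panel.to_json() + "\n")
    return out


def read_screen_dataset(indir) -> ScreenDataset:
    """Load a dataset written by :func:`write_screen_dataset`."""
    indir = Path(indir)
    sheet = read_sample_sheet(indir / "sample_sheet.csv")
    tables: dict[str, EventTable] = {}
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        events = read_events(indir / "events" / f"{sid}.csv")
        tables[sid] = EventTable(
            events=events,
            sample_id=sid,
            switch_id=row["switch_id"] or None,
            trigger_id=row["trigger_id"] or None,
            condition=row["condition"],
            replicate=int(row["replicate"]),
            role=row["role"],
        )
    panel = None
    gt = indir / "ground_truth.json"
    if gt.exists():
        from .simulate import GroundTruthPanel

        panel = GroundTruthPanel.from_json(gt.read_text())
    return ScreenDataset(tables=tables, sample_sheet=sheet, panel=panel)
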