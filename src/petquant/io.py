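"""Tab-separated file formats.

One unit system throughout: time in minutes, activity in kBq/mL, dose in
MBq, weight in grams, injected mass in ug/kg. Decimal points, no thousands
separators. Readers validate and reject — they never silently coerce.

TAC table:      frame_start_min  frame_end_min  <region> [<region> ...]
Blood table:    time_min  whole_blood  plasma  [parent_fraction]
Subject table:  subject_id  genotype  session  injected_dose_MBq
                body_weight_g  injected_mass_ug_per_kg
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import FrameSchedule, TacTable
from .errors import SchemaError, ValidationError
from .input_function import BloodSampleTable

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_blood_table",
    "write_blood_table",
    "read_subject_table",
    "write_subject_table",
]

_FLOAT_FMT = "%.17g"  # exact float round trip


def _read_tsv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse tab-separated file: {exc}") from exc
    return frame


def _numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, data row {row}")
        frame[col] = converted
    return frame


def read_tac_table(path) -> TacTable:
    frame = _read_tsv(path)
    required = ["frame_start_min", "frame_end_min"]
    if list(frame.columns[:2]) != required:
        raise SchemaError(f"{path}: first columns must be {required}, got {list(frame.columns[:2])}")
    regions = [c for c in frame.columns if c not in required]
    if not regions:
        raise SchemaError(f"{path}: no region columns")
    frame = _numeric(frame, frame.columns, path)
    starts = frame["frame_start_min"].to_numpy(dtype=float)
    ends = frame["frame_end_min"].to_numpy(dtype=float)
    if np.any(ends <= starts):
        row = int(np.argmax(ends <= starts)) + 1
        raise SchemaError(f"{path}: frame end <= start at data row {row}")
    gaps = starts[1:] - ends[:-1]
    if starts[0] != 0.0:
        raise SchemaError(f"{path}: first frame must start at 0, data row 1")
    if np.any(np.abs(gaps) > 1e-9):
        row = int(np.argmax(np.abs(gaps) > 1e-9)) + 2
        raise SchemaError(f"{path}: non-contiguous frames at data row {row}")
    schedule = FrameSchedule(starts, ends - starts)
    try:
        return TacTable(schedule, frame[regions])
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_tac_table(tac: TacTable, path) -> None:
    out = tac.values.copy()
    out.insert(0, "frame_start_min", tac.schedule.starts)
    out.insert(1, "frame_end_min", tac.schedule.ends)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_blood_table(path) -> BloodSampleTable:
    frame = _read_tsv(path)
    required = ["time_min", "whole_blood", "plasma"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    frame = _numeric(frame, [c for c in frame.columns if c in required + ["parent_fraction"]], path)
    pf = frame["parent_fraction"].to_numpy(dtype=float) if "parent_fraction" in frame.columns else None
    try:
        return BloodSampleTable(
            time=frame["time_min"].to_numpy(dtype=float),
            whole_blood=frame["whole_blood"].to_numpy(dtype=float),
            plasma=frame["plasma"].to_numpy(dtype=float),
            parent_fraction=pf,
        )
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_blood_table(samples: BloodSampleTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    samples.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


SUBJECT_COLUMNS = [
    "subject_id", "genotype", "session",
    "injected_dose_MBq", "body_weight_g", "injected_mass_ug_per_kg",
]


def read_subject_table(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    frame = _numeric(frame, SUBJECT_COLUMNS[3:], path)
    bad_geno = set(frame["genotype"]) - {"WT", "HET"}
    if bad_geno:
        raise SchemaError(f"{path}: genotype must be WT or HET, found {sorted(bad_geno)}")
    if (frame["injected_dose_MBq"] <= 0).any() or (frame["body_weight_g"] <= 0).any():
        raise SchemaError(f"{path}: doses and body weights must be positive")
    dup = frame.duplicated(subset=["subject_id", "session"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy())) + 1
        raise SchemaError(f"{path}: duplicate (subject, session) at data row {row}")
    return frame[SUBJECT_COLUMNS].reset_index(drop=True)


def write_subject_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame[SUBJECT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
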