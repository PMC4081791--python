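"""Tidy CSV persistence for cohorts (one row per patient-timepoint) plus a
JSON ground-truth sidecar. The column dictionary is versioned in
``COLUMNS``; write/read round-trips records exactly."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .cohort import LatentAssignment
from .records import (INTERVIEW_FLAGS, AxisIFlags, EdeqItems, InterviewItems,
                      PatientRecord, ScaleScores)

SCHEMA_VERSION = 1

_EDEQ_FIELDS = tuple(EdeqItems.__dataclass_fields__)
_SCALE_FIELDS = tuple(ScaleScores.__dataclass_fields__)
_COMORBID_FIELDS = tuple(AxisIFlags.__dataclass_fields__)
_COUNT_FIELDS = ("obe_freq", "sbe_freq", "vomit_freq", "laxative_freq",
                 "diuretic_freq", "exercise_freq", "fasting_score")

COLUMNS: tuple[str, ...] = (("patient_id", "timepoint", "bmi", "age")
                            + INTERVIEW_FLAGS + _EDEQ_FIELDS + _SCALE_FIELDS
                            + _COMORBID_FIELDS)


class SchemaError(ValueError):
    """Cohort file violates the column dictionary; message carries
    row/column coordinates where applicable."""


def write_cohort(records, path) -> None:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "timepoint": r.timepoint,
               "bmi": r.bmi, "age": r.age}
        for name in INTERVIEW_FLAGS:
            row[name] = int(getattr(r.interview, name))
        for name in _EDEQ_FIELDS:
            row[name] = getattr(r.edeq, name)
        for name in _SCALE_FIELDS:
            row[name] = getattr(r.scales, name)
        for name in _COMORBID_FIELDS:
            row[name] = int(getattr(r.comorbidity, name))
        rows.append(row)
    # %.17g round-trips doubles exactly (write∘read = id)
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False,
                                                     float_format="%.17g")


def read_cohort(path) -> list[PatientRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        for col in _COUNT_FIELDS:
            val = row[col]
            try:
                ok = float(val) == int(val) and int(val) >= 0
            except (TypeError, ValueError):
                ok = False
            if not ok:
                raise SchemaError(
                    f"row {i}, column {col!r}: expected a non-negative "
                    f"integer count, got {val!r}")
        try:
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                timepoint=str(row["timepoint"]),
                bmi=float(row["bmi"]), age=float(row["age"]),
                interview=InterviewItems(**{
                    f: bool(int(row[f])) for f in INTERVIEW_FLAGS}),
                edeq=EdeqItems(**{
                    f: (int(row[f]) if f in _COUNT_FIELDS else float(row[f]))
                    for f in _EDEQ_FIELDS}),
                scales=ScaleScores(**{
                    f: float(row[f]) for f in _SCALE_FIELDS}),
                comorbidity=AxisIFlags(**{
                    f: bool(int(row[f])) for f in _COMORBID_FIELDS}))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_truth(truths, path) -> None:
    Path(path).write_text(json.dumps([asdict(t) for t in truths],
                                     indent=0, sort_keys=True) + "\n")


def read_truth(path) -> list[LatentAssignment]:
    return [LatentAssignment(**d) for d in json.loads(Path(path).read_text())]
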