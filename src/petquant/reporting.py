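"""Regional summaries and group descriptives in long ("vertical") CSV form.

Every output measure occupies one row keyed by BIDS entities (subject,
session, task, run), processing stage, region and metric, which keeps the
files trivially consumable by R / pandas / scikit-learn.  Failed fits are
written as empty value cells rather than dropped rows so group n stays
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes_io import DynamicPET, LabelVolume, Volume3D

CSV_HEADER = ["sub", "ses", "task", "run", "stage", "region", "metric", "value"]


class ReportingError(ValueError):
    pass


@dataclass
class ResultRow:
    subject_id: str
    stage: str
    region: str
    metric: str
    value: float | None
    session_id: str | None = None
    task_id: str | None = None
    run_id: str | None = None


def regional_summary(data, labels: LabelVolume, stage: str, metric: str,
                     subject_id: str = "", session_id=None, task_id=None,
                     run_id=None, include_background: bool = False) -> list[ResultRow]:
    """Regional mean of a parametric map (plain mean) or a dynamic volume
    (duration-weighted mean over frames, then regional mean).

    Background (label 0) is excluded by default.
    """
    if isinstance(data, DynamicPET):
        w = data.frame_durations / data.frame_durations.sum()
        vol = np.tensordot(data.frames, w, axes=([3], [0]))
    elif isinstance(data, Volume3D):
        vol = data.data
    else:
        vol = np.asarray(data, dtype=float)
    if vol.shape != labels.labels.shape:
        raise ReportingError("labels are not aligned to the data grid")
    rows: list[ResultRow] = []
    ids = labels.region_ids(include_background=include_background)
    support = vol != 0
    if not any((labels.labels == rid).any() for rid in ids):
        raise ReportingError("no regions present in the label volume")
    overlap = support & (labels.labels > 0 if not include_background
                         else np.ones_like(support))
    if not overlap.any():
        raise ReportingError("no overlap between labels and data support")
    for rid in ids:
        m = labels.labels == rid
        rows.append(ResultRow(
            subject_id=subject_id, stage=stage,
            region=labels.region_name(rid), metric=metric,
            value=float(vol[m].mean()),
            session_id=session_id, task_id=task_id, run_id=run_id))
    return rows


def rows_to_frame(rows: list[ResultRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "sub": [r.subject_id for r in rows],
        "ses": [r.session_id or "" for r in rows],
        "task": [r.task_id or "" for r in rows],
        "run": [r.run_id or "" for r in rows],
        "stage": [r.stage for r in rows],
        "region": [r.region for r in rows],
        "metric": [r.metric for r in rows],
        "value": [r.value for r in rows],
    })


_GROUP_COLUMNS = {"subject": "sub", "session": "ses", "task": "task"}


def group_descriptives(rows: list[ResultRow],
                       group_by=("subject",)) -> pd.DataFrame:
    """mean / sd / min / max / n per (group, region, metric).

    ``group_by`` is any subset of {subject, session, task}; sd is reported
    as 0 for singleton groups.
    """
    if not rows:
        raise ReportingError("no rows to summarize")
    for key in group_by:
        if key not in _GROUP_COLUMNS:
            raise ReportingError(f"unknown group key {key!r}")
    df = rows_to_frame(rows)
    keys = [_GROUP_COLUMNS[k] for k in group_by] + ["region", "metric"]
    grouped = df.groupby(keys, dropna=False)["value"]
    out = grouped.agg(mean="mean", sd="std", min="min", max="max", n="count")
    out["sd"] = out["sd"].fillna(0.0)
    return out.reset_index().sort_values(keys, kind="stable").reset_index(drop=True)


def write_vertical_csv(rows: list[ResultRow], path) -> None:
    """Write rows as long-format CSV with the stable header
    ``sub,ses,task,run,stage,region,metric,value`` and deterministic row
    order; missing entities and failed fits are empty cells."""
    df = rows_to_frame(rows)
    df = df.sort_values(CSV_HEADER[:-1], kind="stable")
    lines = [",".join(CSV_HEADER)]
    for _, row in df.iterrows():
        value = "" if row["value"] is None or (isinstance(row["value"], float)
                                               and np.isnan(row["value"])) \
            else f"{row['value']:.10g}"
        lines.append(",".join([str(row[c]) for c in CSV_HEADER[:-1]] + [value]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vertical_csv(path) -> list[ResultRow]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != CSV_HEADER:
        raise ReportingError(f"unexpected header in {path}")
    rows = []
    for _, r in df.iterrows():
        rows.append(ResultRow(
            subject_id=r["sub"], session_id=r["ses"] or None,
            task_id=r["task"] or None, run_id=r["run"] or None,
            stage=r["stage"], region=r["region"], metric=r["metric"],
            value=float(r["value"]) if r["value"] != "" else None))
    return rows
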