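"""File I/O: long-format panel CSV and the recurrence-table adapter.

Panel CSV layout (one row per subject-visit, frozen column order)::

    subject_id, visit, t_gap, y, x1, ..., xp

``t_gap`` is the increment since the previous visit, not cumulative time;
cumulative inputs must be differenced before loading.  ``x1`` is the
intercept column of ones.

Recurrence tables follow the standard bladder-tumour layout::

    id, rx, number, size, stop, enum, event

with ``rx`` the treatment arm (1 = placebo, 2 = thiotepa), ``number`` the
initial tumour count (8 codes "8 or more" and is kept as numeric 8),
``size`` the largest initial tumour size in cm, ``stop`` the gap time since
the previous visit, ``enum`` the recurrence index (1-4) and ``event`` the
binary recurrence indicator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import PanelDataset, SubjectRecord

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "panel_to_frame",
    "read_recurrence_csv",
    "bladder_to_panel",
    "ZERO_GAP_FLOOR",
]

# stop == 0 rows are floored to this value: the exponential density needs t > 0
ZERO_GAP_FLOOR = 0.01


def panel_to_frame(data: PanelDataset) -> pd.DataFrame:
    rows = []
    for s in data.subjects:
        for k, (t, y) in enumerate(s.visits, start=1):
            row = {"subject_id": s.subject_id, "visit": k, "t_gap": t, "y": y}
            row.update({f"x{j + 1}": s.x[j] for j in range(data.p)})
            rows.append(row)
    return pd.DataFrame(rows)


def write_panel_csv(data: PanelDataset, path) -> None:
    panel_to_frame(data).to_csv(path, index=False)


def read_panel_csv(path) -> PanelDataset:
    """Load and validate a long-format panel CSV.

    Rows are grouped by subject and ordered by visit index.  Non-positive
    gap times, non-binary outcomes and missing columns raise errors naming
    the offending row (1-based data row, header excluded).
    """
    frame = pd.read_csv(path)
    required = {"subject_id", "visit", "t_gap", "y"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"panel file {path} is missing columns: {sorted(missing)}")
    xcols = sorted(
        (c for c in frame.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not xcols:
        raise ValueError(f"panel file {path} has no covariate columns x1..xp")
    for idx, row in frame.iterrows():
        rowno = idx + 1
        if not row["t_gap"] > 0:
            raise ValueError(f"row {rowno}: gap time must be > 0, got {row['t_gap']}")
        if row["y"] not in (0, 1):
            raise ValueError(f"row {rowno}: outcome must be 0/1, got {row['y']}")
    subjects = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("visit")
        x = grp.iloc[0][xcols].to_numpy(dtype=float)
        visits = list(zip(grp["t_gap"].tolist(), grp["y"].astype(int).tolist()))
        subjects.append(SubjectRecord(subject_id=sid, x=x, visits=visits))
    return PanelDataset(subjects)


def read_recurrence_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"id", "rx", "number", "size", "stop", "enum", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"recurrence file {path} is missing columns: {sorted(missing)}")
    return frame


def bladder_to_panel(table: pd.DataFrame) -> PanelDataset:
    """Convert a recurrence table to a panel dataset.

    Per subject: visits ordered by ``enum``; y = event, t = stop (zero gaps
    floored to ZERO_GAP_FLOOR with a warning); covariates
    x = (1, rx, number, size), so p = 4.  More than four recurrences per
    subject, or duplicate (id, enum) pairs, are rejected.
    """
    required = {"id", "rx", "number", "size", "stop", "enum", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"recurrence table is missing columns: {sorted(missing)}")
    if not table["enum"].isin([1, 2, 3, 4]).all():
        bad = table.loc[~table["enum"].isin([1, 2, 3, 4]), "enum"].unique()
        raise ValueError(f"enum must be in 1..4; found {bad.tolist()}")
    if table.duplicated(subset=["id", "enum"]).any():
        dup = table[table.duplicated(subset=["id", "enum"], keep=False)]["id"].unique()
        raise ValueError(f"duplicate (id, enum) rows for ids {dup.tolist()}")
    n_floored = int((table["stop"] <= 0).sum())
    if n_floored:
        warnings.warn(
            f"{n_floored} rows with stop <= 0 floored to {ZERO_GAP_FLOOR}",
            UserWarning,
            stacklevel=2,
        )
    subjects = []
    for sid, grp in table.groupby("id", sort=True):
        grp = grp.sort_values("enum")
        first = grp.iloc[0]
        x = np.array([1.0, float(first["rx"]), float(first["number"]), float(first["size"])])
        visits = [
            (max(float(r["stop"]), ZERO_GAP_FLOOR), int(r["event"])) for _, r in grp.iterrows()
        ]
        subjects.append(SubjectRecord(subject_id=sid, x=x, visits=visits))
    return PanelDataset(subjects)
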