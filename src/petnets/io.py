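"""CSV readers/writers in the tabular layout used for graph construction.

Both orientations share the same dialect: comma-separated, UTF-8, a header
row of column labels and a first column of subject identifiers.  Dynamic
tables have time points (seconds) as columns; static tables have region
names as columns.  Group labels travel in an optional JSON sidecar mapping
subject id -> group, or may be passed as a dict.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import RegionSUVTable, TACMatrix, TableFormatError

__all__ = [
    "read_tac_csv",
    "read_suv_csv",
    "write_tac_csv",
    "write_suv_csv",
    "read_groups_json",
    "write_groups_json",
]


def _read_table(path) -> tuple[list[str], list[str], np.ndarray]:
    """Parse header, row ids and a dense float matrix; errors name the cell."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise TableFormatError(f"{path}: needs a header row and at least one data row")
    header = rows[0]
    ncol = len(header)
    ids, data = [], []
    for rno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise TableFormatError(
                f"{path}: row {rno} has {len(row)} fields, expected {ncol}"
            )
        ids.append(row[0])
        parsed = []
        for cno, cell in enumerate(row[1:], start=2):
            if cell.strip() == "":
                raise TableFormatError(
                    f"{path}: missing value at row {rno}, column {cno} "
                    f"({header[cno - 1]!r})"
                )
            try:
                parsed.append(float(cell))
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric value {cell!r} at row {rno}, "
                    f"column {cno} ({header[cno - 1]!r})"
                ) from None
        data.append(parsed)
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise TableFormatError(f"{path}: duplicate subject ids {dupes}")
    return header[1:], ids, np.asarray(data, dtype=float)


def _resolve_groups(subject_ids, groups) -> list[str]:
    if groups is None:
        return ["unknown"] * len(subject_ids)
    if isinstance(groups, (str, Path)):
        groups = read_groups_json(groups)
    missing = [s for s in subject_ids if s not in groups]
    if missing:
        raise TableFormatError(f"group labels missing for subjects {missing}")
    return [groups[s] for s in subject_ids]


def read_tac_csv(
    path,
    region_label: str,
    groups: Mapping[str, str] | str | Path | None = None,
) -> TACMatrix:
    """Read a subjects x time-points CSV (column labels = seconds)."""
    cols, ids, values = _read_table(path)
    try:
        grid = np.array([float(c) for c in cols])
    except ValueError:
        raise TableFormatError(
            f"{path}: time-point column labels must be numeric seconds"
        ) from None
    return TACMatrix(
        region_label=region_label,
        subject_ids=ids,
        group_labels=_resolve_groups(ids, groups),
        time_grid=grid,
        values=values,
    )


def read_suv_csv(
    path,
    groups: Mapping[str, str] | str | Path | None = None,
) -> RegionSUVTable:
    """Read a subjects x regions CSV of static SUV values."""
    cols, ids, values = _read_table(path)
    return RegionSUVTable(
        subject_ids=ids,
        group_labels=_resolve_groups(ids, groups),
        region_labels=cols,
        values=values,
    )


def _write_table(path, col_labels: Sequence[str], row_ids: Sequence[str], values):
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", *col_labels])
        for sid, row in zip(row_ids, np.asarray(values)):
            w.writerow([sid, *(repr(float(x)) for x in row)])


def write_tac_csv(tac: TACMatrix, path) -> None:
    _write_table(path, [repr(float(t)) for t in tac.time_grid], tac.subject_ids, tac.values)


def write_suv_csv(table: RegionSUVTable, path) -> None:
    _write_table(path, table.region_labels, table.subject_ids, table.values)


def read_groups_json(path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)


def write_groups_json(groups: Mapping[str, str], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(dict(groups), fh, indent=1, sort_keys=True)
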