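"""Core data containers for whole-body PET network analysis.

Dynamic data live in :class:`TACMatrix` objects (one region, subjects x time
grid of SUV values); static data live in :class:`RegionSUVTable` objects
(subjects x regions).  Both carry subject identifiers and group labels so the
downstream network pipelines can colour nodes and run group diagnostics.

All SUV values are dimensionless (activity normalised to injected dose and
body weight); all times are seconds post-injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TableFormatError",
    "InterpolationSpec",
    "TACMatrix",
    "RegionSUVTable",
    "DEFAULT_GRID",
    "interpolate_tac",
    "static_suv",
    "combine_regions",
]


class TableFormatError(ValueError):
    """Raised when a tabular input violates the expected layout."""


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-d matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative SUV values")
    return arr


def _check_subjects(subject_ids: Sequence[str], group_labels: Sequence[str], n_rows: int):
    if len(subject_ids) != n_rows:
        raise ValueError(
            f"{len(subject_ids)} subject ids for {n_rows} data rows"
        )
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if list(subject_ids).count(s) > 1})
        raise TableFormatError(f"duplicate subject ids: {dupes}")
    if len(group_labels) != len(subject_ids):
        raise ValueError("group_labels must align with subject_ids")
    if len(set(group_labels)) > 2:
        raise ValueError(
            f"more than two group labels present: {sorted(set(group_labels))}"
        )


@dataclass(frozen=True)
class InterpolationSpec:
    """Uniform resampling grid for TAC standardisation.

    The default reproduces the standard grid used throughout the package:
    240 equally spaced samples from 14 s to 2416 s post-injection
    (about 40 minutes, one sample every ~10 s).
    """

    t_start: float = 14.0
    t_end: float = 2416.0
    n_points: int = 240

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)


DEFAULT_GRID = InterpolationSpec()


@dataclass(frozen=True)
class TACMatrix:
    """Time-activity curves of one region for a cohort of subjects."""

    region_label: str
    subject_ids: tuple
    group_labels: tuple
    time_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be 1-d and strictly increasing")
        vals = _as_float_matrix(self.values, "values")
        if vals.shape[1] != grid.size:
            raise ValueError(
                f"values has {vals.shape[1]} columns but grid has {grid.size} points"
            )
        _check_subjects(self.subject_ids, self.group_labels, vals.shape[0])
        object.__setattr__(self, "time_grid", grid)
        object.__setattr__(self, "values", vals)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subject_groups(self) -> dict:
        return dict(zip(self.subject_ids, self.group_labels))


@dataclass(frozen=True)
class RegionSUVTable:
    """Static SUV fingerprints: one row per subject, one column per region."""

    subject_ids: tuple
    group_labels: tuple
    region_labels: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region_labels must be unique")
        vals = _as_float_matrix(self.values, "values")
        if vals.shape[1] != len(self.region_labels):
            raise ValueError(
                f"values has {vals.shape[1]} columns for "
                f"{len(self.region_labels)} regions"
            )
        _check_subjects(self.subject_ids, self.group_labels, vals.shape[0])
        object.__setattr__(self, "values", vals)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def exclude_regions(self, names: Sequence[str]) -> "RegionSUVTable":
        """Drop named region columns; unknown names raise."""
        names = list(names)
        unknown = [n for n in names if n not in self.region_labels]
        if unknown:
            raise KeyError(f"regions not in table: {unknown}")
        keep = [i for i, r in enumerate(self.region_labels) if r not in names]
        return replace(
            self,
            region_labels=tuple(self.region_labels[i] for i in keep),
            values=self.values[:, keep],
        )

    def select_group(self, group: str) -> "RegionSUVTable":
        idx = [i for i, g in enumerate(self.group_labels) if g == group]
        if not idx:
            raise ValueError(f"no subjects in group {group!r}")
        return replace(
            self,
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            group_labels=tuple(self.group_labels[i] for i in idx),
            values=self.values[idx],
        )

    def subject_groups(self) -> dict:
        return dict(zip(self.subject_ids, self.group_labels))


def interpolate_tac(
    raw_times: Sequence[float],
    raw_values: Sequence[float],
    spec: InterpolationSpec = DEFAULT_GRID,
) -> np.ndarray:
    """Resample one TAC onto the uniform grid by piecewise-linear interpolation.

    Linear interpolation is used so the resampled curve passes exactly through
    the measured frames; no extrapolation is performed — the raw samples must
    cover the full target span.
    """
    t = np.asarray(raw_times, dtype=float)
    v = np.asarray(raw_values, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("raw_times must contain at least two samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("raw_times must be strictly increasing")
    if t.size != v.size:
        raise ValueError("raw_times and raw_values length mismatch")
    if t[0] > spec.t_start or t[-1] < spec.t_end:
        raise ValueError(
            f"raw samples cover [{t[0]:g}, {t[-1]:g}] s but the grid requires "
            f"[{spec.t_start:g}, {spec.t_end:g}] s; extrapolation is not performed"
        )
    return np.interp(spec.grid, t, v)


def static_suv(
    tac: Sequence[float],
    spec: InterpolationSpec = DEFAULT_GRID,
    window_s: float = 600.0,
) -> float:
    """Mean uptake over the trailing window of a grid-sampled TAC.

    The default 600 s window is the "last ten minutes" equilibrium average;
    samples with time >= t_end - window_s are included.
    """
    if window_s > spec.t_end - spec.t_start:
        raise ValueError("window_s exceeds the grid span")
    y = np.asarray(tac, dtype=float)
    if y.size != spec.n_points:
        raise ValueError("tac length does not match the interpolation grid")
    mask = spec.grid >= spec.t_end - window_s
    if not mask.any():
        raise ValueError("averaging window contains no grid samples")
    return float(y[mask].mean())


def combine_regions(tacs: Sequence[TACMatrix], method: str = "mean") -> TACMatrix:
    """Merge regions (e.g. aorta + ventricle into a blood pool) element-wise.

    Only the unweighted mean is supported; inputs must share subject order
    and time grid exactly.
    """
    if method != "mean":
        raise ValueError(f"unsupported combination method {method!r}")
    tacs = list(tacs)
    if not tacs:
        raise ValueError("no TACMatrix inputs")
    first = tacs[0]
    for t in tacs[1:]:
        if t.subject_ids != first.subject_ids or t.group_labels != first.group_labels:
            raise ValueError("subject sets/orders differ between regions")
        if t.time_grid.shape != first.time_grid.shape or not np.array_equal(
            t.time_grid, first.time_grid
        ):
            raise ValueError("time grids differ between regions")
    stacked = np.mean([t.values for t in tacs], axis=0)
    label = " + ".join(t.region_label for t in tacs)
    return TACMatrix(
        region_label=label,
        subject_ids=first.subject_ids,
        group_labels=first.group_labels,
        time_grid=first.time_grid,
        values=stacked,
    )
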