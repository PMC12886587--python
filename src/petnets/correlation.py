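"""Pairwise correlation measures and their nominal significance.

Edges in every network carry a Pearson (or Spearman) coefficient; two-sided
p-values come from the classical t transform t = r*sqrt((m-2)/(1-r^2)) with
m-2 degrees of freedom.  For TAC correlations m is the number of interpolated
samples, which are autocorrelated — those p-values are nominal screening
values, not effective ones, and the r threshold dominates in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationResult",
    "pearson",
    "spearman",
    "corr_pvalue",
    "pairwise_matrix",
]


class UndefinedCorrelationError(ValueError):
    """A correlation was requested for a zero-variance vector."""


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _validate_pair(x, y)
    xd = x - x.mean()
    yd = y - y.mean()
    r = float(xd @ yd / np.sqrt((xd @ xd) * (yd @ yd)))
    return min(1.0, max(-1.0, r))


def spearman(x, y) -> float:
    """Pearson correlation of mean ranks (ties share the mean rank)."""
    x, y = _validate_pair(x, y)
    return pearson(stats.rankdata(x), stats.rankdata(y))


def corr_pvalue(r: float, m: int) -> float:
    """Two-sided p-value of a correlation from m paired observations."""
    if m < 3:
        raise ValueError("p-value requires at least 3 observations")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((m - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=m - 2))


@dataclass(frozen=True)
class CorrelationResult:
    """All pairwise correlations over a set of entities.

    Entities are subjects (inter-subject networks) or regions (ΔPCC method);
    observations are the columns of the data matrix handed to
    :func:`pairwise_matrix`.
    """

    entity_ids: tuple
    r_matrix: np.ndarray
    p_matrix: np.ndarray
    method: str
    m: int

    def __post_init__(self):
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))
        r = np.asarray(self.r_matrix, dtype=float)
        p = np.asarray(self.p_matrix, dtype=float)
        n = len(self.entity_ids)
        if r.shape != (n, n) or p.shape != (n, n):
            raise ValueError("matrix shapes must match entity count")
        if not np.allclose(r, r.T) or not np.allclose(p, p.T):
            raise ValueError("correlation/p matrices must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-12) or np.any((p < 0) | (p > 1)):
            raise ValueError("r outside [-1,1] or p outside [0,1]")
        object.__setattr__(self, "r_matrix", r)
        object.__setattr__(self, "p_matrix", p)

    def pair(self, a, b) -> tuple[float, float]:
        i = self.entity_ids.index(a)
        j = self.entity_ids.index(b)
        return float(self.r_matrix[i, j]), float(self.p_matrix[i, j])


def pairwise_matrix(data, entity_ids=None, method: str = "pearson") -> CorrelationResult:
    """Correlate every pair of rows of an entities x observations matrix."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("data must be 2-d with at least 2 entities")
    n, m = X.shape
    if m < 3:
        raise ValueError("need at least 3 observations per entity")
    if entity_ids is None:
        entity_ids = tuple(range(n))
    if len(entity_ids) != n:
        raise ValueError("entity_ids must match the number of rows")
    flat = np.ptp(X, axis=1) == 0
    if flat.any():
        bad = [entity_ids[i] for i in np.where(flat)[0]]
        raise UndefinedCorrelationError(f"zero-variance entities: {bad}")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    R = np.corrcoef(X)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(R) * np.sqrt((m - 2) / (1.0 - R * R))
    P = 2.0 * stats.t.sf(t, df=m - 2)
    P[np.abs(R) >= 1.0] = 0.0
    np.fill_diagonal(P, 0.0)
    P = (P + P.T) / 2.0  # enforce exact symmetry against fp noise
    return CorrelationResult(
        entity_ids=entity_ids, r_matrix=R, p_matrix=P, method=method, m=m
    )
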