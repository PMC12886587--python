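"""Intersubject network pipelines: dynamic d-networks and static s-networks.

A d-network correlates subjects' full time-activity curves within one region;
an s-network correlates subjects' static regional-SUV fingerprints.  Both
apply the same machinery: pairwise Pearson correlation, a joint (r, p)
threshold, and k-nearest-neighbour edge reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core import RegionSUVTable, TACMatrix
from .correlation import pairwise_matrix
from .graphs import build_network, group_mixing, knn_reduce

__all__ = [
    "PipelineConfig",
    "build_dnetwork",
    "build_snetwork",
    "region_mean_comparison",
    "RegionMeansResult",
    "permutation_group_test",
    "PermutationResult",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for the intersubject pipelines.

    Defaults are the operating point used throughout: edges need r > 0.65,
    with p < 0.001 for dynamic networks and p < 0.05 for static networks,
    then k = 3 nearest-neighbour edge reduction.
    """

    r_min: float = 0.65
    alpha_dnet: float = 0.001
    alpha_snet: float = 0.05
    k: int = 3
    excluded_regions: tuple = ()
    method: str = "pearson"
    knn_semantics: str = "union"

    def __post_init__(self):
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min outside [-1, 1]")
        for a in (self.alpha_dnet, self.alpha_snet):
            if not 0 < a <= 1:
                raise ValueError("alpha outside (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        object.__setattr__(self, "excluded_regions", tuple(self.excluded_regions))


def build_dnetwork(tac: TACMatrix, config: PipelineConfig = PipelineConfig()) -> nx.Graph:
    """Subject-versus-subject network from one region's dynamic curves."""
    if tac.n_subjects < 3:
        raise ValueError("a d-network needs at least 3 subjects")
    corr = pairwise_matrix(tac.values, tac.subject_ids, method=config.method)
    g = build_network(corr, config.r_min, config.alpha_dnet, tac.subject_groups())
    g = knn_reduce(g, config.k, config.knn_semantics)
    g.graph["region"] = tac.region_label
    return g


def build_snetwork(
    table: RegionSUVTable, config: PipelineConfig = PipelineConfig()
) -> nx.Graph:
    """Subject-versus-subject network from static regional fingerprints."""
    if config.excluded_regions:
        table = table.exclude_regions(config.excluded_regions)
    if len(table.region_labels) < 3:
        raise ValueError(
            f"only {len(table.region_labels)} regions remain after exclusion; "
            "need at least 3"
        )
    if table.n_subjects < 3:
        raise ValueError("an s-network needs at least 3 subjects")
    corr = pairwise_matrix(table.values, table.subject_ids, method=config.method)
    g = build_network(corr, config.r_min, config.alpha_snet, table.subject_groups())
    g = knn_reduce(g, config.k, config.knn_semantics)
    g.graph["regions"] = list(table.region_labels)
    return g


@dataclass(frozen=True)
class RegionMeansResult:
    region_labels: tuple
    means: np.ndarray
    sds: np.ndarray
    f_statistic: float
    p_value: float


def region_mean_comparison(table: RegionSUVTable) -> RegionMeansResult:
    """Per-region mean ± SD and a one-way ANOVA across regions.

    Regions act as groups and subjects' static SUVs as observations, testing
    whether any region's mean uptake differs from the rest.
    """
    if len(table.region_labels) < 2 or table.n_subjects < 2:
        raise ValueError("ANOVA needs at least 2 regions and 2 subjects")
    cols = [table.values[:, j] for j in range(len(table.region_labels))]
    f, p = stats.f_oneway(*cols)
    if np.isnan(f):  # all observations identical across every region
        f, p = 0.0, 1.0
    return RegionMeansResult(
        region_labels=table.region_labels,
        means=table.values.mean(axis=0),
        sds=table.values.std(axis=0, ddof=1),
        f_statistic=float(f),
        p_value=float(p),
    )


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_quantile_05: float
    null_quantiles: tuple
    p_value: float
    n_permutations: int


def permutation_group_test(
    g: nx.Graph, n_permutations: int = 1000, seed: int | None = None
) -> PermutationResult:
    """Label-permutation null for the between-group edge fraction.

    Node group labels are shuffled while the edge set is held fixed; the
    one-sided p-value asks whether the observed between-group fraction is
    unusually small (i.e. the groups segregate).
    """
    rng = np.random.default_rng(seed)
    groups = {n: d.get("group") for n, d in g.nodes(data=True)}
    if any(v is None for v in groups.values()):
        raise ValueError("every node needs a group attribute")
    nodes = list(g.nodes)
    labels = np.array([groups[n] for n in nodes])
    edges = [(nodes.index(u), nodes.index(v)) for u, v in g.edges]
    if not edges:
        raise ValueError("graph has no edges")
    eu = np.array([e[0] for e in edges])
    ev = np.array([e[1] for e in edges])
    observed = float(np.mean(labels[eu] != labels[ev]))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        null[i] = np.mean(perm[eu] != perm[ev])
    p = float((np.sum(null <= observed) + 1) / (n_permutations + 1))
    return PermutationResult(
        observed=observed,
        null_quantile_05=float(np.quantile(null, 0.05)),
        null_quantiles=tuple(np.quantile(null, [0.025, 0.5, 0.975])),
        p_value=p,
        n_permutations=n_permutations,
    )
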