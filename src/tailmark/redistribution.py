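"""Cross-stage dynamics of gene-body histone-mark signal.

Given per-stage profile matrices over the same transcripts (developmental
order, e.g. ES -> NP -> WB), a candidate gene set's profiles are concatenated
stage-wise and clustered (correlation-distance hierarchical clustering, cut
at k=3). Each group then gets a semantic label from its per-stage tail
scores s_1..s_S (computed on the group's mean profile) against a threshold
tau (default 2.0):

- ``constant``     every stage scores >= tau (gene-body mark throughout),
- ``late_only``    only the final stage scores >= tau,
- ``progressive``  the first stage is below tau, every later stage is >= tau
                   with non-decreasing scores (mark acquired mid-development
                   and strengthened),
- ``other``        anything else.

Labels are derived from the scores only, never hand-assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import (
    ClusterResult,
    HierarchicalResult,
    TailScoreConfig,
    cut_tree,
    hierarchical_cluster,
    tail_score,
)
from .coverage import ProfileMatrix

__all__ = [
    "StageSet",
    "RedistributionResult",
    "combine_stage_profiles",
    "classify_groups",
    "overlap_table",
    "SEMANTIC_LABELS",
]

logger = logging.getLogger(__name__)

SEMANTIC_LABELS = ("constant", "late_only", "progressive", "other")


@dataclass
class StageSet:
    """Ordered developmental stages, one profile matrix per stage."""

    labels: list[str]
    matrices: dict[str, ProfileMatrix]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("need at least one stage")
        missing = [s for s in self.labels if s not in self.matrices]
        if missing:
            raise ValueError(f"no matrix for stages {missing}")
        first = self.matrices[self.labels[0]]
        for s in self.labels[1:]:
            m = self.matrices[s]
            if m.n_bins != first.n_bins or set(m.row_ids) != set(first.row_ids):
                raise ValueError(
                    f"stage {s!r} does not share the row universe / bin count "
                    "of the first stage"
                )

    @property
    def n_stages(self) -> int:
        return len(self.labels)

    def __getitem__(self, stage: str) -> ProfileMatrix:
        return self.matrices[stage]


def combine_stage_profiles(
    stages: StageSet, genes: Sequence[str]
) -> np.ndarray:
    """Horizontally concatenate each gene's per-stage profiles in stage order.

    Result is genes x (n_stages * n_bins); matrices should be depth-normalized
    (rpm) upstream when libraries differ.
    """
    genes = list(genes)
    missing = [
        g for g in genes if g not in set(stages[stages.labels[0]].row_ids)
    ]
    if missing:
        raise KeyError(f"genes missing from stage matrices: {missing[:10]}")
    blocks = [stages[s].subset(genes).counts for s in stages.labels]
    return np.hstack(blocks)


@dataclass
class RedistributionResult:
    """Per-gene cross-stage group with per-group per-stage tail scores."""

    genes: list[str]
    group_labels: np.ndarray                 # gene -> group index (0..k-1)
    stage_labels: list[str]
    group_tail_scores: np.ndarray            # k x n_stages (on group mean profiles)
    semantic_labels: list[str]               # per group
    tau: float
    tree: HierarchicalResult | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.group_tail_scores.shape[0]

    def group_members(self, group: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.group_labels) if l == group]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, grp in zip(self.genes, self.group_labels):
            rows.append(
                [g, int(grp), self.semantic_labels[grp]]
                + [float(s) for s in self.group_tail_scores[grp]]
            )
        cols = ["gene", "group", "label"] + [f"s_{s}" for s in self.stage_labels]
        return pd.DataFrame(rows, columns=cols)


def _semantic_label(scores: np.ndarray, tau: float) -> str:
    above = scores >= tau
    if above.all():
        return "constant"
    if above[-1] and not above[:-1].any():
        return "late_only"
    if (
        len(scores) >= 2
        and not above[0]
        and above[1:].all()
        and np.all(np.diff(scores[1:]) >= 0)
    ):
        return "progressive"
    return "other"


def classify_groups(
    stages: StageSet,
    genes: Sequence[str],
    tail_cfg: TailScoreConfig = TailScoreConfig(),
    tau: float = 2.0,
    k: int = 3,
    linkage: str = "average",
    combined: np.ndarray | None = None,
) -> RedistributionResult:
    """Cluster combined cross-stage profiles and label the dynamics.

    ``combined`` may be supplied to avoid recomputation; it must equal
    :func:`combine_stage_profiles` output for the same genes/stages.
    """
    genes = list(genes)
    if len(genes) < max(3, k):
        raise ValueError(f"need at least {max(3, k)} genes")
    if combined is None:
        combined = combine_stage_profiles(stages, genes)
    tree = hierarchical_cluster(combined, linkage=linkage)
    tree.row_ids = genes
    labels = cut_tree(tree, k)

    geometry = stages[stages.labels[0]].geometry
    scores = np.zeros((k, stages.n_stages))
    for grp in range(k):
        members = [g for g, l in zip(genes, labels) if l == grp]
        for j, s in enumerate(stages.labels):
            mean = stages[s].mean_profile(members)
            scores[grp, j] = tail_score(mean, geometry, tail_cfg)
    semantic = [_semantic_label(scores[grp], tau) for grp in range(k)]

    flags = []
    if len(set(semantic)) < k:
        flags.append("degenerate: multiple groups share one semantic label")
        logger.warning("classify_groups: %s", flags[-1])
    return RedistributionResult(
        genes, labels, list(stages.labels), scores, semantic, tau, tree, flags
    )


def overlap_table(
    geneset: Iterable[str], cluster_result: ClusterResult
) -> pd.DataFrame:
    """Per-cluster overlap counts and fractions for a gene list.

    Genes outside the clustering universe are reported (logged), not fatal.
    Counts sum to |geneset ∩ universe|.
    """
    geneset = set(geneset)
    if not geneset:
        raise ValueError("empty geneset")
    if cluster_result.row_ids is None:
        raise ValueError("cluster result carries no row ids")
    universe = set(cluster_result.row_ids)
    outside = geneset - universe
    if outside:
        logger.warning(
            "%d of %d genes are outside the cluster universe", len(outside), len(geneset)
        )
    inside = geneset & universe
    rows = []
    for c in range(cluster_result.k):
        members = set(cluster_result.members(c))
        k = len(inside & members)
        rows.append(
            (
                c,
                len(members),
                k,
                k / len(inside) if inside else 0.0,
                k / len(members) if members else 0.0,
            )
        )
    return pd.DataFrame(
        rows, columns=["cluster", "cluster_size", "overlap",
                       "frac_of_geneset", "frac_of_cluster"]
    )
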