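"""Model/Results interfaces over the two headline analyses.

`TailDiscovery` wraps the two-stage K-means search for gene-body-marked
("tail") genes in one stage's profile matrix; `StageRedistribution` wraps the
cross-stage grouping of a candidate gene set. Both follow the familiar
model-object idiom: construct from data, call ``fit()``, read estimates and
diagnostics off the returned results object, print ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import (
    ClusterResult,
    KMeansConfig,
    PCAResult,
    TailScoreConfig,
    pca,
    select_tail_cluster,
    tail_score,
    two_stage_tail_discovery,
)
from .coverage import ProfileMatrix
from .redistribution import (
    RedistributionResult,
    StageSet,
    classify_groups,
    combine_stage_profiles,
)

__all__ = [
    "TailDiscovery",
    "TailDiscoveryResults",
    "StageRedistribution",
    "RedistributionResults",
]


class TailDiscovery:
    """Two-stage K-means discovery of gene-body-marked genes.

    Parameters
    ----------
    matrix
        Profile matrix of one stage (typically the most differentiated one).
    stage1, stage2
        K-means configurations for the coarse (default k=7) and refinement
        (default k=4) passes, 50 restarts each.
    tail
        Gene-body / upstream-flank windows for the tail score used to pick
        the tail cluster at each stage.
    """

    def __init__(
        self,
        matrix: ProfileMatrix,
        stage1: KMeansConfig = KMeansConfig(k=7, repeats=50),
        stage2: KMeansConfig = KMeansConfig(k=4, repeats=50),
        tail: TailScoreConfig = TailScoreConfig(),
    ):
        self.matrix = matrix
        self.stage1_cfg = stage1
        self.stage2_cfg = stage2
        self.tail_cfg = tail

    def fit(self, seed: int | None = None) -> "TailDiscoveryResults":
        candidates, s1, s2 = two_stage_tail_discovery(
            self.matrix, self.stage1_cfg, self.stage2_cfg, self.tail_cfg, seed=seed
        )
        geom = self.matrix.geometry
        sel1, scores1 = select_tail_cluster(s1, geom, self.tail_cfg)
        sel2, scores2 = select_tail_cluster(s2, geom, self.tail_cfg)
        return TailDiscoveryResults(
            model=self,
            candidate_ids=candidates,
            stage1=s1,
            stage2=s2,
            stage1_scores=scores1,
            stage2_scores=scores2,
            selected=(sel1, sel2),
            seed=seed,
        )


@dataclass
class TailDiscoveryResults:
    model: TailDiscovery
    candidate_ids: list[str]
    stage1: ClusterResult
    stage2: ClusterResult
    stage1_scores: np.ndarray
    stage2_scores: np.ndarray
    selected: tuple[int, int]
    seed: int | None

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_ids)

    def recovery(self, truth_ids: Sequence[str]) -> tuple[float, float]:
        """(precision, recall) of the candidate set against a planted truth."""
        truth = set(truth_ids)
        found = set(self.candidate_ids)
        if not found or not truth:
            return 0.0, 0.0
        tp = len(found & truth)
        return tp / len(found), tp / len(truth)

    def summary(self) -> str:
        lines = [
            "Two-stage tail discovery",
            "========================",
            f"stage label        : {self.model.matrix.stage_label or '-'}",
            f"rows x bins        : {self.model.matrix.counts.shape[0]} x "
            f"{self.model.matrix.n_bins}",
            f"seed               : {self.seed}",
            "",
            "stage 1 (k=%d): cluster sizes / tail scores" % self.stage1.k,
        ]
        for c in range(self.stage1.k):
            mark = " <- selected" if c == self.selected[0] else ""
            lines.append(
                f"  cluster {c}: n={int(self.stage1.sizes[c]):5d}  "
                f"score={self.stage1_scores[c]:8.3f}{mark}"
            )
        lines.append("stage 2 (k=%d): cluster sizes / tail scores" % self.stage2.k)
        for c in range(self.stage2.k):
            mark = " <- selected" if c == self.selected[1] else ""
            lines.append(
                f"  cluster {c}: n={int(self.stage2.sizes[c]):5d}  "
                f"score={self.stage2_scores[c]:8.3f}{mark}"
            )
        lines += ["", f"candidate gene-body-marked genes: {self.n_candidates}"]
        return "\n".join(lines)


class StageRedistribution:
    """Cross-stage grouping of a gene set's combined profiles.

    Hierarchical clustering (1 - Pearson distance, default average linkage)
    of the stage-concatenated profiles, cut at ``k`` (default 3) groups; each
    group is labeled constant / late_only / progressive / other from its
    per-stage tail scores against the threshold ``tau``.
    """

    def __init__(
        self,
        stages: StageSet,
        genes: Sequence[str],
        tail: TailScoreConfig = TailScoreConfig(),
        tau: float = 2.0,
        k: int = 3,
        linkage: str = "average",
        n_components: int = 2,
    ):
        self.stages = stages
        self.genes = list(genes)
        self.tail_cfg = tail
        self.tau = tau
        self.k = k
        self.linkage = linkage
        self.n_components = n_components

    def fit(self) -> "RedistributionResults":
        combined = combine_stage_profiles(self.stages, self.genes)
        result = classify_groups(
            self.stages, self.genes, self.tail_cfg, self.tau,
            k=self.k, linkage=self.linkage, combined=combined,
        )
        pcs = pca(combined, min(self.n_components, *combined.shape))
        sil = _silhouette(combined, result.group_labels)
        return RedistributionResults(self, result, combined, pcs, sil)


def _silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels.tolist())) < 2:
        return float("nan")
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(X, labels, metric="correlation"))


@dataclass
class RedistributionResults:
    model: StageRedistribution
    classification: RedistributionResult
    combined: np.ndarray
    pca: PCAResult
    silhouette: float
    extras: dict = field(default_factory=dict)

    @property
    def group_labels(self) -> np.ndarray:
        return self.classification.group_labels

    @property
    def semantic_labels(self) -> list[str]:
        return self.classification.semantic_labels

    def summary(self) -> str:
        c = self.classification
        lines = [
            "Cross-stage redistribution",
            "==========================",
            f"genes              : {len(c.genes)}",
            f"stages             : {' -> '.join(c.stage_labels)}",
            f"groups (k)         : {c.k}   tau = {c.tau}",
            f"PCA evr            : "
            + ", ".join(f"{v:.3f}" for v in self.pca.explained_variance_ratio),
            f"silhouette (corr)  : {self.silhouette:.3f}",
            "",
            "group  n      label         " + "  ".join(
                f"s_{s:<6s}" for s in c.stage_labels
            ),
        ]
        for g in range(c.k):
            n = int((c.group_labels == g).sum())
            scores = "  ".join(f"{v:8.2f}" for v in c.group_tail_scores[g])
            lines.append(f"{g:>5d}  {n:<5d}  {c.semantic_labels[g]:<12s}  {scores}")
        for f in c.flags:
            lines.append(f"flag: {f}")
        return "\n".join(lines)
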