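"""End-to-end orchestration: per-stage matrices -> tail discovery on the
final stage -> cross-stage overlaps -> combined-profile grouping -> reports.

The run is a pure function of (input files, config, seed): all randomness is
derived from the config seed, and every TSV written is byte-stable across
reruns. The tail discovery is performed on the *last* (most differentiated)
stage and the candidate set is then traced backwards through the earlier
stages' clusterings, mirroring the discover-then-project design of gene-body
mark analyses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotations import load_annotations, load_chrom_sizes, make_windows
from .clustering import KMeansConfig, TailScoreConfig, kmeans, select_tail_cluster
from .coverage import CoverageConfig, ProfileMatrix, compute_profile_matrix
from .genesets import bh_adjust, hypergeom_overlap
from .models import RedistributionResults, StageRedistribution, TailDiscovery, TailDiscoveryResults
from .redistribution import StageSet, overlap_table

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "plot_profiles"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; the last stage is where tail discovery happens."""

    stage_reads: dict                  # ordered stage label -> BED path
    annotation: str
    chrom_sizes: str
    annotation_dialect: str = "refgene"
    flank: int = 10_000
    bin_size: int = 20
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    normalization: str = "rpm"         # used when combining stages
    kmeans_stage1: KMeansConfig = field(default_factory=lambda: KMeansConfig(k=7))
    kmeans_stage2: KMeansConfig = field(default_factory=lambda: KMeansConfig(k=4))
    tail: TailScoreConfig = field(default_factory=TailScoreConfig)
    cut_k: int = 3
    tau: float = 2.0
    out_dir: str = "tailmark_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stage_reads:
            raise ValueError("at least one stage is required")

    @property
    def stages(self) -> list[str]:
        return list(self.stage_reads)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("coverage", CoverageConfig),
            ("kmeans_stage1", KMeansConfig),
            ("kmeans_stage2", KMeansConfig),
            ("tail", TailScoreConfig),
        ):
            if key in raw and isinstance(raw[key], Mapping):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """All computed objects of one run plus where their TSVs went."""

    config: PipelineConfig
    matrices: dict
    discovery: TailDiscoveryResults
    overlaps: dict                      # stage -> DataFrame with p/q columns
    stage_clusterings: dict             # stage -> ClusterResult (k=7)
    redistribution: RedistributionResults | None
    output_files: dict = field(default_factory=dict)

    @property
    def candidate_ids(self) -> list[str]:
        return self.discovery.candidate_ids


def _stage_seed(base: int, offset: int) -> int:
    return (int(base) + offset) % (2**31 - 1)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    logger.info("loading annotation %s (%s)", cfg.annotation, cfg.annotation_dialect)
    genes = load_annotations(cfg.annotation, cfg.annotation_dialect)
    sizes = load_chrom_sizes(cfg.chrom_sizes)
    windows = make_windows(genes, sizes, cfg.flank, cfg.bin_size)

    matrices: dict[str, ProfileMatrix] = {}
    for stage, reads_path in cfg.stage_reads.items():
        logger.info(
            "stage %s: binning extended reads (+%d bp, %s rule, %d bp bins)",
            stage, cfg.coverage.extension, cfg.coverage.bin_rule, cfg.bin_size,
        )
        m = compute_profile_matrix(reads_path, windows, cfg.coverage, sizes, stage)
        if cfg.normalization == "rpm":
            m = m.to_rpm()
        matrices[stage] = m
        p = out / f"matrix_{stage}.tsv"
        m.to_tsv(p)
        files[f"matrix_{stage}"] = str(p)

    final = cfg.stages[-1]
    logger.info("tail discovery on final stage %s (k=%d then k=%d, %d restarts)",
                final, cfg.kmeans_stage1.k, cfg.kmeans_stage2.k,
                cfg.kmeans_stage1.repeats)
    discovery = TailDiscovery(
        matrices[final], cfg.kmeans_stage1, cfg.kmeans_stage2, cfg.tail
    ).fit(seed=_stage_seed(cfg.seed, 0))
    candidates = discovery.candidate_ids
    pd.DataFrame({"transcript_id": candidates}).to_csv(
        out / "candidate_genes.tsv", sep="\t", index=False
    )
    files["candidates"] = str(out / "candidate_genes.tsv")

    # project the candidate set onto every earlier stage's k=7 clustering
    overlaps: dict[str, pd.DataFrame] = {}
    stage_clusterings = {final: discovery.stage1}
    geometry = matrices[final].geometry
    for i, stage in enumerate(cfg.stages[:-1]):
        cfg1 = dataclasses.replace(
            cfg.kmeans_stage1, seed=_stage_seed(cfg.seed, 100 + i)
        )
        res = kmeans(matrices[stage], cfg1)
        stage_clusterings[stage] = res
        table = overlap_table(candidates, res)
        _, scores = select_tail_cluster(res, geometry, cfg.tail)
        table["tail_score"] = scores
        n_inside = int(table["overlap"].sum())
        tests = [
            hypergeom_overlap(
                len(res.row_ids), n_inside, int(r.cluster_size), int(r.overlap)
            )
            for r in table.itertuples(index=False)
        ]
        table["p"] = [t.p_value for t in tests]
        table["q"] = bh_adjust(table["p"].to_numpy())
        overlaps[stage] = table
        p = out / f"overlap_{stage}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        files[f"overlap_{stage}"] = str(p)
        asg = pd.DataFrame(
            {"transcript_id": res.row_ids, "stage": stage, "cluster": res.labels}
        )
        asg.to_csv(out / f"clusters_{stage}.tsv", sep="\t", index=False)
        files[f"clusters_{stage}"] = str(out / f"clusters_{stage}.tsv")

    # cross-stage redistribution of the candidate set
    redistribution = None
    if len(cfg.stages) >= 2:
        stageset = StageSet(cfg.stages, matrices)
        redistribution = StageRedistribution(
            stageset, candidates, cfg.tail, cfg.tau, cfg.cut_k
        ).fit()
        frame = redistribution.classification.to_frame()
        p = out / "redistribution.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        files["redistribution"] = str(p)
        scores = pd.DataFrame(
            redistribution.pca.scores,
            columns=[f"PC{i + 1}" for i in range(redistribution.pca.scores.shape[1])],
        )
        scores.insert(0, "gene", candidates)
        scores["group"] = redistribution.group_labels
        p = out / "pca_scores.tsv"
        scores.to_csv(p, sep="\t", index=False, float_format="%.6g")
        files["pca_scores"] = str(p)
    else:
        logger.info("single-stage run: redistribution step skipped")

    report = RunReport(
        cfg, matrices, discovery, overlaps, stage_clusterings, redistribution, files
    )
    _write_report_json(report, out / "run_report.json")
    files["report"] = str(out / "run_report.json")
    return report


def _write_report_json(report: RunReport, path: Path) -> None:
    cfg = report.config
    doc = {
        "config": _jsonable(cfg.to_dict()),
        "stages": cfg.stages,
        "n_candidates": report.discovery.n_candidates,
        "stage1_tail_scores": report.discovery.stage1_scores.tolist(),
        "stage2_tail_scores": report.discovery.stage2_scores.tolist(),
        "selected_clusters": list(report.discovery.selected),
        "overlap_totals": {
            s: int(t["overlap"].sum()) for s, t in report.overlaps.items()
        },
    }
    if report.redistribution is not None:
        c = report.redistribution.classification
        doc["groups"] = {
            "sizes": np.bincount(c.group_labels, minlength=c.k).tolist(),
            "semantic_labels": c.semantic_labels,
            "tail_scores": c.group_tail_scores.tolist(),
            "silhouette": report.redistribution.silhouette,
            "pca_explained_variance_ratio":
                report.redistribution.pca.explained_variance_ratio.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# plotting


def plot_profiles(
    matrix: ProfileMatrix,
    subsets: Mapping[str, Sequence[str]],
    path: str | Path,
    title: str = "",
) -> dict[str, np.ndarray]:
    """Mean-profile line plot (x = bp relative to TSS) for named gene subsets.

    Returns the plotted mean vectors keyed by subset name so callers can
    check them numerically.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not subsets:
        raise ValueError("no subsets to plot")
    x = matrix.bin_centers
    vectors: dict[str, np.ndarray] = {}
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, ids in subsets.items():
        v = matrix.mean_profile(list(ids))
        vectors[name] = v
        ax.plot(x, v, label=f"{name} (n={len(list(ids))})", lw=1.2)
    ax.axvline(0.0, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel(
        "mean reads/bin" if matrix.normalization == "raw" else "mean rpm/bin"
    )
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return vectors


def plot_combined_heatmap(
    combined: np.ndarray,
    group_labels: np.ndarray,
    stage_labels: Sequence[str],
    path: str | Path,
) -> None:
    """Row heatmap of the stage-concatenated matrix, rows ordered by group."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = np.argsort(group_labels, kind="stable")
    X = combined[order]
    fig, ax = plt.subplots(figsize=(8, 6))
    vmax = np.percentile(X, 99) or 1.0
    ax.imshow(X, aspect="auto", cmap="viridis", vmin=0, vmax=vmax,
              interpolation="nearest")
    n_bins = combined.shape[1] // len(stage_labels)
    for i, s in enumerate(stage_labels):
        if i:
            ax.axvline(i * n_bins - 0.5, color="w", lw=1.0)
        ax.text((i + 0.5) * n_bins, -2, s, ha="center", va="bottom", fontsize=9)
    ax.set_xlabel("stage-concatenated bins")
    ax.set_ylabel("genes (grouped)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
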