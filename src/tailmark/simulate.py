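"""Synthetic multi-stage ChIP-seq read sets with planted profile archetypes.

Every gene carries one of three per-stage profile archetypes for the fragment
(midpoint) density around its TSS, in transcript orientation:

``promoter_bimodal``
    two Gaussian peaks flanking the TSS (defaults -150 and +300 bp, sd 150),
    the generic active-promoter shape;
``body_tail``
    the same promoter pair plus an exponentially decaying gene-body component
    over 0..+8 kb downstream (mixture weight 0.6 tail) - the tissue-specific
    gene-body signature;
``silent``
    no gene-specific signal (background only).

A gene's *trajectory class* fixes its archetype at each developmental stage
(default stages ES -> NP -> WB):

===================  =========  ================  =========
class                stage 1    stage 2           stage 3
===================  =========  ================  =========
group1_constant      body_tail  body_tail         body_tail
group2_late          silent     silent            body_tail
group3_progressive   silent     body_tail (weak)  body_tail
nonspecific_promoter promoter   promoter          promoter
background           silent     silent            silent
===================  =========  ================  =========

Read counts per gene are Poisson; read 5' positions are placed so that the
*extended* fragment (read length + extension bp) is centered on a midpoint
drawn from the archetype density, so binned coverage of extended reads
reconstructs the density under either bin rule. Promoter-class genes draw a
per-gene intensity from a broad lognormal, emulating the wide dynamic range
of promoter marking in real chromatin data; uniform background reads cover
the whole genome. Everything is deterministic given the seed (per-stage
streams are derived from seed + stage index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotations import ChromSizes, GeneAnnotation
from .coverage import ProfileMatrix

__all__ = [
    "ArchetypeParams",
    "SimConfig",
    "SyntheticTruth",
    "simulate_truth",
    "simulate_reads",
    "write_reads_bed",
    "write_refgene",
    "expected_profile_matrix",
    "TRAJECTORY_CLASSES",
]

TRAJECTORY_CLASSES = (
    "group1_constant",
    "group2_late",
    "group3_progressive",
    "nonspecific_promoter",
    "background",
)

# trajectory class -> per-stage archetype (3 developmental stages)
_TRAJECTORY_ARCHETYPES = {
    "group1_constant": ("body_tail", "body_tail", "body_tail"),
    "group2_late": ("silent", "silent", "body_tail"),
    "group3_progressive": ("silent", "body_tail_weak", "body_tail"),
    "nonspecific_promoter": ("promoter_bimodal",) * 3,
    "background": ("silent",) * 3,
}


@dataclass(frozen=True)
class ArchetypeParams:
    """Shape parameters shared by the profile archetypes (bp, TSS-relative)."""

    peak_offsets: tuple[int, int] = (-150, 300)
    peak_sd: float = 150.0
    tail_from: int = 0
    tail_to: int = 8_000
    tail_decay: float = 1.0 / 6_000  # exponential rate per bp
    tail_weight: float = 0.6         # body_tail mixture weight of the tail
    weak_intensity: float = 0.5      # body_tail_weak depth multiplier

    def __post_init__(self) -> None:
        if not 0 < self.tail_weight < 1:
            raise ValueError("tail_weight must be in (0, 1)")
        if self.tail_to <= self.tail_from:
            raise ValueError("empty tail span")

    # -- midpoint density CDF in transcript-relative coordinates -------------

    def _tail_cdf(self, x: np.ndarray) -> np.ndarray:
        span = self.tail_to - self.tail_from
        z = np.clip(x - self.tail_from, 0, span)
        denom = 1.0 - np.exp(-self.tail_decay * span)
        return (1.0 - np.exp(-self.tail_decay * z)) / denom

    def _peaks_cdf(self, x: np.ndarray, balance: float = 0.5) -> np.ndarray:
        a, b = self.peak_offsets
        return balance * norm.cdf(x, a, self.peak_sd) + (1 - balance) * norm.cdf(
            x, b, self.peak_sd
        )

    def cdf(self, archetype: str, x: np.ndarray, balance: float = 0.5) -> np.ndarray:
        """CDF of the fragment-midpoint offset for one archetype.

        ``balance`` is the mixture weight of the upstream promoter peak.
        """
        x = np.asarray(x, float)
        if archetype == "promoter_bimodal":
            return self._peaks_cdf(x, balance)
        if archetype in ("body_tail", "body_tail_weak"):
            w = self.tail_weight
            return w * self._tail_cdf(x) + (1 - w) * self._peaks_cdf(x, balance)
        if archetype == "silent":
            return np.zeros_like(x)
        raise ValueError(f"unknown archetype {archetype!r}")

    def sample_offsets(
        self,
        archetype: str,
        n: int,
        rng: np.random.Generator,
        balance: float = 0.5,
    ) -> np.ndarray:
        """Draw n TSS-relative fragment-midpoint offsets."""
        if n == 0 or archetype == "silent":
            return np.zeros(0, dtype=np.int64)
        if archetype == "promoter_bimodal":
            from_tail = np.zeros(n, dtype=bool)
        else:
            from_tail = rng.random(n) < self.tail_weight
        out = np.empty(n)
        n_tail = int(from_tail.sum())
        if n_tail:
            span = self.tail_to - self.tail_from
            u = rng.random(n_tail)
            denom = 1.0 - np.exp(-self.tail_decay * span)
            out[from_tail] = self.tail_from - np.log(1.0 - u * denom) / self.tail_decay
        n_pk = n - n_tail
        if n_pk:
            which = rng.random(n_pk) >= balance  # True -> downstream peak
            mu = np.where(which, self.peak_offsets[1], self.peak_offsets[0])
            out[~from_tail] = rng.normal(mu, self.peak_sd)
        return np.rint(out).astype(np.int64)

    def intensity(self, archetype: str) -> float:
        if archetype == "silent":
            return 0.0
        if archetype == "body_tail_weak":
            return self.weak_intensity
        return 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic genome and libraries."""

    n_genes: dict = field(
        default_factory=lambda: {
            "group1_constant": 74,
            "group2_late": 73,
            "group3_progressive": 209,
            "nonspecific_promoter": 400,
            "background": 250,
        }
    )
    stages: tuple[str, ...] = ("ES", "NP", "WB")
    chrom_lengths: dict = field(
        default_factory=lambda: {f"chr{i}": 8_000_000 for i in range(1, 5)}
    )
    reads_per_gene: float = 400.0      # Poisson mean at intensity 1
    background_per_mb: float = 50.0
    read_length: int = 36
    extension: int = 200               # must match the coverage extension
    min_spacing: int = 25_000          # TSS-to-TSS within a chromosome
    edge_margin: int = 12_000          # keep windows inside the chromosome
    promoter_intensity_sigma: float = 0.8  # lognormal sd of promoter depths
    promoter_balance_range: tuple[float, float] = (0.1, 0.9)  # upstream-peak weight
    promoter_balance_beta: float = 0.25  # Beta(a, a) shape; < 1 is U-shaped
    archetypes: ArchetypeParams = ArchetypeParams()
    seed: int = 0

    @property
    def fragment_length(self) -> int:
        return self.read_length + self.extension

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise ValueError(f"unknown stage {stage!r}; have {self.stages}") from None


@dataclass
class SyntheticTruth:
    """Planted per-gene trajectory/archetype table - the recovery oracle."""

    table: pd.DataFrame      # transcript_id, chrom, strand, tss, trajectory,
                             # intensity, archetype_<stage>...
    annotations: list[GeneAnnotation]
    sizes: ChromSizes
    cfg: SimConfig

    def archetype_of(self, stage: str) -> pd.Series:
        return self.table.set_index("transcript_id")[f"archetype_{stage}"]

    def tail_genes(self, stage: str) -> list[str]:
        """Transcripts planted with a gene-body tail (any strength) at a stage."""
        a = self.table[f"archetype_{stage}"]
        return list(self.table.loc[a.str.startswith("body_tail"), "transcript_id"])

    def genes_of(self, trajectory: str) -> list[str]:
        return list(
            self.table.loc[self.table["trajectory"] == trajectory, "transcript_id"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def simulate_truth(cfg: SimConfig = SimConfig()) -> SyntheticTruth:
    """Lay out the synthetic genome and assign trajectory classes.

    Deterministic given ``cfg.seed``. TSSs are spaced >= ``min_spacing`` apart
    and kept ``edge_margin`` bp from chromosome ends; strands and class
    placement are randomized.
    """
    bad = set(cfg.n_genes) - set(TRAJECTORY_CLASSES)
    if bad:
        raise ValueError(f"unknown trajectory classes {sorted(bad)}")
    rng = np.random.default_rng(cfg.seed)
    n_total = int(sum(cfg.n_genes.values()))

    # candidate TSS slots across chromosomes
    slots: list[tuple[str, int]] = []
    for chrom, length in cfg.chrom_lengths.items():
        pos = cfg.edge_margin
        while pos < length - cfg.edge_margin:
            slots.append((chrom, pos))
            pos += cfg.min_spacing
    if len(slots) < n_total:
        need = cfg.min_spacing * n_total + 2 * cfg.edge_margin
        raise ValueError(
            f"genome too small for {n_total} genes at {cfg.min_spacing} bp "
            f"spacing ({len(slots)} slots); need about {need} bp total"
        )
    chosen = sorted(rng.choice(len(slots), size=n_total, replace=False))
    placed = [slots[i] for i in chosen]

    classes = np.repeat(
        list(cfg.n_genes.keys()), [int(cfg.n_genes[c]) for c in cfg.n_genes]
    )
    rng.shuffle(classes)
    strands = rng.choice(["+", "-"], size=n_total)
    tx_lens = rng.integers(9_000, 15_001, size=n_total)
    intensities = np.ones(n_total)
    balances = np.full(n_total, 0.5)
    is_prom = classes == "nonspecific_promoter"
    n_prom = int(is_prom.sum())
    intensities[is_prom] = rng.lognormal(
        mean=0.0, sigma=cfg.promoter_intensity_sigma, size=n_prom
    )
    # promoter marking is typically asymmetric around the TSS: draw the
    # upstream-peak weight from a U-shaped Beta stretched over the range
    lo, hi = cfg.promoter_balance_range
    a = cfg.promoter_balance_beta
    balances[is_prom] = lo + (hi - lo) * rng.beta(a, a, size=n_prom)

    rows, annotations = [], []
    for i, ((chrom, tss), cls) in enumerate(zip(placed, classes)):
        tid = f"tx{i:05d}"
        strand = strands[i]
        L = int(tx_lens[i])
        if strand == "+":
            tx_start, tx_end = tss, tss + L
        else:
            tx_start, tx_end = tss - L + 1, tss + 1
        annotations.append(
            GeneAnnotation(tid, f"gene{i:05d}", chrom, strand, tx_start, tx_end)
        )
        rec = {
            "transcript_id": tid,
            "chrom": chrom,
            "strand": strand,
            "tss": tss,
            "trajectory": cls,
            "intensity": float(intensities[i]),
            "peak_balance": float(balances[i]),
        }
        for j, stage in enumerate(cfg.stages):
            rec[f"archetype_{stage}"] = _TRAJECTORY_ARCHETYPES[cls][j]
        rows.append(rec)

    table = pd.DataFrame(rows)
    return SyntheticTruth(table, annotations, ChromSizes(cfg.chrom_lengths), cfg)


def simulate_reads(
    truth: SyntheticTruth, stage: str, cfg: SimConfig | None = None
) -> pd.DataFrame:
    """Draw one stage's aligned-read set (BED6-shaped DataFrame).

    Per gene, the read count is Poisson(reads_per_gene x intensity); read 5'
    ends are placed so the extended fragment is centered on an archetype-drawn
    midpoint. Background reads are uniform over the genome. Deterministic
    given (cfg.seed, stage).
    """
    cfg = cfg or truth.cfg
    si = cfg.stage_index(stage)
    rng = np.random.default_rng([cfg.seed, si])
    arch = cfg.archetypes
    half = cfg.fragment_length // 2
    rl = cfg.read_length

    chroms, starts, strands = [], [], []
    for rec in truth.table.itertuples(index=False):
        a = getattr(rec, f"archetype_{stage}")
        lam = cfg.reads_per_gene * arch.intensity(a) * rec.intensity
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n == 0:
            continue
        rel = arch.sample_offsets(a, n, rng, balance=rec.peak_balance)
        mid = rec.tss + rel if rec.strand == "+" else rec.tss - rel
        read_strand = rng.choice(["+", "-"], size=n)
        # extended fragment is [mid - half, mid - half + fragment_length);
        # recover the read's own coordinates from its strand
        s = np.where(
            read_strand == "+", mid - half, mid - half + cfg.fragment_length - rl
        )
        s = np.clip(s, 0, truth.sizes[rec.chrom] - rl)
        chroms.extend([rec.chrom] * n)
        starts.append(s)
        strands.append(read_strand)

    for chrom, length in cfg.chrom_lengths.items():
        n_bg = int(rng.poisson(cfg.background_per_mb * length / 1e6))
        if n_bg == 0:
            continue
        s = rng.integers(0, length - rl + 1, size=n_bg)
        chroms.extend([chrom] * n_bg)
        starts.append(s)
        strands.append(rng.choice(["+", "-"], size=n_bg))

    if starts:
        start = np.concatenate(starts).astype(np.int64)
        strand = np.concatenate(strands)
    else:
        start = np.zeros(0, dtype=np.int64)
        strand = np.zeros(0, dtype=str)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": start,
            "end": start + rl,
            "strand": pd.Series(strand, dtype=str),
        }
    )


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a read table as BED6 (name=read index, score=0)."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["end"],
            "name": [f"read{i}" for i in range(len(reads))],
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_refgene(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write transcripts as a UCSC refGene-style flat file (with bin column)."""
    with open(path, "w") as fh:
        for g in annotations:
            fh.write(
                "\t".join(
                    [
                        "0", g.transcript_id, g.chrom, g.strand,
                        str(g.tx_start), str(g.tx_end),
                        str(g.tx_start), str(g.tx_end),
                        "1", f"{g.tx_start},", f"{g.tx_end},",
                        "0", g.gene_symbol, "unk", "unk", "-1,",
                    ]
                )
                + "\n"
            )


def expected_profile_matrix(
    truth: SyntheticTruth,
    stage: str,
    flank: int = 10_000,
    bin_size: int = 20,
    include_background: bool = True,
) -> ProfileMatrix:
    """Noise-free expected binned coverage of extended reads (overlap rule).

    The expected count of a bin is the archetype midpoint mass within the bin
    dilated by half the fragment length on each side, times the Poisson mean -
    the closed-form limit of the simulator at infinite replication. Useful as
    the noiseless reference for recovery analyses.
    """
    cfg = truth.cfg
    arch = cfg.archetypes
    half = cfg.fragment_length // 2
    n_bins = (2 * flank) // bin_size
    edges = np.arange(n_bins + 1) * bin_size - flank  # TSS-relative bin edges
    lo, hi = edges[:-1] - half, edges[1:] + half
    bg = (
        cfg.background_per_mb / 1e6 * (bin_size + cfg.fragment_length)
        if include_background
        else 0.0
    )
    counts = np.zeros((len(truth.table), n_bins))
    for i, rec in enumerate(truth.table.itertuples(index=False)):
        a = getattr(rec, f"archetype_{stage}")
        lam = cfg.reads_per_gene * arch.intensity(a) * rec.intensity
        if lam > 0:
            b = rec.peak_balance
            counts[i] = lam * (arch.cdf(a, hi, b) - arch.cdf(a, lo, b))
        counts[i] += bg
    return ProfileMatrix(
        counts,
        list(truth.table["transcript_id"]),
        flank,
        bin_size,
        stage_label=stage,
        normalization="raw",
        meta={"expected": True},
    )
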