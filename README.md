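# tailmark

Strand-aware TSS metaprofiles, gene-body "tail" discovery and cross-stage
histone-mark redistribution analysis for ChIP-seq.

## The problem

H3K4me2 normally marks promoters with a bimodal peak around the transcription
start site (TSS). On tissue-specific genes it does something different: it
spreads into the transcribed region, producing a sustained "tail" of signal
out to roughly +8 kb downstream of the TSS. Tracking where that gene-body
signature appears — and when it is acquired across developmental stages such
as embryonic stem cells (ES), neural progenitors (NP) and whole brain (WB) —
identifies tissue-specific genes and the stage at which they commit.

`tailmark` implements that analysis as a tested, reusable pipeline:

1. **Binned TSS profiles.** Aligned reads (BED6) are extended 3′-ward by a
   fixed fragment allowance (default 200 bp) and counted into 20-bp bins over
   ±10 kb windows around every annotated TSS, oriented along transcription, so
   bin 0 is always the most upstream bin. This yields a genes × 1000 profile
   matrix per stage; `rpm` normalization (counts × 10⁶ / library size) makes
   stages comparable.
2. **Two-stage tail discovery.** K-means (squared Euclidean, k = 7,
   50 restarts with uniform random distinct-row initialization) clusters the
   profiles of the most differentiated stage; the cluster with the highest
   *tail score* is re-clustered at k = 4 and the refined tail cluster is the
   candidate set of gene-body-marked genes. The tail score of a centroid
   **c** is

   ```
   score(c) = mean(c over +2..+8 kb) / (mean(c over −10..−2 kb) + ε)
   ```

   a scale-invariant gene-body/upstream-flank signal ratio that formalizes
   what is otherwise a visual call (a flat profile scores ≈ 1).
3. **Cross-stage redistribution.** The candidates' per-stage profiles are
   concatenated (ES‖NP‖WB, 3000 columns), clustered hierarchically under
   correlation distance d(x,y) = 1 − r(x,y) with average linkage, and cut
   into k = 3 groups. Each group is labeled from its per-stage tail scores
   against a threshold τ (default 2): `constant` (all stages ≥ τ),
   `late_only` (only the final stage ≥ τ), `progressive` (acquired at the
   intermediate stage and non-decreasing), else `other`. PCA and a silhouette
   coefficient report how separated the groups are.
4. **Overlap statistics.** Candidate-set overlaps with any stage's k = 7
   clusters (or user GMT gene sets) are scored with an exact upper-tail
   hypergeometric test P(X ≥ k) and Benjamini–Hochberg adjustment.

A first-class synthetic-data module generates multi-stage read sets with
planted profile archetypes (promoter-bimodal, body-tail, silent) and
trajectory classes, together with the ground truth, so every pipeline stage
is testable end to end without downloading anything.

## Worked example

```python
from tailmark import (
    SimConfig, simulate_truth, simulate_reads, make_windows,
    compute_profile_matrix, CoverageConfig, TailDiscovery,
    StageRedistribution, StageSet,
)

cfg = SimConfig(seed=17)                      # ~1000 genes, stages ES -> NP -> WB
truth = simulate_truth(cfg)
windows = make_windows(truth.annotations, truth.sizes)

matrices = {}
for stage in cfg.stages:
    reads = simulate_reads(truth, stage, cfg)
    matrices[stage] = compute_profile_matrix(
        reads, windows, CoverageConfig(), truth.sizes, stage
    ).to_rpm()

discovery = TailDiscovery(matrices["WB"]).fit(seed=17)
print(discovery.summary())

redis = StageRedistribution(StageSet(list(cfg.stages), matrices),
                           discovery.candidate_ids).fit()
print(redis.summary())
```

prints

```
Two-stage tail discovery
========================
stage label        : WB
rows x bins        : 1006 x 1000
seed               : 17

stage 1 (k=7): cluster sizes / tail scores
  cluster 0: n=  485  score= 278.737 <- selected
  ...
stage 2 (k=4): cluster sizes / tail scores
  cluster 2: n=  361  score= 357.902 <- selected
  ...
candidate gene-body-marked genes: 361

Cross-stage redistribution
==========================
genes              : 361
stages             : ES -> NP -> WB
groups (k)         : 3   tau = 2.0
PCA evr            : 0.779, 0.079
silhouette (corr)  : 0.792

group  n      label         s_ES      s_NP      s_WB
    0  209    progressive       1.29    212.58    328.72
    1  79     constant        357.91    258.21    358.86
    2  73     late_only         1.06      0.88    421.19
```

Reading: the coarse k = 7 pass isolates a mixed low-signal cluster of 485
genes; the k = 4 refinement extracts 361 candidates (356 of the simulation's
planted gene-body genes plus 5 weak-promoter bystanders). The 3-cut of the
combined profiles recovers the three planted trajectories — 209 genes gain
the mark progressively from the NP stage, 79 carry it throughout, 73 acquire
it only in the final stage — and the per-stage tail scores drive the labels.

The same steps are available from the shell:

```sh
tailmark simulate --seed 17 --out sim/
tailmark run --config pipeline.yaml --seed 17 --out results/
tailmark discover --reads sim/reads_WB.bed --annotation sim/annotation.refgene.txt \
    --chrom-sizes sim/chrom.sizes --out candidates.txt
```

## Real data

The pipeline accepts any BED6 read files (one interval per mapped read,
strand required), a refGene/GTF/BED12 annotation and a chrom.sizes table —
e.g. mouse ES/NP/WB H3K4me2 ChIP-seq alignments derived from GEO series
GSE11172 mapped against mm8, converted to BED with `bedtools bamtobed`.
Point the per-stage entries of the YAML config at the files, in
developmental order; discovery runs on the last stage. There is no built-in
downloader. Exact reproduction of published gene counts from such data is
not a goal: they depend on the original clustering software's RNG state.

See `docs/methods.md` for the model details, parameter choices and
limitations.
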