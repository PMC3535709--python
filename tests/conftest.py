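import numpy as np
import pytest

from tailmark.annotations import ChromSizes, GeneAnnotation, make_windows
from tailmark.coverage import CoverageConfig, compute_profile_matrix
from tailmark.simulate import SimConfig, simulate_reads, simulate_truth


@pytest.fixture(scope="session")
def tiny_sizes():
    return ChromSizes({"chr1": 1_000_000})


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down simulation: same structure, ~1/10 the genes."""
    return SimConfig(
        n_genes={
            "group1_constant": 8,
            "group2_late": 8,
            "group3_progressive": 20,
            "nonspecific_promoter": 40,
            "background": 24,
        },
        chrom_lengths={"chrA": 1_500_000, "chrB": 1_500_000},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate_truth(small_cfg)


@pytest.fixture(scope="session")
def small_windows(small_truth):
    return make_windows(small_truth.annotations, small_truth.sizes)


@pytest.fixture(scope="session")
def small_matrices(small_cfg, small_truth, small_windows):
    out = {}
    for stage in small_cfg.stages:
        reads = simulate_reads(small_truth, stage, small_cfg)
        out[stage] = compute_profile_matrix(
            reads, small_windows, CoverageConfig(), small_truth.sizes, stage
        )
    return out
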