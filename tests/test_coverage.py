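import numpy as np
import pytest

from oracles import brute_force_profile
from tailmark.annotations import ChromSizes, GeneAnnotation, make_windows
from tailmark.coverage import (
    CoverageConfig,
    ProfileMatrix,
    ReadAlignment,
    compute_profile_matrix,
    extend_read,
    mean_profile,
    read_bed_reads,
)


class TestExtendRead:
    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [
            ("+", 1000, 1036, (1000, 1236)),
            ("-", 1000, 1036, (800, 1036)),  # same total extended length as +
            ("-", 50, 86, (0, 86)),  # clipped at chromosome start
        ],
    )
    def test_three_prime_extension(self, tiny_sizes, strand, start, end, expected):
        r = ReadAlignment("chr1", start, end, strand)
        assert extend_read(r, 200, tiny_sizes) == expected

    def test_clipped_at_chromosome_end(self):
        sizes = ChromSizes({"c": 1100})
        r = ReadAlignment("c", 1000, 1036, "+")
        assert extend_read(r, 200, sizes) == (1000, 1100)


def _plus_gene(tss, tid="t", chrom="chr1"):
    return GeneAnnotation(tid, "", chrom, "+", tss, tss + 15_000)


class TestProfileMatrixExamples:
    def test_single_read_overlap_rule_increments_12_bins(self, tiny_sizes):
        windows = make_windows([_plus_gene(1000 + 9000)], tiny_sizes)
        # gene TSS at 10_000; read at TSS start
        reads = [ReadAlignment("chr1", 10_000, 10_036, "+")]
        m = compute_profile_matrix(reads, windows, CoverageConfig(), tiny_sizes)
        row = m.counts[0]
        # extended interval covers relative [0, 236) -> bins 500..511
        assert row[500:512].tolist() == [1] * 12
        assert row.sum() == 12

    def test_single_read_midpoint_rule_single_bin(self, tiny_sizes):
        windows = make_windows([_plus_gene(10_000)], tiny_sizes)
        reads = [ReadAlignment("chr1", 10_000, 10_036, "+")]
        cfg = CoverageConfig(bin_rule="midpoint")
        m = compute_profile_matrix(reads, windows, cfg, tiny_sizes)
        assert m.counts[0, 505] == 1 and m.counts.sum() == 1

    def test_zero_reads_zero_matrix(self, tiny_sizes):
        windows = make_windows([_plus_gene(10_000)], tiny_sizes)
        m = compute_profile_matrix([], windows, CoverageConfig(), tiny_sizes)
        assert m.counts.shape == (1, 1000) and m.counts.sum() == 0

    def test_read_in_two_overlapping_windows_counts_in_both(self, tiny_sizes):
        genes = [_plus_gene(10_000, "a"), _plus_gene(14_000, "b")]
        windows = make_windows(genes, tiny_sizes)
        reads = [ReadAlignment("chr1", 12_000, 12_036, "+")]
        m = compute_profile_matrix(reads, windows, CoverageConfig(), tiny_sizes)
        assert (m.counts[0] > 0).any() and (m.counts[1] > 0).any()

    def test_unknown_chrom_skipped_with_count(self, tiny_sizes):
        windows = make_windows([_plus_gene(10_000)], tiny_sizes)
        reads = [
            ReadAlignment("chrUn", 100, 136, "+"),
            ReadAlignment("chr1", 10_000, 10_036, "+"),
        ]
        m = compute_profile_matrix(reads, windows, CoverageConfig(), tiny_sizes)
        assert m.meta["n_skipped_reads"] == 1
        assert m.counts.sum() == 12


def _random_instance(rng, n_reads, n_windows, chrom_len=40_000, flank=400, bin_size=20):
    sizes = ChromSizes({"c": chrom_len})
    genes = []
    for i in range(n_windows):
        strand = rng.choice(["+", "-"])
        tss = int(rng.integers(0, chrom_len))
        if strand == "+":
            g = GeneAnnotation(f"g{i}", "", "c", "+", tss, tss + 500)
        else:
            g = GeneAnnotation(f"g{i}", "", "c", "-", max(0, tss - 500), tss + 1)
        genes.append(g)
    windows = make_windows(genes, sizes, flank, bin_size)
    reads = []
    for _ in range(n_reads):
        s = int(rng.integers(0, chrom_len - 36))
        reads.append(("c", s, s + 36, str(rng.choice(["+", "-"]))))
    return reads, windows, sizes


@pytest.mark.parametrize("bin_rule", ["overlap", "midpoint"])
def test_matches_brute_force_oracle(bin_rule):
    rng = np.random.default_rng(42)
    for _ in range(8):
        reads, windows, sizes = _random_instance(
            rng, n_reads=int(rng.integers(0, 80)), n_windows=int(rng.integers(1, 6))
        )
        m = compute_profile_matrix(
            [ReadAlignment(*r) for r in reads],
            windows,
            CoverageConfig(bin_rule=bin_rule),
            sizes,
        )
        expected = brute_force_profile(reads, windows, 200, sizes, bin_rule)
        np.testing.assert_array_equal(m.counts, expected)


def test_strand_symmetry_bit_identical():
    """Mirroring reads and genes about a genomic point preserves the matrix."""
    rng = np.random.default_rng(7)
    M = 40_000
    reads, windows, sizes = _random_instance(rng, 120, 6, chrom_len=M)
    mirrored_genes = []
    for w in windows:
        tss2 = M - w.tss
        strand2 = "-" if w.strand == "+" else "+"
        if strand2 == "+":
            g = GeneAnnotation(w.transcript_id, "", "c", "+", tss2, tss2 + 500)
        else:
            g = GeneAnnotation(w.transcript_id, "", "c", "-", max(0, tss2 - 500), tss2 + 1)
        mirrored_genes.append(g)
    mirrored_windows = make_windows(mirrored_genes, sizes, 400, 20)
    mirrored_reads = [
        ReadAlignment("c", M - e, M - s, "-" if st == "+" else "+")
        for _, s, e, st in reads
    ]
    m1 = compute_profile_matrix(
        [ReadAlignment(*r) for r in reads], windows, CoverageConfig(), sizes
    )
    m2 = compute_profile_matrix(mirrored_reads, mirrored_windows, CoverageConfig(), sizes)
    np.testing.assert_array_equal(m1.counts, m2.counts)


class TestNormalization:
    def test_rpm_scales_cells_by_library_size(self, tiny_sizes):
        windows = make_windows([_plus_gene(10_000)], tiny_sizes)
        reads = [ReadAlignment("chr1", 10_000, 10_036, "+")] * 4
        m = compute_profile_matrix(reads, windows, CoverageConfig(), tiny_sizes)
        r = m.to_rpm()
        assert r.normalization == "rpm"
        np.testing.assert_allclose(r.counts, m.counts * 1e6 / 4)

    def test_rpm_requires_library_size(self):
        m = ProfileMatrix(np.zeros((1, 1000)), ["a"])
        with pytest.raises(ValueError):
            m.to_rpm()


class TestMeanProfile:
    def test_single_row_identity(self):
        m = ProfileMatrix(np.arange(1000.0)[None, :], ["a"])
        np.testing.assert_array_equal(mean_profile(m), np.arange(1000.0))

    def test_two_rows_average(self):
        X = np.zeros((2, 1000))
        X[0, 0], X[1, 1] = 2, 2
        m = ProfileMatrix(X, ["a", "b"])
        v = m.mean_profile(["a", "b"])
        assert v[0] == 1 and v[1] == 1

    def test_subset_matches_explicit_summation(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3, size=(20, 1000)).astype(float)
        ids = [f"g{i}" for i in range(20)]
        m = ProfileMatrix(X, ids)
        pick = [ids[i] for i in rng.choice(20, 7, replace=False)]
        expected = sum(X[ids.index(g)] for g in pick) / len(pick)
        np.testing.assert_allclose(m.mean_profile(pick), expected)

    def test_empty_subset_rejected(self):
        m = ProfileMatrix(np.zeros((2, 1000)), ["a", "b"])
        with pytest.raises(ValueError):
            m.mean_profile([])


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        m = ProfileMatrix(rng.poisson(2, (3, 1000)).astype(float), ["a", "b", "c"])
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        m2 = ProfileMatrix.from_tsv(p)
        assert m2.row_ids == ["a", "b", "c"]
        np.testing.assert_allclose(m2.counts, m.counts)

    def test_bed_reader_requires_strand(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t10\t46\n")
        with pytest.raises(ValueError):
            read_bed_reads(p)

    def test_bed_reader_parses_bed6(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t10\t46\tr0\t0\t+\nchr2\t5\t41\tr1\t0\t-\n")
        df = read_bed_reads(p)
        assert list(df["strand"]) == ["+", "-"]
        assert list(df["end"] - df["start"]) == [36, 36]
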