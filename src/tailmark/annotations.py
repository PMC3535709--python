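"""Gene annotations, chromosome sizes and strand-aware binned TSS windows.

Coordinates are 0-based, half-open (BED convention) everywhere. UCSC refGene
flat files already use this convention; GTF input (1-based, inclusive) is
converted on load. The transcription start site (TSS) of a ``-`` strand
transcript is ``tx_end - 1``, i.e. the 5' end of the transcript, which is the
only reading under which "upstream"/"downstream" keep their transcriptional
meaning in profile plots.

A :class:`TSSWindow` covers ``[tss - flank, tss + flank)`` on the genome, cut
into contiguous ``bin_size``-bp bins and *oriented along transcription*: bin 0
is always the most upstream bin, bin ``n_bins - 1`` the most downstream,
regardless of strand. Bins falling (even partly) outside the chromosome are
flagged in ``clipped_bins`` and carry zero counts; the gene is kept so profile
matrices stay rectangular.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "GeneAnnotation",
    "ChromSizes",
    "TSSWindow",
    "BinGeometry",
    "load_annotations",
    "load_chrom_sizes",
    "tss_of",
    "make_windows",
    "write_windows_bed",
]

_STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One transcript record: id, location and orientation."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise AnnotationError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.tx_start < self.tx_end:
            raise AnnotationError(
                f"transcript {self.transcript_id!r}: require tx_start < tx_end, "
                f"got [{self.tx_start}, {self.tx_end})"
            )

    @property
    def tss(self) -> int:
        return tss_of(self)


def tss_of(gene: GeneAnnotation) -> int:
    """0-based genomic position of the transcription start site (5' end)."""
    return gene.tx_start if gene.strand == "+" else gene.tx_end - 1


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp). All lengths must be positive."""

    def __init__(self, sizes: Mapping[str, int]):
        bad = {c: n for c, n in sizes.items() if int(n) <= 0}
        if bad:
            raise AnnotationError(f"non-positive chromosome lengths: {bad}")
        self._sizes = {str(c): int(n) for c, n in sizes.items()}

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ChromSizes({self._sizes!r})"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, n in self._sizes.items():
                fh.write(f"{chrom}\t{n}\n")


def load_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) chrom.sizes TSV."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(_open_text(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{lineno}: expected 'name<TAB>length'")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as e:
            raise AnnotationError(f"{path}:{lineno}: bad length {parts[1]!r}") from e
    return ChromSizes(sizes)


@dataclass(frozen=True)
class BinGeometry:
    """Shared window geometry: half-width and bin width in bp."""

    flank: int = 10_000
    bin_size: int = 20

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.bin_size <= 0:
            raise ValueError("flank and bin_size must be positive")
        if (2 * self.flank) % self.bin_size != 0:
            raise ValueError(
                f"window width 2*{self.flank} is not a multiple of bin_size "
                f"{self.bin_size}"
            )

    @property
    def n_bins(self) -> int:
        return (2 * self.flank) // self.bin_size

    def bin_range(self, from_bp: int, to_bp: int) -> tuple[int, int]:
        """Bin index range (half-open) covering transcript-relative [from_bp, to_bp).

        Offsets are relative to the TSS, negative = upstream. The returned
        range includes every bin overlapping the interval.
        """
        if not -self.flank <= from_bp < to_bp <= self.flank:
            raise ValueError(
                f"[{from_bp}, {to_bp}) outside window [-{self.flank}, {self.flank})"
            )
        lo = (from_bp + self.flank) // self.bin_size
        hi = -((-(to_bp + self.flank)) // self.bin_size)  # ceil div
        return int(lo), int(hi)


@dataclass(frozen=True)
class TSSWindow:
    """A transcript's strand-oriented, binned +/- flank window around its TSS."""

    transcript_id: str
    chrom: str
    strand: str
    tss: int
    flank: int = 10_000
    bin_size: int = 20
    clipped_bins: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_bins(self) -> int:
        return (2 * self.flank) // self.bin_size

    @property
    def geometry(self) -> BinGeometry:
        return BinGeometry(self.flank, self.bin_size)

    @property
    def genomic_start(self) -> int:
        return self.tss - self.flank

    @property
    def genomic_end(self) -> int:
        return self.tss + self.flank

    def bin_interval(self, index: int) -> tuple[int, int]:
        """Genomic half-open interval of a bin (may extend outside the chromosome)."""
        if not 0 <= index < self.n_bins:
            raise IndexError(index)
        if self.strand == "+":
            start = self.genomic_start + index * self.bin_size
        else:
            start = self.genomic_end - (index + 1) * self.bin_size
        return start, start + self.bin_size

    def bin_of(self, pos: int) -> int:
        """Transcript-oriented bin index containing genomic position ``pos``."""
        if not self.genomic_start <= pos < self.genomic_end:
            raise ValueError(f"position {pos} outside window of {self.transcript_id}")
        if self.strand == "+":
            return (pos - self.genomic_start) // self.bin_size
        return (self.genomic_end - 1 - pos) // self.bin_size


def make_windows(
    genes: Iterable[GeneAnnotation],
    sizes: ChromSizes,
    flank: int = 10_000,
    bin_size: int = 20,
) -> list[TSSWindow]:
    """Build one binned TSS window per transcript.

    Bins reaching past ``[0, chrom_length)`` are flagged in ``clipped_bins``
    (and later forced to zero counts) rather than dropping the transcript.
    """
    BinGeometry(flank, bin_size)  # validates divisibility
    genes = list(genes)
    missing = [g.transcript_id for g in genes if g.chrom not in sizes]
    if missing:
        raise AnnotationError(
            "transcripts on chromosomes absent from the sizes table: "
            + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )
    windows = []
    for g in genes:
        tss = tss_of(g)
        chrom_len = sizes[g.chrom]
        w = TSSWindow(g.transcript_id, g.chrom, g.strand, tss, flank, bin_size)
        clipped = []
        if w.genomic_start < 0 or w.genomic_end > chrom_len:
            for b in range(w.n_bins):
                s, e = w.bin_interval(b)
                if s < 0 or e > chrom_len:
                    clipped.append(b)
        if clipped:
            w = TSSWindow(
                g.transcript_id, g.chrom, g.strand, tss, flank, bin_size,
                clipped_bins=frozenset(clipped),
            )
        windows.append(w)
    return windows


def write_windows_bed(windows: Iterable[TSSWindow], path: str | Path) -> None:
    """Write windows as BED6 (name=transcript_id, score=0)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.chrom}\t{max(0, w.genomic_start)}\t{w.genomic_end}\t"
                f"{w.transcript_id}\t0\t{w.strand}\n"
            )


# ---------------------------------------------------------------------------
# annotation file dialects


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def load_annotations(path: str | Path, dialect: str = "refgene") -> list[GeneAnnotation]:
    """Load transcript records from refGene, GTF or BED12 input.

    One :class:`GeneAnnotation` per transcript, in file order (for GTF, in
    order of first appearance of each transcript_id, spanning the min/max of
    its features). Isoforms are *not* collapsed: every entry is profiled.
    """
    dialect = dialect.lower()
    parsers = {"refgene": _parse_refgene, "gtf": _parse_gtf, "bed12": _parse_bed12}
    if dialect not in parsers:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with _open_text(path) as fh:
        return parsers[dialect](fh, str(path))


def _parse_refgene(fh: Iterable[str], name: str) -> list[GeneAnnotation]:
    # UCSC refGene flat format, with or without the leading 'bin' column:
    # [bin] name chrom strand txStart txEnd cdsStart cdsEnd exonCount ... name2 ...
    out = []
    for lineno, line in enumerate(fh, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        try:
            if len(f) >= 4 and f[3] in _STRANDS:
                off = 1  # has bin column
            elif len(f) >= 3 and f[2] in _STRANDS:
                off = 0
            else:
                raise AnnotationError("no strand column found")
            tid, chrom, strand = f[off], f[off + 1], f[off + 2]
            tx_start, tx_end = int(f[off + 3]), int(f[off + 4])
            symbol = f[off + 11] if len(f) > off + 11 else ""
            out.append(GeneAnnotation(tid, symbol, chrom, strand, tx_start, tx_end))
        except (AnnotationError, ValueError, IndexError) as e:
            raise AnnotationError(f"{name}:{lineno}: malformed refGene line ({e})") from e
    return out


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _parse_gtf(fh: Iterable[str], name: str) -> list[GeneAnnotation]:
    spans: dict[str, list] = {}
    order: list[str] = []
    for lineno, line in enumerate(fh, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise AnnotationError(f"{name}:{lineno}: expected 9 GTF columns, got {len(f)}")
        chrom, strand = f[0], f[6]
        if strand not in _STRANDS:
            raise AnnotationError(f"{name}:{lineno}: unknown strand {strand!r}")
        try:
            start1, end1 = int(f[3]), int(f[4])
        except ValueError as e:
            raise AnnotationError(f"{name}:{lineno}: bad coordinates") from e
        attrs = _parse_gtf_attrs(f[8])
        tid = attrs.get("transcript_id")
        if tid is None:
            continue  # gene-level or headerless feature
        start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if tid not in spans:
            spans[tid] = [attrs.get("gene_name", attrs.get("gene_id", "")),
                          chrom, strand, start0, end0]
            order.append(tid)
        else:
            rec = spans[tid]
            if (rec[1], rec[2]) != (chrom, strand):
                raise AnnotationError(
                    f"{name}:{lineno}: transcript {tid!r} spans multiple "
                    "chromosomes/strands"
                )
            rec[3] = min(rec[3], start0)
            rec[4] = max(rec[4], end0)
    return [
        GeneAnnotation(tid, spans[tid][0], spans[tid][1], spans[tid][2],
                       spans[tid][3], spans[tid][4])
        for tid in order
    ]


def _parse_bed12(fh: Iterable[str], name: str) -> list[GeneAnnotation]:
    out = []
    for lineno, line in enumerate(fh, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 6:
            raise AnnotationError(f"{name}:{lineno}: BED needs >= 6 columns for strand")
        try:
            out.append(
                GeneAnnotation(f[3], "", f[0], f[5], int(f[1]), int(f[2]))
            )
        except (AnnotationError, ValueError) as e:
            raise AnnotationError(f"{name}:{lineno}: malformed BED line ({e})") from e
    return out
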