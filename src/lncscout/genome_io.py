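"""I/O layer for the genomic formats the discovery pipeline consumes.

Genomes arrive as FASTA, known-gene annotation as GTF or BED, per-sample
read alignments as coordinate-sorted indexed BAM, and (alternatively)
per-sample per-base coverage as bedGraph.  All coordinates are held
internally as 0-based half-open intervals; GTF's 1-based inclusive
convention is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom/start/end/strand region (0-based, half-open).

    The unit of sliding windows, exons, gene spans and merged candidate
    regions.  ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome(Mapping[str, str]):
    """In-memory genome: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"record {name!r} contains invalid bases {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, clip: bool = False) -> str:
        """Sequence of ``[start, end)`` on ``chrom``.

        With ``clip=True`` the range is clipped to the chromosome bounds
        instead of raising.
        """
        n = len(self._seqs[chrom])
        if clip:
            start, end = max(0, start), min(n, end)
            if start >= end:
                return ""
        elif start < 0 or end > n or start >= end:
            raise ValueError(f"range {chrom}:{start}-{end} out of bounds (len {n})")
        return self._seqs[chrom][start:end]


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased; only A/C/G/T/N are accepted.  Malformed
    records raise :class:`ValueError` naming the offending record.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA record {record.id!r}")
        if len(record.seq) == 0:
            raise ValueError(f"empty FASTA record {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(seqs)


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class AnnotationRecord:
    interval: GenomicInterval
    gene_id: str
    source: str = ""


class AnnotationSet:
    """Gene-level intervals with O(log n + k) overlap queries."""

    def __init__(self, records: Iterable[AnnotationRecord] = ()):
        self._records = sorted(records, key=lambda r: r.interval)
        self._trees: dict[str, IntervalTree] = {}
        for rec in self._records:
            tree = self._trees.setdefault(rec.interval.chrom, IntervalTree())
            tree.addi(rec.interval.start, rec.interval.end, rec)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], source: str = ""
    ) -> "AnnotationSet":
        return cls(
            AnnotationRecord(iv, gene_id=f"gene_{i}", source=source)
            for i, iv in enumerate(intervals)
        )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self._records)

    def overlaps(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        return bool(tree is not None and tree.overlaps(interval.start, interval.end))

    def query(self, interval: GenomicInterval) -> list[AnnotationRecord]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted((h.data for h in hits), key=lambda r: r.interval)


_GENE_ID_RE = re.compile(r'gene_id[ =]+"?([^";]+)"?')


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return "gtf"
    if path.suffix.lower() in {".bed"}:
        return "bed"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9:
                # GTF: columns 4/5 are coordinates, column 9 attributes
                try:
                    int(fields[3]), int(fields[4])
                    return "gtf"
                except ValueError:
                    pass
            if len(fields) >= 3:
                try:
                    int(fields[1]), int(fields[2])
                    return "bed"
                except ValueError:
                    pass
            break
    raise ValueError(f"cannot determine annotation format of {path}")


def read_annotation(path: str | Path, fmt: str | None = None) -> AnnotationSet:
    """Read known-gene annotation from GTF or BED into gene spans.

    GTF ``gene`` features are used directly when present; otherwise the
    per-``gene_id`` span (union of exons and introns) is taken.  GTF 1-based
    inclusive coordinates are converted to 0-based half-open.  BED intervals
    are taken as-is.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gtf(path: Path) -> AnnotationSet:
    gene_feats: dict[str, AnnotationRecord] = {}
    spans: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, source, feature = fields[0], fields[1], fields[2]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            strand = fields[6] if fields[6] in ("+", "-") else "."
            m = _GENE_ID_RE.search(fields[8])
            gene_id = m.group(1) if m else f"{chrom}:{start}-{end}"
            if feature == "gene":
                gene_feats[gene_id] = AnnotationRecord(
                    GenomicInterval(chrom, start, end, strand), gene_id, source
                )
            elif feature in ("transcript", "exon", "CDS"):
                cur = spans.get(gene_id)
                if cur is None:
                    spans[gene_id] = [chrom, start, end, strand, source]
                else:
                    cur[1] = min(cur[1], start)
                    cur[2] = max(cur[2], end)
    records = list(gene_feats.values())
    for gene_id, (chrom, start, end, strand, source) in spans.items():
        if gene_id not in gene_feats:
            records.append(
                AnnotationRecord(GenomicInterval(chrom, start, end, strand), gene_id, source)
            )
    return AnnotationSet(records)


def _read_bed(path: Path) -> AnnotationSet:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({end} <= {start})")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            records.append(
                AnnotationRecord(GenomicInterval(chrom, start, end, strand), name, "bed")
            )
    return AnnotationSet(records)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (strand appended as columns 4-6 when set)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Alignments and coverage


def _keep_read(read: pysam.AlignedSegment) -> bool:
    # primary alignments only; duplicates deliberately kept (no dedup step)
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def count_mapped_reads(path: str | Path) -> int:
    """Number of primary mapped read records (the RPM denominator)."""
    n = 0
    with pysam.AlignmentFile(str(path), "rb") as af:
        for read in af.fetch(until_eof=True):
            if _keep_read(read):
                n += 1
    return n


class SampleAlignment:
    """One sample's coordinate-sorted, indexed BAM plus its RPM denominator.

    ``mapped_reads`` is counted from the file (primary alignments only)
    unless supplied.
    """

    def __init__(self, sample_id: str, path: str | Path, mapped_reads: int | None = None):
        self.sample_id = sample_id
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(self.path)
        self._mapped = mapped_reads

    def __repr__(self) -> str:
        return f"SampleAlignment({self.sample_id!r}, {str(self.path)!r})"

    @property
    def mapped_reads(self) -> int:
        if self._mapped is None:
            self._mapped = count_mapped_reads(self.path)
        return self._mapped

    def _open(self) -> pysam.AlignmentFile:
        af = pysam.AlignmentFile(str(self.path), "rb")
        if not af.has_index():
            af.close()
            raise OSError(
                f"{self.path} has no index; run `samtools index {self.path}` first"
            )
        return af

    def fetch(self, region: GenomicInterval) -> Iterator[pysam.AlignedSegment]:
        """Primary reads overlapping the region (by alignment span)."""
        with self._open() as af:
            for read in af.fetch(region.chrom, region.start, region.end):
                if _keep_read(read):
                    yield read

    def per_base_depth(self, region: GenomicInterval) -> np.ndarray:
        """Raw aligned-base depth for every position of ``region``.

        CIGAR N (skipped intron) contributes zero depth; each aligned base
        of each primary read counts once.
        """
        with self._open() as af:
            acgt = af.count_coverage(
                region.chrom,
                region.start,
                region.end,
                quality_threshold=0,
                read_callback=_keep_read,
            )
        return np.asarray(acgt, dtype=np.int64).sum(axis=0)


class SampleCoverage:
    """bedGraph-backed stand-in for :class:`SampleAlignment` coverage access.

    Lets the window scan run without BAM machinery; ``mapped_reads`` must be
    supplied because bedGraph carries no read records.
    """

    def __init__(
        self,
        sample_id: str,
        path: str | Path,
        mapped_reads: int,
        chrom_lengths: Mapping[str, int],
    ):
        self.sample_id = sample_id
        self.path = Path(path)
        if mapped_reads <= 0:
            raise ValueError("mapped_reads must be positive for bedGraph input")
        self._mapped = mapped_reads
        self._depth = read_bedgraph(self.path, chrom_lengths)

    @property
    def mapped_reads(self) -> int:
        return self._mapped

    def per_base_depth(self, region: GenomicInterval) -> np.ndarray:
        arr = self._depth.get(region.chrom)
        if arr is None:
            return np.zeros(len(region))
        return arr[region.start : region.end].copy()


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Dense per-base coverage arrays from a 0-based half-open bedGraph."""
    depth = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom in depth:
                depth[chrom][start:end] += value
    return depth


def write_bedgraph(depth: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encode per-base coverage as bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in depth:
            arr = np.asarray(depth[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    v = arr[s]
                    text = f"{int(v)}" if float(v).is_integer() else f"{v:g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")


def rpm_normalize(raw, mapped_reads: int):
    """Reads-per-million normalization: ``raw / (mapped_reads / 1e6)``.

    Accepts scalars or arrays.  A zero numerator is 0 RPM for any
    denominator; a nonzero numerator with zero mapped reads is an error.
    """
    raw_arr = np.asarray(raw, dtype=float)
    if mapped_reads <= 0:
        if np.any(raw_arr != 0):
            raise ValueError("cannot RPM-normalize nonzero counts with 0 mapped reads")
        return raw if np.isscalar(raw) else np.zeros_like(raw_arr)
    out = raw_arr * (1e6 / mapped_reads)
    return float(out) if np.isscalar(raw) else out


def count_reads_in_regions(
    aln: SampleAlignment, regions: Iterable[GenomicInterval]
) -> np.ndarray:
    """Per-region count of reads with an aligned block overlapping the region.

    A read is counted at most once per region; a read whose only skipped
    intron (CIGAR N) spans the region does not count.
    """
    counts = []
    for region in regions:
        n = 0
        for read in aln.fetch(region):
            if any(
                bs < region.end and region.start < be
                for bs, be in read.get_blocks()
            ):
                n += 1
        counts.append(n)
    return np.asarray(counts, dtype=np.int64)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
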