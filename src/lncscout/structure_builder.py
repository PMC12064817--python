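"""Expansion of merged candidate regions into full gene-body structures.

Merged windows are grid-aligned and only say *where* a novel transcript
lives; this module refines the boundaries from pooled coverage, extracts
splice junctions from gapped (CIGAR N) alignments, infers the strand from
splice-site dinucleotides, assembles an exon chain, and exposes the spliced
sequence that the scoring module consumes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .genome_io import (
    AnnotationSet,
    Genome,
    GenomicInterval,
    SampleAlignment,
    reverse_complement,
)

MIN_INTRON = 30  # shorter skips are treated as deletions, not introns
DEFAULT_MIN_RPM = 0.5
DEFAULT_MAX_GAP = 50
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MAX_EXTENSION = 10_000

# CoverageAccessor(chrom, start, end) -> pooled mean per-base RPM array
CoverageAccessor = Callable[[str, int, int], np.ndarray]


@dataclass(frozen=True)
class SpliceJunction:
    """An intron evidenced by spliced reads.

    ``donor_end`` is one past the last exonic base before the intron (i.e.
    the intron start) and ``acceptor_start`` is the first exonic base after
    it (the intron end), both 0-based half-open.  ``motif`` holds the first
    two and last two intron bases (``GTAG`` for a canonical plus-strand
    intron, ``CTAC`` for its minus-strand counterpart).
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    support: int
    motif: str = ""

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("donor_end must precede acceptor_start")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class TranscriptCandidate:
    """One representative transcript model for a candidate region."""

    id: str
    chrom: str
    exons: list[GenomicInterval]
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("candidate needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons must be non-overlapping")

    @property
    def n_ex(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Transcript start coordinate (genomic end for minus strand)."""
        return self.start if self.strand != "-" else self.end

    @property
    def end3(self) -> int:
        """3'-end coordinate (genomic start for minus strand)."""
        return self.end if self.strand != "-" else self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def extend_boundaries(
    region: GenomicInterval,
    coverage: CoverageAccessor,
    min_rpm: float = DEFAULT_MIN_RPM,
    max_gap: int = DEFAULT_MAX_GAP,
    annotation: AnnotationSet | None = None,
    chrom_length: int | None = None,
    max_extension: int = DEFAULT_MAX_EXTENSION,
) -> GenomicInterval | None:
    """Refine a merged region to the covered extent of its transcript.

    The boundary walk links bases with pooled mean RPM >= ``min_rpm``,
    tolerating runs of up to ``max_gap`` consecutive sub-threshold bases.
    It both *extends* outward past the merged windows (expression often
    continues beyond the last selected window) and *trims* inward (merged
    windows are step-aligned and overshoot the transcript ends).  The walk
    never crosses an annotated gene span or the chromosome ends; outward
    search is capped at ``max_extension`` bases per side.  Returns ``None``
    when no base inside the region reaches ``min_rpm``.
    """
    lo = max(0, region.start - max_extension)
    hi = region.end + max_extension
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if annotation is not None:
        for rec in annotation.query(GenomicInterval(region.chrom, lo, hi)):
            iv = rec.interval
            if iv.end <= region.start:
                lo = max(lo, iv.end)
            elif iv.start >= region.end:
                hi = min(hi, iv.start)
    cov = np.asarray(coverage(region.chrom, lo, hi))
    covered = cov >= min_rpm
    inside = covered[region.start - lo : region.end - lo]
    if not inside.any():
        return None
    seed_left = region.start - lo + int(np.argmax(inside))
    seed_right = region.start - lo + len(inside) - 1 - int(np.argmax(inside[::-1]))

    left = seed_left
    gap = 0
    for pos in range(seed_left - 1, -1, -1):
        if covered[pos]:
            left = pos
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
    right = seed_right
    gap = 0
    for pos in range(seed_right + 1, len(covered)):
        if covered[pos]:
            right = pos
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
    return GenomicInterval(region.chrom, lo + left, lo + right + 1, region.strand)


def collect_junctions(
    samples: Iterable[SampleAlignment],
    region: GenomicInterval,
    genome: Genome,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_intron: int = MIN_INTRON,
) -> list[SpliceJunction]:
    """Splice junctions within the region, aggregated across samples.

    Junctions come from CIGAR skipped-region (N) operations of at least
    ``min_intron`` bases; shorter skips are ignored as deletions.  Support
    below ``min_support`` is discarded.  The 4-mer splice motif (first two
    plus last two intron bases) is read from the genome.
    """
    support: Counter[tuple[int, int]] = Counter()
    for sample in samples:
        for read in sample.fetch(region):
            ref = read.reference_start
            for op, length in read.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    ref += length
                elif op == 2:  # D
                    ref += length
                elif op == 3:  # N
                    if length >= min_intron:
                        support[(ref, ref + length)] += 1
                    ref += length
    out = []
    for (donor_end, acceptor_start), n in sorted(support.items()):
        if n < min_support:
            continue
        if donor_end <= region.start or acceptor_start >= region.end:
            continue
        motif = genome.fetch(region.chrom, donor_end, donor_end + 2, clip=True) + genome.fetch(
            region.chrom, acceptor_start - 2, acceptor_start, clip=True
        )
        out.append(
            SpliceJunction(region.chrom, donor_end, acceptor_start, n, motif)
        )
    return out


def infer_strand(junctions: Sequence[SpliceJunction]) -> str:
    """Majority vote over canonical splice motifs: GT..AG -> '+', CT..AC -> '-'.

    No junctions, no canonical motifs, or a tie yields ``'.'`` (unknown);
    such candidates are later scored on both strands and the better total
    kept.
    """
    plus = sum(1 for j in junctions if j.motif == "GTAG")
    minus = sum(1 for j in junctions if j.motif == "CTAC")
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return "."


def assemble_exons(
    region: GenomicInterval,
    junctions: Sequence[SpliceJunction],
    strand: str = ".",
    candidate_id: str = "candidate",
) -> TranscriptCandidate:
    """Build one exon chain from the region boundaries and its junctions.

    Exon boundaries are the region ends plus the donor/acceptor coordinates
    of the accepted junctions.  Overlapping (mutually exclusive) junctions
    are resolved greedily by support, highest first; accepted introns must
    leave a nonempty exon between and around them.  With no junctions the
    candidate is a single exon spanning the region.
    """
    for j in junctions:
        if j.donor_end <= region.start or j.acceptor_start >= region.end:
            raise ValueError(
                f"junction {j.donor_end}-{j.acceptor_start} outside region "
                f"{region.start}-{region.end}"
            )
    accepted: list[SpliceJunction] = []
    for j in sorted(junctions, key=lambda j: (-j.support, j.donor_end)):
        ok = all(
            j.acceptor_start < a.donor_end or j.donor_end > a.acceptor_start
            for a in accepted
        )
        if ok:
            accepted.append(j)
    accepted.sort(key=lambda j: j.donor_end)
    exons = []
    cursor = region.start
    for j in accepted:
        exons.append(GenomicInterval(region.chrom, cursor, j.donor_end, strand))
        cursor = j.acceptor_start
    exons.append(GenomicInterval(region.chrom, cursor, region.end, strand))
    return TranscriptCandidate(candidate_id, region.chrom, exons, strand)


def spliced_sequence(
    candidate: TranscriptCandidate, genome: Genome, strand: str | None = None
) -> str:
    """Concatenated exon sequence in transcript (5'->3') order.

    Minus-strand candidates are reverse-complemented.  ``strand`` overrides
    the candidate's own strand (used when scoring both orientations of an
    unstranded candidate).
    """
    strand = candidate.strand if strand is None else strand
    chrom_len = len(genome[candidate.chrom])
    for exon in candidate.exons:
        if exon.end > chrom_len:
            raise ValueError(
                f"exon {exon.chrom}:{exon.start}-{exon.end} outside chromosome "
                f"(length {chrom_len})"
            )
    seq = "".join(genome.fetch(candidate.chrom, e.start, e.end) for e in candidate.exons)
    return reverse_complement(seq) if strand == "-" else seq


def valid_junction_count(
    candidate: TranscriptCandidate,
    junctions: Sequence[SpliceJunction],
    strand: str | None = None,
) -> int:
    """Number of exons whose internal boundaries all have canonical junctions.

    An internal boundary is an exon end that is not a transcript end.  A
    boundary is supported when a junction's donor/acceptor coincides with it
    and the junction motif is canonical in transcript orientation (GT..AG on
    '+', genomic CT..AC on '-').  Single-exon candidates have no junctions
    and score 0.
    """
    strand = candidate.strand if strand is None else strand
    if candidate.n_ex == 1:
        return 0
    canonical = "CTAC" if strand == "-" else "GTAG"
    donors = {j.donor_end for j in junctions if j.motif == canonical}
    acceptors = {j.acceptor_start for j in junctions if j.motif == canonical}
    n_valid = 0
    for i, exon in enumerate(candidate.exons):
        checks = []
        if i > 0:
            checks.append(exon.start in acceptors)
        if i < candidate.n_ex - 1:
            checks.append(exon.end in donors)
        if checks and all(checks):
            n_valid += 1
    return n_valid
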