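"""Gene-body scoring of candidate transcripts.

A candidate is scored on four feature groups, each in [0, 1]:

* promoter: GC enrichment around the TSS, Chargaff second-rule violation
  (G+T skew), and presence of a core promoter motif (TATA box, Initiator,
  or DPE) in its expected positional window;
* 3'UTR: a poly(A) signal (AATAAA, perfect or single-mismatch) near the 3'
  end followed by a T-rich stretch of up to 80 bp;
* ORF: the longest ATG..stop open reading frame, rated by the fraction of
  exons it spans and a bonus when it reaches the last exon;
* exon structure: the fraction of exons whose boundaries are supported by
  canonical splice junctions.

The four group scores are summed into a total in [0, 4], which ranks the
candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import Genome, GenomicInterval, reverse_complement
from .structure_builder import (
    SpliceJunction,
    TranscriptCandidate,
    spliced_sequence,
    valid_junction_count,
)

# Promoter window relative to the TSS, on the sense strand.
PROMOTER_UPSTREAM = 200
PROMOTER_DOWNSTREAM = 50
TSS_CONTEXT_FLANK = 40

# Core promoter motif consensi and the positional windows (motif start
# offset relative to the TSS) where a perfect match counts.
TATA_MOTIF = "TATAAA"
TATA_WINDOW = (-33, -23)
INR_MOTIF = "YYANWYY"  # must overlap the TSS
DPE_MOTIF = "RGWYV"
DPE_WINDOW = (21, 35)  # +28 +/- 7

POLYA_MOTIF = "AATAAA"
POLYA_TAIL = 50  # transcript tail searched for the poly(A) signal
POLYA_DOWNSTREAM = 20  # extra downstream genomic bases in the search window
TRICH_SPAN = 80  # T-rich window downstream of the poly(A) hit

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ScoreCard:
    """All sub-scores of one candidate plus their total (the ranking key)."""

    s_gc: float
    s_charg: float
    s_motif: float
    s_prom: float
    s_polya: float
    s_trich: float
    s_3utr: float
    s_orf: float
    s_ex: float
    total: float

    @classmethod
    def from_components(
        cls,
        s_gc: float,
        s_charg: float,
        s_motif: float,
        s_polya: float,
        s_trich: float,
        s_orf: float,
        s_ex: float,
    ) -> "ScoreCard":
        s_prom = score_promoter(s_motif, s_gc, s_charg)
        s_3utr = score_3utr(s_polya, s_trich)
        return cls(
            s_gc=s_gc,
            s_charg=s_charg,
            s_motif=s_motif,
            s_prom=s_prom,
            s_polya=s_polya,
            s_trich=s_trich,
            s_3utr=s_3utr,
            s_orf=s_orf,
            s_ex=s_ex,
            total=s_prom + s_3utr + s_orf + s_ex,
        )


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame of a spliced sequence.

    ``start``/``end`` are spliced-transcript coordinates (half-open,
    including the stop codon); ``n_orf`` counts exons the ORF touches.
    """

    start: int
    end: int
    n_orf: int
    includes_last_exon: bool

    @property
    def p(self) -> float:
        return 0.5 if self.includes_last_exon else 0.0


@dataclass(frozen=True)
class PolyAHit:
    """Best poly(A)-signal hit in a 3'-end search window."""

    match_class: str  # 'perfect' | 'near_perfect' | 'none'
    position: int = -1  # motif start within the search window; -1 when none


def _fraction(seq: str, bases: str) -> float | None:
    """Fraction of ``bases`` among non-N positions; None when all-N/empty."""
    informative = sum(1 for b in seq if b != "N")
    if informative == 0:
        return None
    hits = sum(1 for b in seq if b in bases)
    return hits / informative


def gc_piecewise(frac: float) -> float:
    """GC score as a function of the G+C fraction: 0 below 0.4, 1 above 0.55."""
    if frac < 0.4:
        return 0.0
    if frac > 0.55:
        return 1.0
    return min(1.0, (frac - 0.4) / 0.15)


def chargaff_piecewise(frac: float) -> float:
    """Chargaff-violation score as a function of the G+T fraction."""
    if frac < 0.5:
        return 0.0
    if frac > 0.6:
        return 1.0
    return min(1.0, (frac - 0.5) / 0.1)


def trich_piecewise(frac: float) -> float:
    """T-rich score as a function of the T fraction (square-root ramp)."""
    if frac < 0.3:
        return 0.0
    if frac > 0.4:
        return 1.0
    return min(1.0, math.sqrt((frac - 0.3) / 0.1))


def score_gc(promoter_seq: str) -> float:
    """Promoter GC-enrichment score.

    0 below 40% G+C, 1 above 55%, linear in between.  N bases are masked
    out; an all-N window scores 0 with a warning.
    """
    frac = _fraction(promoter_seq, "GC")
    if frac is None:
        warnings.warn("promoter window is empty or all-N; GC score undefined, using 0")
        return 0.0
    return gc_piecewise(frac)


def score_chargaff(promoter_seq: str) -> float:
    """Chargaff second-rule violation score on the promoter window.

    Measures single-strand G+T skew: 0 below 50%, 1 above 60%, linear in
    between.
    """
    frac = _fraction(promoter_seq, "GT")
    if frac is None:
        warnings.warn("promoter window is empty or all-N; Chargaff score undefined, using 0")
        return 0.0
    return chargaff_piecewise(frac)


def iupac_match(seq: str, pattern: str, pos: int) -> bool:
    """Does ``pattern`` (IUPAC codes) match ``seq`` starting at ``pos``?

    N in the *sequence* is a hard mask and matches nothing.
    """
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for offset, code in enumerate(pattern):
        base = seq[pos + offset]
        if base == "N" or base not in IUPAC[code]:
            return False
    return True


def find_motif_hits(tss_context: str, tss_offset: int) -> list[tuple[str, int]]:
    """Perfect core-promoter motif hits within their positional windows.

    Returns ``(motif_name, start_offset_relative_to_TSS)`` pairs for TATA
    (window -33..-23), Initiator (overlapping the TSS) and DPE (+21..+35).
    """
    hits: list[tuple[str, int]] = []
    for rel in range(TATA_WINDOW[0], TATA_WINDOW[1] + 1):
        if iupac_match(tss_context, TATA_MOTIF, tss_offset + rel):
            hits.append(("TATA", rel))
    for rel in range(-len(INR_MOTIF) + 1, 1):
        if iupac_match(tss_context, INR_MOTIF, tss_offset + rel):
            hits.append(("Inr", rel))
    for rel in range(DPE_WINDOW[0], DPE_WINDOW[1] + 1):
        if iupac_match(tss_context, DPE_MOTIF, tss_offset + rel):
            hits.append(("DPE", rel))
    return hits


def score_motif(tss_context: str, tss_offset: int) -> float:
    """1 when any core promoter motif has a perfect in-window match, else 0."""
    return 1.0 if find_motif_hits(tss_context, tss_offset) else 0.0


def score_promoter(s_motif: float, s_gc: float, s_charg: float) -> float:
    """Total promoter score: mean of motif, GC and Chargaff sub-scores."""
    return (s_motif + s_gc + s_charg) / 3.0


def find_polya(end3_seq: str, motif: str = POLYA_MOTIF) -> PolyAHit:
    """Best poly(A)-signal hit in a 3'-end search window.

    The leftmost exact occurrence wins; failing that, the leftmost
    single-mismatch (near-perfect) occurrence; otherwise no hit.
    """
    best_near = -1
    for pos in range(len(end3_seq) - len(motif) + 1):
        window = end3_seq[pos : pos + len(motif)]
        mismatches = sum(1 for a, b in zip(window, motif) if a != b)
        if mismatches == 0:
            return PolyAHit("perfect", pos)
        if mismatches == 1 and best_near < 0:
            best_near = pos
    if best_near >= 0:
        return PolyAHit("near_perfect", best_near)
    return PolyAHit("none")


def score_polya(hit: PolyAHit) -> float:
    """1 for a perfect poly(A) signal, 0.5 for a single mismatch, else 0."""
    return {"perfect": 1.0, "near_perfect": 0.5, "none": 0.0}[hit.match_class]


def score_trich(downstream_seq: str) -> float:
    """T-richness downstream of the poly(A) site.

    0 below 30% T, 1 above 40%, ``sqrt((%T - 0.3) / 0.1)`` in between.  An
    empty window (no poly(A) hit) scores 0.
    """
    frac = _fraction(downstream_seq, "T")
    if frac is None:
        return 0.0
    return trich_piecewise(frac)


def score_3utr(s_polya: float, s_trich: float) -> float:
    """Total 3'UTR score: mean of poly(A) and T-rich sub-scores."""
    return (s_polya + s_trich) / 2.0


def find_longest_orf(spliced: str, exon_lengths: Sequence[int]) -> OrfResult:
    """Longest ATG..stop ORF over the three forward frames.

    The ORF span (stop codon included) is mapped back onto the exon chain
    (``exon_lengths`` in transcript order) to count the exons it spans and
    whether the last exon is included.  Ties go to the leftmost start; with
    no ORF, ``n_orf`` is 0.
    """
    best: tuple[int, int] | None = None  # (start, end)
    n = len(spliced)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = spliced[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if best is None or length > best[1] - best[0] or (
                    length == best[1] - best[0] and open_start < best[0]
                ):
                    best = (open_start, pos + 3)
                open_start = None
    if best is None:
        return OrfResult(start=0, end=0, n_orf=0, includes_last_exon=False)
    start, end = best
    bounds = []
    acc = 0
    for length in exon_lengths:
        bounds.append((acc, acc + length))
        acc += length
    touched = [i for i, (s, e) in enumerate(bounds) if s < end and start < e]
    return OrfResult(
        start=start,
        end=end,
        n_orf=len(touched),
        includes_last_exon=bool(touched) and touched[-1] == len(bounds) - 1,
    )


def score_orf(n_orf: int, n_ex: int, p: float) -> float:
    """ORF score ``(sqrt(n_orf / n_ex) + p) / 1.5``; 0 when there is no ORF."""
    if n_orf > n_ex:
        raise ValueError(f"n_orf ({n_orf}) cannot exceed n_ex ({n_ex})")
    if n_orf == 0:
        return 0.0
    return (math.sqrt(n_orf / n_ex) + p) / 1.5


def score_exons(n_valid: int, n_ex: int) -> float:
    """Exon-structure score: 0 for single-exon models, else ``n_valid / n_ex``."""
    if n_valid > n_ex:
        raise ValueError(f"n_valid ({n_valid}) cannot exceed n_ex ({n_ex})")
    if n_ex == 1:
        return 0.0
    return n_valid / n_ex


def total_score(card: ScoreCard) -> float:
    """Sum of the four group scores (ranking key, in [0, 4])."""
    return card.s_prom + card.s_3utr + card.s_orf + card.s_ex


# ---------------------------------------------------------------------------
# Candidate-level scoring


@dataclass
class ScoredCandidate:
    candidate: TranscriptCandidate
    card: ScoreCard
    strand: str
    mean_rpm: float = 0.0
    strand_assumed: bool = False

    @property
    def total(self) -> float:
        return self.card.total


def _sense_window(
    genome: Genome, chrom: str, tss: int, strand: str, upstream: int, downstream: int
) -> tuple[str, int]:
    """Sense-strand sequence of [TSS - upstream, TSS + downstream).

    Returns the sequence and the index of the TSS within it (accounting for
    clipping at chromosome ends).
    """
    if strand == "-":
        # sense position p maps to genomic tss - 1 - p
        raw = genome.fetch(chrom, tss - downstream, tss + upstream, clip=True)
        seq = reverse_complement(raw)
        clipped_up = max(0, (tss + upstream) - len(genome[chrom]))
        offset = upstream - clipped_up
    else:
        seq = genome.fetch(chrom, tss - upstream, tss + downstream, clip=True)
        offset = upstream - max(0, upstream - tss)
    return seq, offset


def _downstream_of_end3(genome: Genome, chrom: str, end3: int, strand: str, n: int) -> str:
    """``n`` genomic bases downstream of the 3' end, in sense orientation."""
    if strand == "-":
        return reverse_complement(genome.fetch(chrom, end3 - n, end3, clip=True))
    return genome.fetch(chrom, end3, end3 + n, clip=True)


def _score_oriented(
    candidate: TranscriptCandidate,
    genome: Genome,
    junctions: Sequence[SpliceJunction],
    strand: str,
) -> ScoreCard:
    tss = candidate.start if strand != "-" else candidate.end
    end3 = candidate.end if strand != "-" else candidate.start

    prom_seq, _ = _sense_window(
        genome, candidate.chrom, tss, strand, PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM
    )
    ctx_seq, ctx_off = _sense_window(
        genome, candidate.chrom, tss, strand, TSS_CONTEXT_FLANK, TSS_CONTEXT_FLANK + 1
    )
    s_gc = score_gc(prom_seq)
    s_charg = score_chargaff(prom_seq)
    s_motif = score_motif(ctx_seq, ctx_off)

    spliced = spliced_sequence(candidate, genome, strand=strand)
    tail = spliced[-POLYA_TAIL:]
    downstream = _downstream_of_end3(
        genome, candidate.chrom, end3, strand, POLYA_DOWNSTREAM + TRICH_SPAN
    )
    search = tail + downstream[:POLYA_DOWNSTREAM]
    hit = find_polya(search)
    s_polya = score_polya(hit)
    if hit.match_class == "none":
        s_trich = 0.0
    else:
        extended = tail + downstream
        trich_seq = extended[hit.position + len(POLYA_MOTIF) :][:TRICH_SPAN]
        s_trich = score_trich(trich_seq)

    exon_lengths = [len(e) for e in candidate.exons]
    if strand == "-":
        exon_lengths = exon_lengths[::-1]
    orf = find_longest_orf(spliced, exon_lengths) if len(spliced) >= 3 else OrfResult(0, 0, 0, False)
    s_orf = score_orf(orf.n_orf, candidate.n_ex, orf.p)

    n_valid = valid_junction_count(candidate, junctions, strand=strand)
    s_ex = score_exons(n_valid, candidate.n_ex)

    return ScoreCard.from_components(s_gc, s_charg, s_motif, s_polya, s_trich, s_orf, s_ex)


def score_candidate(
    candidate: TranscriptCandidate,
    genome: Genome,
    junctions: Sequence[SpliceJunction] = (),
    mean_rpm: float = 0.0,
) -> ScoredCandidate:
    """Full score card for one candidate.

    Unstranded candidates are scored in both orientations and the higher
    total is kept (flagged via ``strand_assumed``); ties keep '+'.
    """
    if candidate.strand in ("+", "-"):
        card = _score_oriented(candidate, genome, junctions, candidate.strand)
        return ScoredCandidate(candidate, card, candidate.strand, mean_rpm)
    plus = _score_oriented(candidate, genome, junctions, "+")
    minus = _score_oriented(candidate, genome, junctions, "-")
    if minus.total > plus.total:
        return ScoredCandidate(candidate, minus, "-", mean_rpm, strand_assumed=True)
    return ScoredCandidate(candidate, plus, "+", mean_rpm, strand_assumed=True)


def rank_candidates(scored: Iterable[ScoredCandidate]) -> list[ScoredCandidate]:
    """Descending by total; ties by mean cohort RPM (desc) then coordinate."""
    return sorted(
        scored,
        key=lambda s: (
            -s.card.total,
            -s.mean_rpm,
            s.candidate.chrom,
            s.candidate.start,
        ),
    )


def scores_to_frame(ranked: Sequence[ScoredCandidate]) -> pd.DataFrame:
    rows = []
    for rank, s in enumerate(ranked, start=1):
        c = s.candidate
        rows.append(
            {
                "rank": rank,
                "id": c.id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": s.strand,
                "strand_assumed": s.strand_assumed,
                "n_ex": c.n_ex,
                "mean_rpm": s.mean_rpm,
                "s_gc": s.card.s_gc,
                "s_charg": s.card.s_charg,
                "s_motif": s.card.s_motif,
                "s_prom": s.card.s_prom,
                "s_polya": s.card.s_polya,
                "s_trich": s.card.s_trich,
                "s_3utr": s.card.s_3utr,
                "s_orf": s.card.s_orf,
                "s_ex": s.card.s_ex,
                "total": s.card.total,
            }
        )
    return pd.DataFrame(rows)


def write_scores(ranked: Sequence[ScoredCandidate], path: str | Path) -> None:
    scores_to_frame(ranked).to_csv(path, sep="\t", index=False, float_format="%.6g")
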