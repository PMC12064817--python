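"""Self-contained synthetic test cohorts.

Emulates the input the discovery pipeline consumes: a small genome with a
handful of annotated decoy genes plus planted intergenic transcripts whose
expression is high in a minority of samples (so the top-20%-vs-median
outlier rule fires) and whose sequence realizes controllable gene-body
features: promoter composition and motifs, canonical GT..AG introns, an
ORF, a poly(A) signal and a T-rich tail.  Reads are simulated error-free at
fixed length; per-sample alignments are written as sorted, indexed BAM or,
alternatively, as bedGraph coverage.

Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
import yaml

from . import scoring
from .genome_io import (
    AnnotationRecord,
    AnnotationSet,
    Genome,
    GenomicInterval,
    SampleAlignment,
    SampleCoverage,
    reverse_complement,
    write_bedgraph,
    write_genome,
)
from .structure_builder import SpliceJunction, TranscriptCandidate

PLANT_FLANK = 250  # genomic bases rewritten on each side of a plant
PLANT_BUFFER = 300  # background-read exclusion zone around plants

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class PlantSpec:
    """One planted intergenic transcript and its realized features."""

    plant_id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    promoter_gc: float = 0.5  # target G+C fraction of the promoter window
    promoter_gt: float = 0.5  # target G+T fraction (Chargaff violation)
    motif: str | None = None  # 'tata' or None
    polya: str | None = None  # 'perfect' | 'near' | None
    trich_t: float = 0.5  # T fraction downstream of the poly(A) site
    orf: bool = False
    expressed_in: tuple[int, ...] = (0, 1)
    depth: float = 10.0

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1], self.strand)

    @property
    def exon_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, a, b, self.strand) for a, b in self.exons]


@dataclass(frozen=True)
class DecoySpec:
    """An annotated gene with its own outlier expression (must be filtered)."""

    gene_id: str
    region: GenomicInterval
    expressed_in: tuple[int, ...] = ()
    depth: float = 10.0


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic cohort; the seed fully determines all outputs."""

    n_samples: int = 5
    chrom: str = "chr1"
    genome_length: int = 50_000
    n_decoy_genes: int = 2
    n_plants: int = 2
    background_reads: int = 200
    read_length: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_samples < 5:
            raise ValueError("need >= 5 samples for the quintile selection rule")


@dataclass
class PlantTruth:
    """Expected structure and scores of one plant, from the planted sequence."""

    plant: PlantSpec
    candidate: TranscriptCandidate
    junctions: list[SpliceJunction]
    card: scoring.ScoreCard


@dataclass
class CohortResult:
    spec: CohortSpec
    genome: Genome
    annotation: AnnotationSet
    truths: list[PlantTruth]
    decoys: list[DecoySpec]
    samples: list
    outdir: Path
    paths: dict[str, Path]


def default_plants(spec: CohortSpec) -> list[PlantSpec]:
    """The two stock plants: one full-featured '+', one sparse '-'.

    Plant 1 carries every scorable feature (TATA box, GC-rich skewed
    promoter, three canonical-junction exons, an ORF spanning all exons
    including the last, a perfect poly(A) signal and a T-rich tail), so its
    expected total is 4.0.  Plant 2 is a two-exon minus-strand transcript
    with a low-GC promoter, no promoter motif, a near-perfect poly(A)
    signal and no designed ORF.
    """
    plants = [
        PlantSpec(
            plant_id="plant_full",
            chrom=spec.chrom,
            exons=((15_000, 15_400), (15_500, 15_800), (15_900, 16_250)),
            strand="+",
            promoter_gc=0.60,
            promoter_gt=0.65,
            motif="tata",
            polya="perfect",
            trich_t=0.50,
            orf=True,
            expressed_in=(0, 1),
        ),
        PlantSpec(
            plant_id="plant_sparse",
            chrom=spec.chrom,
            exons=((25_000, 25_300), (25_400, 25_700)),
            strand="-",
            promoter_gc=0.35,
            promoter_gt=0.45,
            motif=None,
            polya="near",
            trich_t=0.25,
            orf=False,
            expressed_in=(1, 2),
        ),
    ]
    return plants[: spec.n_plants]


def default_decoys(spec: CohortSpec) -> list[DecoySpec]:
    regions = [(5_000, 8_000), (40_000, 43_000), (33_000, 35_000)]
    out = []
    for i in range(spec.n_decoy_genes):
        start, end = regions[i % len(regions)]
        expressed = tuple(
            s % spec.n_samples for s in range(2 + i, 4 + i)
        )
        out.append(
            DecoySpec(
                gene_id=f"decoy_{i}",
                region=GenomicInterval(spec.chrom, start, end, "+"),
                expressed_in=expressed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sequence construction helpers


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def seq_with_counts(rng: np.random.Generator, counts: Mapping[str, int]) -> str:
    """Random-order sequence with an exact per-base count."""
    chars = np.array(
        [b for base, k in sorted(counts.items()) for b in base * k]
    )
    rng.shuffle(chars)
    return "".join(chars)


def seq_with_composition(
    rng: np.random.Generator, n: int, fractions: Mapping[str, float]
) -> str:
    """Random-order sequence of length ``n`` realizing exact base fractions.

    Counts come from largest-remainder rounding, so the realized fraction of
    each base is within 1/n of its target.
    """
    items = sorted(fractions.items())
    raw = [n * f for _, f in items]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(items)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return seq_with_counts(rng, {base: c for (base, _), c in zip(items, counts)})


def _promoter_composition(gc: float, gt: float) -> dict[str, float]:
    # one consistent split of A/C/G/T fractions given the G+C and G+T targets
    g = gc * gt
    c = gc - g
    t = gt - g
    a = 1.0 - g - c - t
    if min(g, c, t, a) < 0:
        raise ValueError(f"infeasible promoter composition gc={gc}, gt={gt}")
    return {"A": a, "C": c, "G": g, "T": t}


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in scoring.STOP_CODONS
]


def _scrub_promoter_motifs(window: list[str], tss_index: int, max_iter: int = 80) -> None:
    """Mutate ``window`` in place until no core promoter motif matches."""
    for _ in range(max_iter):
        hits = scoring.find_motif_hits("".join(window), tss_index)
        if not hits:
            return
        name, rel = hits[0]
        pattern = {"TATA": scoring.TATA_MOTIF, "Inr": scoring.INR_MOTIF, "DPE": scoring.DPE_MOTIF}[name]
        # break the match at its most constrained position
        idx = tss_index + rel
        for offset, code in enumerate(pattern):
            options = [b for b in "ACGT" if b not in scoring.IUPAC[code]]
            if options:
                window[idx + offset] = options[0]
                break
    raise RuntimeError("could not scrub promoter motifs")


def _polya_distance(seq: str, pos: int) -> int:
    motif = scoring.POLYA_MOTIF
    return sum(1 for a, b in zip(seq[pos : pos + len(motif)], motif) if a != b)


def _fixup_polya(
    getters: tuple,
    intended: str,
    planted_pos: int | None,
    max_iter: int = 200,
) -> None:
    """Mutate the poly(A) search window until the intended hit is leftmost.

    ``getters`` is ``(read_search, write_at)`` mapping search-window indices
    onto the underlying sequence buffers.  Mutations only touch positions
    that currently match an 'A' of the motif (so the T count of an
    overlapping T-rich window is preserved) and never touch the planted
    motif itself.
    """
    read_search, write_at = getters
    for _ in range(max_iter):
        search = read_search()
        hit = scoring.find_polya(search)
        ok = (
            (intended == "none" and hit.match_class == "none")
            or (intended == "perfect" and hit.match_class == "perfect" and hit.position == planted_pos)
            or (intended == "near" and hit.match_class == "near_perfect" and hit.position == planted_pos)
        )
        if ok:
            return
        pos = hit.position
        mutated = False
        for offset, code in enumerate(scoring.POLYA_MOTIF):
            idx = pos + offset
            if planted_pos is not None and planted_pos <= idx < planted_pos + len(scoring.POLYA_MOTIF):
                continue
            if code == "A" and search[idx] == "A":
                write_at(idx, "C")
                mutated = True
                break
        if not mutated:
            # fall back: break any non-planted position of the hit
            for offset in range(len(scoring.POLYA_MOTIF)):
                idx = pos + offset
                if planted_pos is not None and planted_pos <= idx < planted_pos + len(scoring.POLYA_MOTIF):
                    continue
                write_at(idx, "C" if search[idx] != "C" else "G")
                mutated = True
                break
        if not mutated:
            raise RuntimeError("poly(A) fix-up stuck inside planted motif")
    raise RuntimeError("could not realize the intended poly(A) hit")


# ---------------------------------------------------------------------------
# Genome generation and planting


def generate_genome(
    spec: CohortSpec, decoys: Sequence[DecoySpec] | None = None
) -> tuple[dict[str, str], AnnotationSet, list[DecoySpec]]:
    """Random genome plus decoy-gene annotation, deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    seqs = {spec.chrom: random_seq(rng, spec.genome_length)}
    if decoys is None:
        decoys = default_decoys(spec)
    for d in decoys:
        if d.region.end > spec.genome_length:
            raise ValueError(f"decoy {d.gene_id} does not fit the genome")
    annotation = AnnotationSet(
        AnnotationRecord(d.region, d.gene_id, "synthetic") for d in decoys
    )
    return seqs, annotation, list(decoys)


def plant_transcripts(
    seqs: Mapping[str, str],
    plants: Sequence[PlantSpec],
    annotation: AnnotationSet,
    seed: int,
) -> tuple[Genome, list[PlantTruth]]:
    """Rewrite the genome so every plant realizes its declared features.

    Returns the edited genome and a truth table holding, per plant, the
    expected transcript model, its junctions, and the score card computed
    from the planted sequence.
    """
    rng = np.random.default_rng(seed + 1)
    spans = [p.span for p in plants]
    for i, p in enumerate(plants):
        if annotation.overlaps(p.span):
            raise ValueError(f"plant {p.plant_id} declared intergenic but overlaps annotation")
        for q in spans[:i]:
            if p.span.overlaps(q):
                raise ValueError(f"plant {p.plant_id} overlaps another plant")
    chrom_chars = {c: list(s) for c, s in seqs.items()}
    for plant in plants:
        _plant_one(chrom_chars[plant.chrom], plant, rng)
    genome = Genome({c: "".join(chars) for c, chars in chrom_chars.items()})
    truths = [_truth_for(genome, plant) for plant in plants]
    return genome, truths


def _plant_one(chars: list[str], plant: PlantSpec, rng: np.random.Generator) -> None:
    span = plant.span
    if span.start < PLANT_FLANK or span.end + PLANT_FLANK > len(chars):
        raise ValueError(f"plant {plant.plant_id} too close to a chromosome end")
    lo, hi = span.start - PLANT_FLANK, span.end + PLANT_FLANK
    local = chars[lo:hi]
    if plant.strand == "-":
        local = list(reverse_complement("".join(local)))
        m = hi - lo
        exons_local = sorted(
            (m - (b - lo), m - (a - lo)) for a, b in plant.exons
        )
    else:
        exons_local = [(a - lo, b - lo) for a, b in plant.exons]

    tss = exons_local[0][0]
    end3 = exons_local[-1][1]
    up, down = scoring.PROMOTER_UPSTREAM, scoring.PROMOTER_DOWNSTREAM

    # promoter window [TSS-200, TSS+50) with the target composition
    window = list(
        seq_with_composition(
            rng, up + down, _promoter_composition(plant.promoter_gc, plant.promoter_gt)
        )
    )
    if plant.motif == "tata":
        window[up - 28 : up - 22] = list(scoring.TATA_MOTIF)
    elif plant.motif is None:
        # context used by the motif score is [TSS-40, TSS+40]
        ctx_lo = up - scoring.TSS_CONTEXT_FLANK
        ctx = window[ctx_lo : up + scoring.TSS_CONTEXT_FLANK + 1]
        _scrub_promoter_motifs(ctx, scoring.TSS_CONTEXT_FLANK)
        window[ctx_lo : up + scoring.TSS_CONTEXT_FLANK + 1] = ctx
    local[tss - up : tss + down] = window

    # spliced transcript body; first `down` bases shared with the window
    length = sum(b - a for a, b in exons_local)
    spliced = list(random_seq(rng, length))
    spliced[:down] = window[up:]
    if plant.orf:
        atg = down + 10
        stop_end = length - 54
        stop_end -= (stop_end - atg) % 3
        spliced[atg : atg + 3] = list("ATG")
        body = rng.choice(_NON_STOP_CODONS, size=(stop_end - 3 - (atg + 3)) // 3)
        spliced[atg + 3 : stop_end - 3] = list("".join(body))
        spliced[stop_end - 3 : stop_end] = list("TGA")

    # 3' end: poly(A) signal in the transcript tail, T-rich stretch after it
    tail_n = scoring.POLYA_TAIL
    planted_pos = tail_n - 21 if plant.polya else None
    down_n = scoring.POLYA_DOWNSTREAM + scoring.TRICH_SPAN
    downstream = list(random_seq(rng, down_n))
    if plant.polya:
        motif = scoring.POLYA_MOTIF if plant.polya == "perfect" else "AATAAG"
        spliced[length - 21 : length - 15] = list(motif)
        trich = list(
            seq_with_composition(
                rng,
                scoring.TRICH_SPAN,
                {
                    "T": plant.trich_t,
                    "A": (1 - plant.trich_t) / 3,
                    "C": (1 - plant.trich_t) / 3,
                    "G": (1 - plant.trich_t) / 3,
                },
            )
        )
        spliced[length - 15 :] = trich[:15]
        downstream[: scoring.TRICH_SPAN - 15] = trich[15:]

    def read_search() -> str:
        return "".join(spliced[length - tail_n :]) + "".join(
            downstream[: scoring.POLYA_DOWNSTREAM]
        )

    def write_at(idx: int, base: str) -> None:
        if idx < tail_n:
            spliced[length - tail_n + idx] = base
        else:
            downstream[idx - tail_n] = base

    _fixup_polya((read_search, write_at), plant.polya or "none", planted_pos)

    # write exons, canonical introns, and the downstream block back
    offset = 0
    for a, b in exons_local:
        local[a:b] = spliced[offset : offset + (b - a)]
        offset += b - a
    for (_, a_end), (b_start, _) in zip(exons_local, exons_local[1:]):
        intron = ["G", "T"] + list(random_seq(rng, b_start - a_end - 4)) + ["A", "G"]
        local[a_end:b_start] = intron
    local[end3 : end3 + down_n] = downstream

    if plant.strand == "-":
        local = list(reverse_complement("".join(local)))
    chars[lo:hi] = local


def _truth_for(genome: Genome, plant: PlantSpec) -> PlantTruth:
    candidate = TranscriptCandidate(
        plant.plant_id, plant.chrom, plant.exon_intervals, plant.strand
    )
    junctions = []
    for left, right in zip(candidate.exons, candidate.exons[1:]):
        motif = genome.fetch(plant.chrom, left.end, left.end + 2) + genome.fetch(
            plant.chrom, right.start - 2, right.start
        )
        junctions.append(
            SpliceJunction(plant.chrom, left.end, right.start, support=10, motif=motif)
        )
    scored = scoring.score_candidate(candidate, genome, junctions)
    return PlantTruth(plant, candidate, junctions, scored.card)


# ---------------------------------------------------------------------------
# Read simulation


def _spliced_read_blocks(
    exons: Sequence[tuple[int, int]], start: int, read_length: int
) -> list[tuple[int, int]]:
    """Genomic (start, end) blocks of a read at spliced position ``start``."""
    blocks = []
    offset = 0
    remaining = read_length
    for a, b in exons:
        exon_len = b - a
        if start < offset + exon_len and remaining > 0:
            s = max(start, offset)
            take = min(remaining, offset + exon_len - s)
            blocks.append((a + (s - offset), a + (s - offset) + take))
            remaining -= take
        offset += exon_len
        if remaining <= 0:
            break
    return blocks


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (a, b) in enumerate(blocks):
        if i > 0:
            parts.append(f"{a - blocks[i - 1][1]}N")
        parts.append(f"{b - a}M")
    return "".join(parts)


def _transcript_read_starts(length: int, read_length: int, depth: float) -> list[int]:
    if length <= read_length:
        return [0]
    step = max(1, round(read_length / depth))
    starts = set(range(0, length - read_length + 1, step))
    starts.add(length - read_length)
    return sorted(starts)


def simulate_cohort(
    genome: Genome,
    truths: Sequence[PlantTruth],
    decoys: Sequence[DecoySpec],
    spec: CohortSpec,
    outdir: str | Path,
    fmt: str = "bam",
) -> tuple[list, dict[str, Path]]:
    """Simulate per-sample alignments (BAM) or coverage (bedGraph).

    Background reads share identical positions in every sample and each
    sample is topped up with filler reads inside the first decoy gene so
    that all samples have the same mapped-read total: in RPM space the
    background is then exactly uniform across the cohort and only the
    planted transcripts (and decoy genes) show outlier structure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 2)
    R = spec.read_length
    chrom = spec.chrom
    chrom_len = len(genome[chrom])

    allowed = np.ones(chrom_len - R + 1, dtype=bool)
    for t in truths:
        span = t.plant.span
        zone_lo = max(0, span.start - PLANT_BUFFER - R + 1)
        zone_hi = min(len(allowed), span.end + PLANT_BUFFER)
        allowed[zone_lo:zone_hi] = False
    background = np.sort(
        rng.choice(np.flatnonzero(allowed), size=spec.background_reads, replace=True)
    )

    # (pos, cigar, seq) triples per read source
    def block_reads(blocks_list):
        reads = []
        for blocks in blocks_list:
            pos = blocks[0][0]
            cigar = _blocks_to_cigar(blocks)
            seq = "".join(genome.fetch(chrom, a, b) for a, b in blocks)
            reads.append((pos, cigar, seq))
        return reads

    bg_reads = block_reads([[(int(p), int(p) + R)] for p in background])
    plant_reads = {}
    for t in truths:
        exons = [(e.start, e.end) for e in t.candidate.exons]
        length = sum(b - a for a, b in exons)
        starts = _transcript_read_starts(length, R, t.plant.depth)
        plant_reads[t.plant.plant_id] = block_reads(
            [_spliced_read_blocks(exons, s, min(R, length)) for s in starts]
        )
    decoy_reads = {}
    for d in decoys:
        starts = [
            d.region.start + s
            for s in _transcript_read_starts(len(d.region), R, d.depth)
        ]
        decoy_reads[d.gene_id] = block_reads([[(s, s + R)] for s in starts])

    per_sample: list[list[tuple[int, str, str]]] = []
    for i in range(spec.n_samples):
        reads = list(bg_reads)
        for t in truths:
            if i in t.plant.expressed_in:
                reads.extend(plant_reads[t.plant.plant_id])
        for d in decoys:
            if i in d.expressed_in:
                reads.extend(decoy_reads[d.gene_id])
        per_sample.append(reads)

    if decoys:  # equalize mapped-read totals with filler inside a decoy gene
        target = max(len(r) for r in per_sample)
        filler = decoys[0].region
        span = len(filler) - R
        for i, reads in enumerate(per_sample):
            need = target - len(reads)
            fill_positions = [filler.start + (k * 37) % span for k in range(need)]
            reads.extend(block_reads([[(p, p + R)] for p in fill_positions]))

    paths: dict[str, Path] = {}
    samples = []
    mapped_rows = []
    for i, reads in enumerate(per_sample):
        sample_id = f"sample_{i}"
        reads.sort(key=lambda r: r[0])
        if fmt == "bam":
            path = outdir / f"{sample_id}.bam"
            _write_bam(reads, chrom, genome, path)
            samples.append(SampleAlignment(sample_id, path, mapped_reads=len(reads)))
        elif fmt == "bedgraph":
            path = outdir / f"{sample_id}.bedgraph"
            depth = {chrom: np.zeros(chrom_len)}
            for pos, cigar, _seq in reads:
                ref = pos
                num = ""
                for ch in cigar:
                    if ch.isdigit():
                        num += ch
                    else:
                        n = int(num)
                        num = ""
                        if ch == "M":
                            depth[chrom][ref : ref + n] += 1
                        ref += n
            write_bedgraph(depth, path)
            samples.append(
                SampleCoverage(sample_id, path, len(reads), genome.lengths)
            )
        else:
            raise ValueError(f"unknown output format {fmt!r}")
        paths[sample_id] = path
        mapped_rows.append((sample_id, len(reads), path.name))

    mapped_path = outdir / "mapped_reads.tsv"
    with open(mapped_path, "w") as fh:
        fh.write("sample_id\tmapped_reads\tfile\n")
        for sample_id, n, name in mapped_rows:
            fh.write(f"{sample_id}\t{n}\t{name}\n")
    paths["mapped_reads"] = mapped_path
    return samples, paths


def _write_bam(
    reads: Sequence[tuple[int, str, str]], chrom: str, genome: Genome, path: Path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in genome.lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        tid = out.get_tid(chrom)
        for i, (pos, cigar, seq) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read_{i}"
            a.flag = 0
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            out.write(a)
    pysam.index(str(path))


# ---------------------------------------------------------------------------
# Orchestration


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in annotation:
            iv = rec.interval
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(
                f"{iv.chrom}\t{rec.source or 'synthetic'}\tgene\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{strand}\t.\tgene_id \"{rec.gene_id}\";\n"
            )


def write_truth_table(truths: Sequence[PlantTruth], path: str | Path) -> None:
    cols = ["s_gc", "s_charg", "s_motif", "s_prom", "s_polya", "s_trich", "s_3utr", "s_orf", "s_ex", "total"]
    with open(path, "w") as fh:
        fh.write("plant_id\tchrom\tstart\tend\tstrand\tn_ex\t" + "\t".join(cols) + "\n")
        for t in truths:
            c = t.candidate
            vals = "\t".join(f"{getattr(t.card, col):.6g}" for col in cols)
            fh.write(f"{c.id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.n_ex}\t{vals}\n")


def generate_cohort(
    spec: CohortSpec,
    outdir: str | Path,
    fmt: str = "bam",
    plants: Sequence[PlantSpec] | None = None,
    decoys: Sequence[DecoySpec] | None = None,
) -> CohortResult:
    """Full cohort: genome + annotation + planted transcripts + alignments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs, annotation, decoys = generate_genome(spec, decoys)
    if plants is None:
        plants = default_plants(spec)
    genome, truths = plant_transcripts(seqs, plants, annotation, spec.seed)
    samples, paths = simulate_cohort(genome, truths, decoys, spec, outdir, fmt)

    paths["genome"] = outdir / "genome.fa"
    write_genome(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf(annotation, paths["annotation"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth_table(truths, paths["truth"])
    paths["spec"] = outdir / "cohort.yaml"
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump({"cohort": spec.__dict__, "format": fmt}, fh, sort_keys=True)

    return CohortResult(spec, genome, annotation, truths, list(decoys), samples, outdir, paths)


def fixture_small(outdir: str | Path, fmt: str = "bam", seed: int = 42) -> CohortResult:
    """The stock micro-cohort: 5 samples, 50 kb genome, 2 plants, 2 decoys."""
    return generate_cohort(CohortSpec(seed=seed), outdir, fmt=fmt)
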