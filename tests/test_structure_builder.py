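"""Boundary refinement, junction extraction, exon assembly, spliced sequence."""

import numpy as np
import pytest

from lncscout.genome_io import AnnotationSet, Genome, GenomicInterval, SampleAlignment
from lncscout.structure_builder import (
    SpliceJunction,
    TranscriptCandidate,
    assemble_exons,
    collect_junctions,
    extend_boundaries,
    infer_strand,
    spliced_sequence,
    valid_junction_count,
)

from conftest import make_bam


def track_accessor(track):
    track = np.asarray(track, dtype=float)

    def accessor(chrom, start, end):
        out = np.zeros(end - start)
        lo, hi = max(0, start), min(len(track), end)
        out[lo - start : hi - start] = track[lo:hi]
        return out

    return accessor


class TestExtendBoundaries:
    def test_extends_to_covered_span(self):
        track = np.zeros(2000)
        track[400:1100] = 1.0
        region = GenomicInterval("chr1", 500, 1000)
        out = extend_boundaries(region, track_accessor(track), chrom_length=2000)
        assert (out.start, out.end) == (400, 1100)

    def test_exactly_bounded_coverage_unchanged(self):
        track = np.zeros(2000)
        track[500:1000] = 1.0
        region = GenomicInterval("chr1", 500, 1000)
        out = extend_boundaries(region, track_accessor(track), chrom_length=2000)
        assert (out.start, out.end) == (500, 1000)

    def test_never_extends_into_annotated_gene(self):
        track = np.ones(3000)
        region = GenomicInterval("chr1", 500, 1000)
        ann = AnnotationSet.from_intervals([GenomicInterval("chr1", 1050, 2000)])
        out = extend_boundaries(
            region, track_accessor(track), annotation=ann, chrom_length=3000,
            max_extension=400,
        )
        assert out.end == 1050
        assert out.start == 100  # capped by max_extension on the open side

    def test_trims_overshooting_region_to_coverage(self):
        track = np.zeros(2000)
        track[600:900] = 2.0
        region = GenomicInterval("chr1", 250, 1250)  # step-aligned overshoot
        out = extend_boundaries(region, track_accessor(track), chrom_length=2000)
        assert (out.start, out.end) == (600, 900)

    def test_small_gaps_are_bridged_large_gaps_stop_the_walk(self):
        track = np.zeros(2000)
        track[500:600] = 1.0
        track[640:700] = 1.0  # 40-base gap < max_gap: bridged
        track[900:950] = 1.0  # 200-base gap > max_gap: separate
        region = GenomicInterval("chr1", 500, 620)
        out = extend_boundaries(region, track_accessor(track), chrom_length=2000)
        assert (out.start, out.end) == (500, 700)

    def test_uncovered_region_returns_none(self):
        region = GenomicInterval("chr1", 500, 1000)
        assert extend_boundaries(region, track_accessor(np.zeros(2000)), chrom_length=2000) is None


class TestJunctions:
    def _genome(self):
        seq = ["A"] * 1000
        seq[150:152] = "GT"  # canonical donor for intron [150, 250)
        seq[248:250] = "AG"
        return Genome({"chr1": "".join(seq)})

    def test_cigar_arithmetic(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(100, "50M100N50M", "A" * 100)] * 3)
        aln = SampleAlignment("s", bam)
        region = GenomicInterval("chr1", 0, 1000)
        (j,) = collect_junctions([aln], region, self._genome())
        assert (j.donor_end, j.acceptor_start) == (150, 250)
        assert j.support == 3
        assert j.motif == "GTAG"

    def test_support_threshold(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(100, "50M100N50M", "A" * 100)] * 2)
        aln = SampleAlignment("s", bam)
        region = GenomicInterval("chr1", 0, 1000)
        assert collect_junctions([aln], region, self._genome(), min_support=3) == []

    def test_support_aggregates_across_samples(self, tmp_path):
        alns = [
            SampleAlignment(f"s{i}", make_bam(tmp_path / f"{i}.bam", [(100, "50M100N50M", "A" * 100)]))
            for i in range(3)
        ]
        region = GenomicInterval("chr1", 0, 1000)
        (j,) = collect_junctions(alns, region, self._genome(), min_support=3)
        assert j.support == 3

    def test_short_skip_treated_as_deletion(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(100, "50M10N50M", "A" * 100)] * 5)
        aln = SampleAlignment("s", bam)
        region = GenomicInterval("chr1", 0, 1000)
        assert collect_junctions([aln], region, self._genome()) == []


class TestStrand:
    def test_canonical_motifs(self):
        j = lambda motif: SpliceJunction("chr1", 100, 200, 5, motif)
        assert infer_strand([j("GTAG"), j("GTAG")]) == "+"
        assert infer_strand([j("CTAC")]) == "-"
        assert infer_strand([]) == "."
        assert infer_strand([j("GTAG"), j("CTAC")]) == "."
        assert infer_strand([j("ATAC")]) == "."


class TestAssembly:
    def test_two_exon_construction(self):
        region = GenomicInterval("chr1", 400, 1100)
        j = SpliceJunction("chr1", 700, 900, 5, "GTAG")
        t = assemble_exons(region, [j], "+")
        assert [(e.start, e.end) for e in t.exons] == [(400, 700), (900, 1100)]
        assert t.n_ex == 2 and t.tss == 400 and t.end3 == 1100

    def test_no_junctions_single_exon(self):
        region = GenomicInterval("chr1", 400, 1100)
        t = assemble_exons(region, [])
        assert t.n_ex == 1
        assert (t.exons[0].start, t.exons[0].end) == (400, 1100)

    def test_two_compatible_junctions(self):
        region = GenomicInterval("chr1", 0, 1000)
        js = [
            SpliceJunction("chr1", 200, 300, 5, "GTAG"),
            SpliceJunction("chr1", 600, 700, 8, "GTAG"),
        ]
        t = assemble_exons(region, js, "+")
        assert [(e.start, e.end) for e in t.exons] == [(0, 200), (300, 600), (700, 1000)]

    def test_conflicting_junctions_resolved_by_support(self):
        region = GenomicInterval("chr1", 0, 1000)
        js = [
            SpliceJunction("chr1", 200, 500, 3, "GTAG"),
            SpliceJunction("chr1", 300, 600, 9, "GTAG"),
        ]
        t = assemble_exons(region, js, "+")
        assert [(e.start, e.end) for e in t.exons] == [(0, 300), (600, 1000)]

    def test_junction_outside_region_errors(self):
        region = GenomicInterval("chr1", 400, 1100)
        with pytest.raises(ValueError):
            assemble_exons(region, [SpliceJunction("chr1", 100, 200, 5)])

    def test_minus_strand_tss_orientation(self):
        region = GenomicInterval("chr1", 400, 1100)
        t = assemble_exons(region, [], "-")
        assert t.tss == 1100 and t.end3 == 400

    def test_exons_tile_subset_of_region(self):
        region = GenomicInterval("chr1", 0, 5000)
        rng = np.random.default_rng(5)
        js = []
        pos = 100
        while pos < 4500:
            d = pos + int(rng.integers(50, 200))
            a = d + int(rng.integers(40, 200))
            if a >= 4900:
                break
            js.append(SpliceJunction("chr1", d, a, int(rng.integers(1, 20)), "GTAG"))
            pos = a + int(rng.integers(50, 200))
        t = assemble_exons(region, js, "+")
        assert all(a.end < b.start for a, b in zip(t.exons, t.exons[1:]))
        assert sum(len(e) for e in t.exons) <= len(region)


class TestSplicedSequence:
    genome = Genome({"chr1": "ACGTTTGCA"})

    def _t(self, strand):
        exons = [GenomicInterval("chr1", 0, 3), GenomicInterval("chr1", 6, 9)]
        return TranscriptCandidate("t", "chr1", exons, strand)

    def test_plus_strand_splice(self):
        assert spliced_sequence(self._t("+"), self.genome) == "ACGGCA"

    def test_minus_strand_reverse_complement(self):
        assert spliced_sequence(self._t("-"), self.genome) == "TGCCGT"

    def test_single_exon_substring_identity(self):
        t = TranscriptCandidate("t", "chr1", [GenomicInterval("chr1", 2, 7)], "+")
        assert spliced_sequence(t, self.genome) == "GTTTG"

    def test_out_of_bounds_exon_errors(self):
        t = TranscriptCandidate("t", "chr1", [GenomicInterval("chr1", 5, 20)], "+")
        with pytest.raises(ValueError):
            spliced_sequence(t, self.genome)


class TestValidJunctions:
    def _two_exon(self, strand="+"):
        exons = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        return TranscriptCandidate("t", "chr1", exons, strand)

    def test_canonical_junction_validates_both_exons(self):
        j = SpliceJunction("chr1", 100, 200, 5, "GTAG")
        assert valid_junction_count(self._two_exon(), [j]) == 2

    def test_non_canonical_motif_validates_nothing(self):
        j = SpliceJunction("chr1", 100, 200, 5, "ATAC")
        assert valid_junction_count(self._two_exon(), [j]) == 0

    def test_single_exon_is_zero(self):
        t = TranscriptCandidate("t", "chr1", [GenomicInterval("chr1", 0, 100)], "+")
        assert valid_junction_count(t, []) == 0

    def test_minus_strand_uses_ctac(self):
        j = SpliceJunction("chr1", 100, 200, 5, "CTAC")
        assert valid_junction_count(self._two_exon("-"), [j]) == 2
        assert valid_junction_count(self._two_exon("+"), [j]) == 0

    def test_middle_exon_needs_both_boundaries(self):
        exons = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 200, 300),
            GenomicInterval("chr1", 400, 500),
        ]
        t = TranscriptCandidate("t", "chr1", exons, "+")
        j1 = SpliceJunction("chr1", 100, 200, 5, "GTAG")
        j2 = SpliceJunction("chr1", 300, 400, 5, "ATAC")  # non-canonical
        assert valid_junction_count(t, [j1, j2]) == 1  # only the first exon
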