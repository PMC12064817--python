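"""The piecewise scoring scheme: branch values, continuity, ORF oracle, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncscout.genome_io import Genome, GenomicInterval, reverse_complement
from lncscout.scoring import (
    OrfResult,
    PolyAHit,
    ScoreCard,
    ScoredCandidate,
    chargaff_piecewise,
    find_longest_orf,
    find_polya,
    gc_piecewise,
    rank_candidates,
    score_candidate,
    score_chargaff,
    score_exons,
    score_gc,
    score_motif,
    score_orf,
    score_polya,
    score_promoter,
    score_trich,
    score_3utr,
    total_score,
    trich_piecewise,
)
from lncscout.structure_builder import SpliceJunction, TranscriptCandidate


def seq_with_fraction(bases: str, frac: float, n: int = 200) -> str:
    """Sequence of length n whose `bases` fraction is exactly `frac`."""
    k = round(frac * n)
    assert abs(k - frac * n) < 1e-9, "fraction not exactly realizable"
    fill = "".join(b for b in "ACGT" if b not in bases)
    return (bases * n)[:k] + (fill * n)[: n - k]


class TestPromoterScores:
    @pytest.mark.parametrize(
        "frac, expected",
        [(0.30, 0.0), (0.40, 0.0), (0.475, 0.5), (0.55, 1.0), (0.60, 1.0)],
    )
    def test_gc_branches(self, frac, expected):
        assert score_gc(seq_with_fraction("GC", frac)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "frac, expected",
        [(0.45, 0.0), (0.50, 0.0), (0.55, 0.5), (0.60, 1.0), (0.65, 1.0)],
    )
    def test_chargaff_branches(self, frac, expected):
        assert score_chargaff(seq_with_fraction("GT", frac)) == pytest.approx(expected)

    def test_n_bases_are_masked(self):
        # 10 G + 10 A + 20 N: GC fraction is 0.5 over informative bases
        assert score_gc("G" * 10 + "A" * 10 + "N" * 20) == pytest.approx(
            gc_piecewise(0.5)
        )

    def test_all_n_window_warns_and_scores_zero(self):
        with pytest.warns(UserWarning):
            assert score_gc("N" * 50) == 0.0

    def test_promoter_mean(self):
        assert score_promoter(1, 1, 1) == 1.0
        assert score_promoter(0, 0, 0) == 0.0
        assert score_promoter(1, 0.5, 0) == pytest.approx(0.5)


class TestMotif:
    def _context(self, insert=None, at=None):
        # motif-free background: no TATAAA, no Inr/DPE degenerate hits
        ctx = list("GGCGGC" * 14)[:81]
        if insert is not None:
            ctx[at : at + len(insert)] = list(insert)
        return "".join(ctx)

    def test_tata_in_window(self):
        ctx = self._context("TATAAA", 40 - 28)
        assert score_motif(ctx, 40) == 1.0

    def test_no_motif(self):
        assert score_motif(self._context(), 40) == 0.0

    def test_tata_outside_positional_window(self):
        ctx = self._context("TATAAA", 40 - 10)  # -10: outside [-33, -23]
        assert score_motif(ctx, 40) == 0.0

    def test_initiator_overlapping_tss(self):
        ctx = self._context("CCATTCC", 40 - 2)  # YYANWYY across the TSS
        assert score_motif(ctx, 40) == 1.0

    def test_dpe_in_window(self):
        ctx = self._context("AGATA", 40 + 28)  # RGWYV at +28
        assert score_motif(ctx, 40) == 1.0


class TestPolyA:
    def test_perfect_match(self):
        hit = find_polya("GCGCGCAATAAAGCGC")
        assert hit.match_class == "perfect" and hit.position == 6

    def test_single_mismatch_is_near_perfect(self):
        hit = find_polya("GCGCGCAATAAGGCGC")
        assert hit.match_class == "near_perfect"

    def test_gc_rich_sequence_has_no_hit(self):
        assert find_polya("GCGC" * 10).match_class == "none"

    def test_leftmost_perfect_beats_later_perfect(self):
        assert find_polya("AATAAACCAATAAA").position == 0

    def test_perfect_beats_earlier_near(self):
        hit = find_polya("AATAAG" + "GCGC" + "AATAAA")
        assert hit.match_class == "perfect" and hit.position == 10

    @pytest.mark.parametrize(
        "cls, expected", [("perfect", 1.0), ("near_perfect", 0.5), ("none", 0.0)]
    )
    def test_polya_score_map(self, cls, expected):
        assert score_polya(PolyAHit(cls, 0)) == expected


class TestTrich:
    @pytest.mark.parametrize(
        "frac, expected",
        [(0.25, 0.0), (0.30, 0.0), (0.325, 0.5), (0.40, 1.0), (0.45, 1.0)],
    )
    def test_branches(self, frac, expected):
        seq = seq_with_fraction("T", frac, n=80)
        assert score_trich(seq) == pytest.approx(expected)

    def test_empty_window_scores_zero(self):
        assert score_trich("") == 0.0

    def test_3utr_mean(self):
        assert score_3utr(1, 1) == 1.0
        assert score_3utr(0, 0) == 0.0
        assert score_3utr(0.5, 1) == pytest.approx(0.75)


class TestPiecewiseShape:
    EPS = 1e-9

    @pytest.mark.parametrize(
        "fn, breakpoints",
        [
            (gc_piecewise, [(0.4, 0.0), (0.55, 1.0)]),
            (chargaff_piecewise, [(0.5, 0.0), (0.6, 1.0)]),
            (trich_piecewise, [(0.3, 0.0), (0.4, 1.0)]),
        ],
    )
    def test_continuity_at_breakpoints(self, fn, breakpoints):
        # tolerance accommodates the sqrt ramp: f(0.3 + 1e-9) = 1e-4
        for x, value in breakpoints:
            assert fn(x) == pytest.approx(value, abs=2e-4)
            assert fn(x - self.EPS) == pytest.approx(value, abs=2e-4)
            assert fn(x + self.EPS) == pytest.approx(value, abs=2e-4)

    @pytest.mark.parametrize("fn", [gc_piecewise, chargaff_piecewise, trich_piecewise])
    def test_monotone_nondecreasing(self, fn):
        xs = np.linspace(0, 1, 401)
        ys = [fn(x) for x in xs]
        assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))
        assert all(0 <= y <= 1 for y in ys)


def brute_force_orf(seq: str):
    """Independent enumeration of every ATG..stop ORF; longest, then leftmost."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2 + 1, 3):
            if seq[j : j + 3] in stops:
                cand = (i, j + 3)
                if best is None or (cand[1] - cand[0], -cand[0]) > (
                    best[1] - best[0],
                    -best[0],
                ):
                    best = cand
                break
    return best


class TestOrf:
    def test_simple_orf(self):
        r = find_longest_orf("ATGAAATGA", [9])
        assert (r.start, r.end) == (0, 9)
        assert r.n_orf == 1 and r.includes_last_exon and r.p == 0.5

    def test_no_orf(self):
        r = find_longest_orf("CCCCCC", [6])
        assert r.n_orf == 0 and r.p == 0.0

    def test_orf_without_stop_is_not_an_orf(self):
        r = find_longest_orf("ATGAAAAAA", [9])
        assert r.n_orf == 0

    def test_exon_mapping_excludes_last(self):
        # exons of lengths 6, 6, 6; ORF spans first two only
        seq = "ATGAAATGACCCCCCCCC"
        r = find_longest_orf(seq, [6, 6, 6])
        assert r.n_orf == 2 and not r.includes_last_exon and r.p == 0.0

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(19)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            n = int(rng.integers(3, 301))
            seq = "".join(rng.choice(bases, size=n, p=[0.35, 0.15, 0.15, 0.35]))
            expected = brute_force_orf(seq)
            got = find_longest_orf(seq, [n])
            if expected is None:
                assert got.n_orf == 0
            else:
                assert (got.start, got.end) == expected

    @pytest.mark.parametrize(
        "n_orf, n_ex, p, expected",
        [(1, 1, 0.5, 1.0), (1, 4, 0.0, 1 / 3), (0, 3, 0.0, 0.0), (4, 4, 0.5, 1.0)],
    )
    def test_orf_score(self, n_orf, n_ex, p, expected):
        assert score_orf(n_orf, n_ex, p) == pytest.approx(expected)

    def test_orf_score_validates_counts(self):
        with pytest.raises(ValueError):
            score_orf(5, 4, 0.0)

    def test_orf_score_monotone_in_n_orf(self):
        scores = [score_orf(k, 6, 0.0) for k in range(7)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestExonScore:
    @pytest.mark.parametrize(
        "n_valid, n_ex, expected", [(0, 1, 0.0), (3, 4, 0.75), (5, 5, 1.0)]
    )
    def test_values(self, n_valid, n_ex, expected):
        assert score_exons(n_valid, n_ex) == expected

    def test_validates_counts(self):
        with pytest.raises(ValueError):
            score_exons(3, 2)


class TestTotals:
    @given(
        st.floats(0, 1), st.floats(0, 1), st.sampled_from([0.0, 1.0]),
        st.sampled_from([0.0, 0.5, 1.0]), st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_card_bounds(self, gc, charg, motif, polya, trich, orf, ex):
        card = ScoreCard.from_components(gc, charg, motif, polya, trich, orf, ex)
        for name in ("s_gc", "s_charg", "s_motif", "s_prom", "s_polya",
                     "s_trich", "s_3utr", "s_orf", "s_ex"):
            assert 0 <= getattr(card, name) <= 1
        assert 0 <= card.total <= 4
        assert card.total == pytest.approx(total_score(card))
        assert card.s_prom == pytest.approx((card.s_motif + card.s_gc + card.s_charg) / 3)
        assert card.s_3utr == pytest.approx((card.s_polya + card.s_trich) / 2)

    def test_example_sum(self):
        card = ScoreCard.from_components(0.5, 0.5, 0.5, 0.5, 1.0, 1 / 3, 0.75)
        assert card.total == pytest.approx(0.5 + 0.75 + 1 / 3 + 0.75)


class TestRanking:
    def _scored(self, cid, total, rpm=0.0, start=0):
        c = TranscriptCandidate(cid, "chr1", [GenomicInterval("chr1", start, start + 100)], "+")
        card = ScoreCard(0, 0, 0, 0, 0, 0, 0, 0, 0, total)
        return ScoredCandidate(c, card, "+", rpm)

    def test_descending_by_total(self):
        ranked = rank_candidates(
            [self._scored("a", 3.0), self._scored("b", 1.0), self._scored("c", 2.5)]
        )
        assert [s.candidate.id for s in ranked] == ["a", "c", "b"]

    def test_tie_broken_by_mean_rpm(self):
        ranked = rank_candidates(
            [self._scored("low", 2.0, rpm=5), self._scored("high", 2.0, rpm=9)]
        )
        assert [s.candidate.id for s in ranked] == ["high", "low"]

    def test_final_tie_broken_by_coordinate(self):
        ranked = rank_candidates(
            [self._scored("right", 2.0, start=500), self._scored("left", 2.0, start=10)]
        )
        assert [s.candidate.id for s in ranked] == ["left", "right"]


class TestStrandSymmetry:
    def test_scoring_is_strand_symmetric(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=3000))
        genome_fwd = Genome({"chr1": seq})
        genome_rev = Genome({"chr1": reverse_complement(seq)})
        n = len(seq)
        exons_fwd = [GenomicInterval("chr1", 1000, 1200), GenomicInterval("chr1", 1300, 1600)]
        exons_rev = [
            GenomicInterval("chr1", n - 1600, n - 1300),
            GenomicInterval("chr1", n - 1200, n - 1000),
        ]
        t_fwd = TranscriptCandidate("f", "chr1", exons_fwd, "+")
        t_rev = TranscriptCandidate("r", "chr1", exons_rev, "-")
        j_fwd = [SpliceJunction("chr1", 1200, 1300, 5, seq[1200:1202] + seq[1298:1300])]
        rev = reverse_complement(seq)
        j_rev = [
            SpliceJunction(
                "chr1", n - 1300, n - 1200, 5,
                rev[n - 1300 : n - 1298] + rev[n - 1202 : n - 1200],
            )
        ]
        card_fwd = score_candidate(t_fwd, genome_fwd, j_fwd).card
        card_rev = score_candidate(t_rev, genome_rev, j_rev).card
        assert card_fwd == card_rev
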