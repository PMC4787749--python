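"""Penalty normalization, additive pair scoring, and per-sequence ranks."""

import random

import pytest

from primersweep import PenaltyWeights, component_penalty, pair_penalty
from primersweep.pair_builder import PairConstraints, PrimerPair
from primersweep.ranking import rank_pairs
from primersweep.single_filter import Primer, SingleConstraints


def primer_with(seq="GCGATCGATTACGATCGATC", tm=60.0, gc=50.0, sc=6,
                esc=4, run=2, dg=-4.5, direction="forward", occ=(0, 10)):
    return Primer(
        primer_seq=seq, direction=direction,
        occurrences=[(occ[0], occ[1], len(seq))],
        target_sids=frozenset({occ[0]}),
        tm=tm, gc=gc, self_comp=sc, end_self_comp=esc, max_run=run, dg_3p=dg,
    )


def pair_with(fwd, rev, product=105, tm_diff=None, len_diff=None,
              pair_comp=6, end_pair_comp=4, sid=0):
    return PrimerPair(
        sid=sid, forward=fwd, reverse=rev,
        start_f=10, len_f=fwd.length,
        start_r=10 + product - rev.length, len_r=rev.length,
        product_size=product,
        tm_diff=abs(fwd.tm - rev.tm) if tm_diff is None else tm_diff,
        len_diff=abs(fwd.length - rev.length) if len_diff is None else len_diff,
        pair_comp=pair_comp, end_pair_comp=end_pair_comp,
        covered_sids=frozenset({sid}),
    )


class TestComponentPenalty:
    def test_range_midpoint_scores_zero(self):
        assert component_penalty(61.5, "range", 60.0, 63.0) == 0.0

    @pytest.mark.parametrize("value", [60.0, 63.0])
    def test_range_bounds_score_one(self, value):
        assert component_penalty(value, "range", 60.0, 63.0) == 1.0

    def test_cap_extremes(self):
        assert component_penalty(0, "cap", cap=5) == 0.0
        assert component_penalty(5, "cap", cap=5) == 1.0

    def test_clamping_and_degenerate_ranges(self):
        assert component_penalty(70.0, "range", 60.0, 63.0) == 1.0
        assert component_penalty(7, "cap", cap=5) == 1.0
        assert component_penalty(42.0, "range", 42.0, 42.0) == 0.0
        assert component_penalty(3, "cap", cap=0) == 0.0


class TestPairPenalty:
    C = SingleConstraints(min_len=19, max_len=24, min_tm=58, max_tm=62,
                          min_gc=35, max_gc=65, max_self_comp=12,
                          max_3p_self_comp=8, max_contiguous=4, min_dg_3p=-9)
    PC = PairConstraints(max_len_diff=3, max_tm_diff=2.0, min_product=70,
                         max_product=140, max_pair_comp=12, max_3p_pair_comp=8)

    def test_all_midpoints_and_zeros_score_zero(self):
        # length 21.5 is unreachable with integers; use a degenerate
        # length range so the length component vanishes analytically
        c = SingleConstraints(min_len=20, max_len=20, min_tm=58, max_tm=62,
                              min_gc=35, max_gc=65, max_self_comp=12,
                              max_3p_self_comp=8, max_contiguous=4,
                              min_dg_3p=-9)
        f = primer_with(seq="G" * 20, tm=60.0, gc=50.0, sc=0, esc=0, run=0, dg=0.0)
        r = primer_with(seq="C" * 20, tm=60.0, gc=50.0, sc=0, esc=0, run=0,
                        dg=0.0, direction="reverse")
        pair = pair_with(f, r, product=105, pair_comp=0, end_pair_comp=0)
        assert pair_penalty(pair, c, self.PC, PenaltyWeights()) == 0.0

    def test_single_component_perturbation_increases_penalty(self):
        f = primer_with(tm=60.0)
        r = primer_with(tm=60.0, direction="reverse")
        base = pair_penalty(pair_with(f, r, product=105), self.C, self.PC,
                            PenaltyWeights())
        moved = pair_penalty(pair_with(f, r, product=130), self.C, self.PC,
                             PenaltyWeights())
        assert moved > base

    def test_hand_summed_fixture_pair(self):
        """The 19 components of a fully-specified pair, summed by hand."""
        f = primer_with(seq="GCGATCGATTACGATCGATC",  # 20-mer
                        tm=60.5, gc=50.0, sc=6, esc=4, run=2, dg=-4.5)
        r = primer_with(seq="GGCATCGATTACGATCGAAGC",  # 21-mer
                        tm=59.5, gc=45.0, sc=8, esc=2, run=3, dg=-6.0,
                        direction="reverse")
        pair = pair_with(f, r, product=112, pair_comp=9, end_pair_comp=3)
        # forward: length |20-21.5|/2.5, tm |60.5-60|/2, gc 0, sc 6/12,
        #          esc 4/8, run 2/4, dg 4.5/9
        fwd = 0.6 + 0.25 + 0.0 + 0.5 + 0.5 + 0.5 + 0.5
        # reverse: length |21-21.5|/2.5, tm |59.5-60|/2, gc |45-50|/15,
        #          sc 8/12, esc 2/8, run 3/4, dg 6/9
        rev = 0.2 + 0.25 + (1 / 3) + (2 / 3) + 0.25 + 0.75 + (2 / 3)
        # pair: len_diff 1/3, tm_diff 1/2, product |112-105|/35,
        #       pair_comp 9/12, end_pair 3/8
        prc = (1 / 3) + 0.5 + 0.2 + 0.75 + 0.375
        expected = fwd + rev + prc
        assert pair_penalty(pair, self.C, self.PC, PenaltyWeights()) == (
            pytest.approx(expected, abs=1e-12)
        )

    def test_weights_scale_components(self):
        f = primer_with(sc=6)
        r = primer_with(sc=6, direction="reverse")
        pair = pair_with(f, r, product=105)
        w0 = PenaltyWeights(self_comp=0.0)
        w2 = PenaltyWeights(self_comp=2.0)
        base = pair_penalty(pair, self.C, self.PC, PenaltyWeights())
        assert pair_penalty(pair, self.C, self.PC, w0) == pytest.approx(
            base - 2 * 0.5
        )
        assert pair_penalty(pair, self.C, self.PC, w2) == pytest.approx(
            base + 2 * 0.5
        )


class TestRanking:
    def _pairs_with_penalties(self, penalties, sid=0):
        pairs = []
        for i, pen in enumerate(penalties):
            f = primer_with(occ=(sid, 10 + i))
            r = primer_with(direction="reverse", occ=(sid, 80 + i))
            p = pair_with(f, r, sid=sid)
            p.start_f = 10 + i
            p.start_r = 80 + i
            p.penalty = pen
            pairs.append(p)
        return pairs

    def test_dense_ranks_with_deterministic_ties(self):
        pairs = self._pairs_with_penalties([0.5, 0.2, 0.9, 0.5])
        from primersweep.pipeline import _rerank_quantized

        ranked = _rerank_quantized(pairs)
        assert [p.rank for p in ranked] == [1, 2, 3, 4]
        assert [p.penalty for p in ranked] == [0.2, 0.5, 0.5, 0.9]
        # tied pair with the smaller start_f comes first
        tied = [p for p in ranked if p.penalty == 0.5]
        assert tied[0].start_f < tied[1].start_f

    def test_single_pair_gets_rank_one(self):
        (p,) = self._pairs_with_penalties([0.7])
        from primersweep.pipeline import _rerank_quantized

        assert _rerank_quantized([p])[0].rank == 1

    def test_input_order_invariance(self, single_c, pair_c):
        pairs = self._pairs_with_penalties([0.4, 0.1, 0.9, 0.4, 0.2])
        shuffled = pairs[:]
        random.Random(3).shuffle(shuffled)
        a = rank_pairs(pairs, single_c, pair_c)
        b = rank_pairs(shuffled, single_c, pair_c)
        keyed_a = [(p.start_f, p.rank) for p in a]
        keyed_b = [(p.start_f, p.rank) for p in b]
        assert keyed_a == keyed_b

    def test_rank_concordant_with_penalty_within_each_sequence(
        self, bank_design
    ):
        for res in bank_design.values():
            by_sid = {}
            for p in res.pairs:
                by_sid.setdefault(p.sid, []).append(p)
            for group in by_sid.values():
                group.sort(key=lambda p: p.rank)
                assert [p.rank for p in group] == list(range(1, len(group) + 1))
                pens = [p.penalty for p in group]
                assert pens == sorted(pens)
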