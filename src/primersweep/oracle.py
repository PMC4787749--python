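"""Naive reference implementations for end-to-end verification.

Everything here recomputes pipeline stages by direct enumeration,
written independently of the production code paths: complementarity by
summing over alignment anti-diagonals instead of sliding a register,
candidate generation by plain double loops, pair joining by a full
cross product re-deriving every metric, and the penalty by a longhand
nineteen-term summation.  The thermodynamic sums are shared (they are
plain table lookups checked separately against frozen constants and an
external implementation).

These functions are for desk-scale inputs and tests only.
"""

from __future__ import annotations

from .crosshyb_filter import CrossHybParams, brute_force_crosshyb
from .pair_builder import PairConstraints, PrimerPair
from .ranking import PenaltyWeights
from .sequence_db import SequenceDB, gc_content, max_contiguous_run, reverse_complement
from .single_filter import (
    Primer,
    SingleConstraints,
    collapse_to_primers,
)
from .candidate_gen import CandidateSite
from .thermo import ThermoParams, delta_g_3prime, melting_temperature

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "naive_pair_complementarity",
    "naive_end_complementarity",
    "naive_enumerate",
    "naive_single_filter",
    "naive_build_pairs",
    "naive_pair_penalty",
]


def naive_pair_complementarity(s1: str, s2: str) -> int:
    """Best complementary-position count over anti-parallel registers,
    computed by grouping base pairings on anti-diagonals: in any ungapped
    anti-parallel register, position i of s1 faces position j of s2 with
    i + j constant."""
    n1, n2 = len(s1), len(s2)
    best = 0
    for c in range(n1 + n2 - 1):
        score = 0
        for i in range(n1):
            j = c - i
            if 0 <= j < n2 and _COMP[s1[i]] == s2[j]:
                score += 1
        best = max(best, score)
    return best


def naive_end_complementarity(s1: str, s2: str) -> int:
    """Anti-diagonal version restricted to registers pairing s1's 3' base."""
    n1, n2 = len(s1), len(s2)
    best = 0
    for c in range(n1 - 1, n1 - 1 + n2):
        # anti-diagonal c pairs s1[n1-1] with s2[c - (n1-1)], which exists
        score = 0
        for i in range(n1):
            j = c - i
            if 0 <= j < n2 and _COMP[s1[i]] == s2[j]:
                score += 1
        best = max(best, score)
    return best


def naive_enumerate(db: SequenceDB, min_len: int, max_len: int) -> list[CandidateSite]:
    """Plain double-loop enumeration of all oriented candidate sites."""
    sites = []
    for rec in db:
        for length in range(min_len, max_len + 1):
            for start in range(len(rec.sequence) - length + 1):
                window = rec.sequence[start : start + length]
                if any(ch not in "ACGT" for ch in window):
                    continue
                sites.append(CandidateSite(rec.sid, start, length, "forward", window))
                sites.append(
                    CandidateSite(
                        rec.sid, start, length, "reverse", reverse_complement(window)
                    )
                )
    return sites


def naive_single_filter(
    sites: list[CandidateSite], c: SingleConstraints, tp: ThermoParams
) -> list[Primer]:
    """Evaluate each of the six predicates directly on every site."""
    passing = []
    for site in sites:
        s = site.primer_seq
        tm = melting_temperature(s, tp)
        gc = gc_content(s)
        sc = naive_pair_complementarity(s, s)
        esc = naive_end_complementarity(s, s)
        run = max_contiguous_run(s)
        dg = delta_g_3prime(s, tp.dg_window, tp)
        ok = (
            c.min_tm <= tm <= c.max_tm
            and c.min_gc <= gc <= c.max_gc
            and sc <= c.max_self_comp
            and esc <= c.max_3p_self_comp
            and run <= c.max_contiguous
            and dg >= c.min_dg_3p
        )
        if ok:
            passing.append(
                (site, {"tm": tm, "gc": gc, "self_comp": sc, "end_self_comp": esc,
                        "max_run": run, "dg_3p": dg})
            )
    return collapse_to_primers(passing)


def naive_build_pairs(
    primers: list[Primer], db: SequenceDB, pc: PairConstraints, tp: ThermoParams
) -> list[PrimerPair]:
    """Full cross product over forward x reverse occurrences per sid,
    re-deriving every pair metric with the naive scorers."""
    pairs = []
    sids = sorted({sid for p in primers for sid, _, _ in p.occurrences})
    for sid in sids:
        fwd = [
            (p, st, ln)
            for p in primers
            if p.direction == "forward"
            for s, st, ln in p.occurrences
            if s == sid
        ]
        rev = [
            (p, st, ln)
            for p in primers
            if p.direction == "reverse"
            for s, st, ln in p.occurrences
            if s == sid
        ]
        for f, start_f, len_f in fwd:
            for r, start_r, len_r in rev:
                if start_f + len_f > start_r:
                    continue
                product = start_r + len_r - start_f
                len_diff = abs(len_f - len_r)
                tm_diff = abs(f.tm - r.tm)
                pcomp = naive_pair_complementarity(f.primer_seq, r.primer_seq)
                epcomp = max(
                    naive_end_complementarity(f.primer_seq, r.primer_seq),
                    naive_end_complementarity(r.primer_seq, f.primer_seq),
                )
                if (
                    pc.min_product <= product <= pc.max_product
                    and len_diff <= pc.max_len_diff
                    and tm_diff <= pc.max_tm_diff
                    and pcomp <= pc.max_pair_comp
                    and epcomp <= pc.max_3p_pair_comp
                ):
                    pairs.append(
                        PrimerPair(
                            sid=sid, forward=f, reverse=r,
                            start_f=start_f, len_f=len_f,
                            start_r=start_r, len_r=len_r,
                            product_size=product, tm_diff=tm_diff,
                            len_diff=len_diff, pair_comp=pcomp,
                            end_pair_comp=epcomp,
                            covered_sids=f.target_sids & r.target_sids,
                        )
                    )
    return pairs


def _range_pen(v: float, lo: float, hi: float) -> float:
    mid = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    if half <= 0:
        return 0.0
    return min(1.0, abs(v - mid) / half)


def _cap_pen(v: float, cap: float) -> float:
    if cap <= 0:
        return 0.0
    return min(1.0, v / cap)


def naive_pair_penalty(
    pair: PrimerPair,
    c: SingleConstraints,
    pc: PairConstraints,
    w: PenaltyWeights | None = None,
) -> float:
    """Longhand sum of all nineteen normalized penalty components."""
    if w is None:
        w = PenaltyWeights()
    terms = []
    for p in (pair.forward, pair.reverse):
        terms.append(w.length * _range_pen(len(p.primer_seq), c.min_len, c.max_len))
        terms.append(w.tm * _range_pen(p.tm, c.min_tm, c.max_tm))
        terms.append(w.gc * _range_pen(p.gc, c.min_gc, c.max_gc))
        terms.append(w.self_comp * _cap_pen(p.self_comp, c.max_self_comp))
        terms.append(w.end_self_comp * _cap_pen(p.end_self_comp, c.max_3p_self_comp))
        terms.append(w.contiguous * _cap_pen(p.max_run, c.max_contiguous))
        terms.append(w.dg_3p * _cap_pen(abs(p.dg_3p), abs(c.min_dg_3p)))
    terms.append(w.len_diff * _cap_pen(pair.len_diff, pc.max_len_diff))
    terms.append(w.tm_diff * _cap_pen(pair.tm_diff, pc.max_tm_diff))
    terms.append(w.product_size * _range_pen(pair.product_size, pc.min_product,
                                             pc.max_product))
    terms.append(w.pair_comp * _cap_pen(pair.pair_comp, pc.max_pair_comp))
    terms.append(w.end_pair_comp * _cap_pen(pair.end_pair_comp, pc.max_3p_pair_comp))
    return sum(terms)
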