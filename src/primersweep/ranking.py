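"""Penalty scoring and per-sequence ranking of primer pairs.

Each pair receives an additive penalty built from nineteen normalized
components: seven per primer (length, Tm, GC, self-complementarity,
3'-end self-complementarity, contiguous run, 3'-end dG) and five for the
pair (length difference, Tm difference, product size, pair- and 3'-end
pair-complementarity).

Two normalization kinds cover every component:

* *range* constraints (length, Tm, GC, product size): penalty is the
  scaled distance from the range midpoint, ``|v - mid| / half_width``;
  the midpoint scores 0, either bound scores 1.
* *cap* constraints (everything counted or magnitude-bounded): penalty
  is ``v / cap``; zero scores 0, the cap scores 1.  The dG component
  uses magnitudes, ``|dG| / |min_dG|``, so less stable 3' ends score
  lower.

All components clamp to [0, 1]; weights default to 1.  Within each
source sequence, pairs are sorted by ascending penalty and given dense
ranks 1..n, ties broken by coordinates then primer strings so the
ordering is reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .pair_builder import PairConstraints, PrimerPair
from .single_filter import Primer, SingleConstraints

__all__ = ["PenaltyWeights", "component_penalty", "single_primer_penalty",
           "pair_penalty", "rank_pairs"]

SINGLE_COMPONENTS = ("length", "tm", "gc", "self_comp", "end_self_comp",
                     "contiguous", "dg_3p")
PAIR_COMPONENTS = ("len_diff", "tm_diff", "product_size", "pair_comp",
                   "end_pair_comp")


@dataclasses.dataclass
class PenaltyWeights:
    length: float = 1.0
    tm: float = 1.0
    gc: float = 1.0
    self_comp: float = 1.0
    end_self_comp: float = 1.0
    contiguous: float = 1.0
    dg_3p: float = 1.0
    len_diff: float = 1.0
    tm_diff: float = 1.0
    product_size: float = 1.0
    pair_comp: float = 1.0
    end_pair_comp: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"weight {f.name} must be >= 0")


def component_penalty(
    value: float,
    kind: str,
    lo: float | None = None,
    hi: float | None = None,
    cap: float | None = None,
) -> float:
    """Normalized [0, 1] penalty of one constraint component.

    kind="range": 0 at the midpoint of [lo, hi], 1 at either bound.
    kind="cap":   0 at zero, 1 at the cap.
    Degenerate ranges/caps score 0; results clamp to [0, 1].
    """
    if kind == "range":
        if lo is None or hi is None:
            raise ValueError("range kind needs lo and hi")
        half = (hi - lo) / 2.0
        if half <= 0:
            return 0.0
        pen = abs(value - (lo + hi) / 2.0) / half
    elif kind == "cap":
        if cap is None:
            raise ValueError("cap kind needs cap")
        if cap <= 0:
            return 0.0
        pen = value / cap
    else:
        raise ValueError(f"unknown penalty kind {kind!r}")
    return min(1.0, max(0.0, pen))


def single_primer_penalty(
    p: Primer, c: SingleConstraints, w: PenaltyWeights
) -> float:
    """Weighted sum of the seven per-primer components."""
    return (
        w.length * component_penalty(p.length, "range", c.min_len, c.max_len)
        + w.tm * component_penalty(p.tm, "range", c.min_tm, c.max_tm)
        + w.gc * component_penalty(p.gc, "range", c.min_gc, c.max_gc)
        + w.self_comp * component_penalty(p.self_comp, "cap", cap=c.max_self_comp)
        + w.end_self_comp
        * component_penalty(p.end_self_comp, "cap", cap=c.max_3p_self_comp)
        + w.contiguous * component_penalty(p.max_run, "cap", cap=c.max_contiguous)
        + w.dg_3p * component_penalty(abs(p.dg_3p), "cap", cap=abs(c.min_dg_3p))
    )


def pair_penalty(
    pair: PrimerPair,
    c: SingleConstraints,
    pc: PairConstraints,
    w: PenaltyWeights,
) -> float:
    """Total penalty: both primers' seven components plus the five pair
    components, each normalized to [0, 1] and weighted."""
    total = single_primer_penalty(pair.forward, c, w)
    total += single_primer_penalty(pair.reverse, c, w)
    total += w.len_diff * component_penalty(pair.len_diff, "cap", cap=pc.max_len_diff)
    total += w.tm_diff * component_penalty(pair.tm_diff, "cap", cap=pc.max_tm_diff)
    total += w.product_size * component_penalty(
        pair.product_size, "range", pc.min_product, pc.max_product
    )
    total += w.pair_comp * component_penalty(
        pair.pair_comp, "cap", cap=pc.max_pair_comp
    )
    total += w.end_pair_comp * component_penalty(
        pair.end_pair_comp, "cap", cap=pc.max_3p_pair_comp
    )
    return total


def rank_pairs(
    pairs: Sequence[PrimerPair],
    c: SingleConstraints,
    pc: PairConstraints,
    w: PenaltyWeights | None = None,
) -> list[PrimerPair]:
    """Assign penalties and dense per-sequence ranks (1 = best).

    Output is sorted by (sid, rank) and is invariant to input order.
    """
    if w is None:
        w = PenaltyWeights()
    for pair in pairs:
        pair.penalty = pair_penalty(pair, c, pc, w)
    by_sid: dict[int, list[PrimerPair]] = {}
    for pair in pairs:
        by_sid.setdefault(pair.sid, []).append(pair)
    ranked: list[PrimerPair] = []
    for sid in sorted(by_sid):
        group = sorted(by_sid[sid], key=lambda q: (q.penalty,) + q.sort_key())
        for rank, pair in enumerate(group, start=1):
            pair.rank = rank
        ranked.extend(group)
    return ranked
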