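"""Pair construction: per-sequence forward x reverse join with five
pair-level constraints.

For each source sequence, every forward occurrence is joined with every
reverse occurrence downstream of it (binding sites must not overlap).
Product size is the standard amplicon length, measured from the 5' end
of the forward site through the far end of the reverse site:
``(start_r + len_r) - start_f``.

The five pair constraints are length difference, melting-temperature
difference, product size, pair-complementarity and 3'-end
pair-complementarity.  The 3'-end score is the larger of the two
anchor orders (forward 3' end against the reverse primer and vice
versa), since either extendable 3' end can prime a dimer.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .sequence_db import SequenceDB
from .single_filter import Primer
from .thermo import ThermoParams, end_complementarity, pair_complementarity

__all__ = ["PairConstraints", "PrimerPair", "build_pairs", "pair_scores"]


@dataclasses.dataclass
class PairConstraints:
    max_len_diff: int = 3
    max_tm_diff: float = 2.0
    min_product: int = 100
    max_product: int = 250
    max_pair_comp: int = 12
    max_3p_pair_comp: int = 8

    def __post_init__(self) -> None:
        if self.min_product > self.max_product:
            raise ValueError(
                f"min_product {self.min_product} > max_product {self.max_product}"
            )
        for v in (self.max_len_diff, self.max_tm_diff, self.min_product):
            if v < 0:
                raise ValueError("pair constraint values must be >= 0")


@dataclasses.dataclass
class PrimerPair:
    """A forward+reverse primer anchored on one source sequence."""

    sid: int
    forward: Primer
    reverse: Primer
    start_f: int
    len_f: int
    start_r: int
    len_r: int
    product_size: int
    tm_diff: float
    len_diff: int
    pair_comp: int
    end_pair_comp: int
    covered_sids: frozenset[int]
    penalty: float = float("nan")
    rank: int = 0

    def sort_key(self) -> tuple:
        return (self.start_f, self.start_r, self.forward.primer_seq,
                self.reverse.primer_seq)


def pair_scores(fwd_seq: str, rev_seq: str) -> tuple[int, int]:
    """(pair_comp, end_pair_comp) for a primer pair, both anchor orders."""
    pc = pair_complementarity(fwd_seq, rev_seq).score
    epc = max(
        end_complementarity(fwd_seq, rev_seq).score,
        end_complementarity(rev_seq, fwd_seq).score,
    )
    return pc, epc


def build_pairs(
    primers: Sequence[Primer],
    db: SequenceDB,
    pc: PairConstraints,
    tp: ThermoParams,
) -> list[PrimerPair]:
    """Join forward x reverse occurrences per sequence under the five
    pair constraints.  A primer occurring several times on one sequence
    contributes each occurrence independently."""
    by_sid_fwd: dict[int, list[tuple[Primer, int, int]]] = {}
    by_sid_rev: dict[int, list[tuple[Primer, int, int]]] = {}
    for p in primers:
        table = by_sid_fwd if p.direction == "forward" else by_sid_rev
        for sid, start, length in p.occurrences:
            table.setdefault(sid, []).append((p, start, length))
    comp_cache: dict[tuple[str, str], tuple[int, int]] = {}
    pairs: list[PrimerPair] = []
    for sid in sorted(set(by_sid_fwd) & set(by_sid_rev)):
        for f, start_f, len_f in by_sid_fwd[sid]:
            for r, start_r, len_r in by_sid_rev[sid]:
                if start_f + len_f > start_r:
                    continue  # overlapping binding sites
                product = (start_r + len_r) - start_f
                if not (pc.min_product <= product <= pc.max_product):
                    continue
                len_diff = abs(len_f - len_r)
                if len_diff > pc.max_len_diff:
                    continue
                tm_diff = abs(f.tm - r.tm)
                if tm_diff > pc.max_tm_diff:
                    continue
                key = (f.primer_seq, r.primer_seq)
                scores = comp_cache.get(key)
                if scores is None:
                    scores = pair_scores(f.primer_seq, r.primer_seq)
                    comp_cache[key] = scores
                pcomp, epcomp = scores
                if pcomp > pc.max_pair_comp or epcomp > pc.max_3p_pair_comp:
                    continue
                pairs.append(
                    PrimerPair(
                        sid=sid,
                        forward=f,
                        reverse=r,
                        start_f=start_f,
                        len_f=len_f,
                        start_r=start_r,
                        len_r=len_r,
                        product_size=product,
                        tm_diff=tm_diff,
                        len_diff=len_diff,
                        pair_comp=pcomp,
                        end_pair_comp=epcomp,
                        covered_sids=f.target_sids & r.target_sids,
                    )
                )
    return pairs
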