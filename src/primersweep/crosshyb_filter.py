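"""Cross-hybridization specificity filtering.

Two elimination rules remove primers that could anneal to off-target
sequences:

* **5' rule** — a primer is discarded if some off-target window (either
  strand) matches it exactly everywhere beyond the 5'-terminal zone and
  differs in at most ``max_5p_mismatch`` places inside the zone.  A primer
  whose 3' region sits perfectly on an off-target is a mispriming hazard
  regardless of 5' mismatches.

* **general rule** — a primer is discarded if some off-target window of
  equal length (either strand) is within Hamming distance ``k`` of it,
  run for k = 1..K.

The general rule is computed with pigeonhole seed filtering: a length-m
string within k mismatches of a primer must share at least one of the
k+1 contiguous blocks of length floor(m/(k+1)) exactly, at the same
offset.  Candidate (primer, window) pairs are therefore discovered only
through a grouped join on shared seed keys and then verified by a full
Hamming count; verdicts are aggregated over all seed groups before any
primer is removed, so the result does not depend on the grouping.

A sequence counts as a *target* of a primer if the primer string occurs
in it exactly on either strand; every other sequence is off-target.  An
exact duplicate elsewhere therefore marks an additional target (a
multi-target primer), never an elimination.

``brute_force_crosshyb`` is the literal every-window reference
implementation used as the testing oracle.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Iterator, Sequence

import numpy as np

from .sequence_db import SequenceDB
from .single_filter import Primer

__all__ = [
    "CrossHybParams",
    "SeedKey",
    "seed_decompose",
    "five_prime_filter",
    "general_filter",
    "run_crosshyb",
    "brute_force_crosshyb",
    "brute_force_general",
]

logger = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclasses.dataclass
class CrossHybParams:
    """Knobs of the two elimination rules.

    ``five_prime_zone`` is the number of 5'-terminal positions in which
    the 5' rule tolerates mismatches; by default it equals
    ``max_5p_mismatch`` (up to four mismatches, all of them at the 5'
    end), but the two are independent knobs.
    """

    max_5p_mismatch: int = 4
    max_general_mismatch: int = 2
    five_prime_zone: int = 4

    def __post_init__(self) -> None:
        if self.max_5p_mismatch < 0 or self.max_general_mismatch < 0:
            raise ValueError("mismatch bounds must be >= 0")
        if self.five_prime_zone < 0:
            raise ValueError("five_prime_zone must be >= 0")


@dataclasses.dataclass(frozen=True)
class SeedKey:
    seed_seq: str
    seed_index: int
    primer_len: int
    block_offset: int


def seed_decompose(primer_seq: str, k: int) -> list[SeedKey]:
    """Split a primer into k+1 contiguous blocks; the last absorbs the
    remainder.  Blocks 0..k-1 have length floor(m/(k+1))."""
    m = len(primer_seq)
    if k < 0:
        raise ValueError("k must be >= 0")
    if m < k + 1:
        raise ValueError(f"primer of length {m} cannot be split into {k + 1} blocks")
    base = m // (k + 1)
    keys = []
    for j in range(k + 1):
        off = j * base
        end = off + base if j < k else m
        keys.append(SeedKey(primer_seq[off:end], j, m, off))
    return keys


def _block_bounds(m: int, k: int) -> list[tuple[int, int]]:
    base = m // (k + 1)
    return [(j * base, (j + 1) * base if j < k else m) for j in range(k + 1)]


def iter_windows(db: SequenceDB, m: int) -> Iterator[tuple[int, str]]:
    """Yield (sid, window) for every length-m window on both strands."""
    for rec in db:
        seq = rec.sequence
        for i in range(rec.length - m + 1):
            yield rec.sid, seq[i : i + m]
        if rec.length >= m:
            anti = _revcomp_with_n(seq)
            for i in range(rec.length - m + 1):
                yield rec.sid, anti[i : i + m]


_RC_N = str.maketrans("ACGTN", "TGCAN")


def _revcomp_with_n(seq: str) -> str:
    return seq.translate(_RC_N)[::-1]


def exact_occurrence_index(db: SequenceDB, lengths: Iterable[int]) -> dict:
    """For each length m: map window string -> set of sids containing it
    exactly on either strand."""
    index: dict[int, dict[str, set[int]]] = {}
    for m in sorted(set(lengths)):
        table: dict[str, set[int]] = {}
        for sid, w in iter_windows(db, m):
            table.setdefault(w, set()).add(sid)
        index[m] = table
    return index


def _extended_targets(primers: Sequence[Primer], occ_index: dict) -> list[frozenset[int]]:
    out = []
    for p in primers:
        exact = occ_index[p.length].get(p.primer_seq, set())
        out.append(frozenset(p.target_sids) | frozenset(exact))
    return out


def _hamming_leq(a: str, b: str, k: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > k:
                return False
    return True


def five_prime_filter(
    primers: Sequence[Primer],
    db: SequenceDB,
    params: CrossHybParams,
    occ_index: dict | None = None,
) -> list[Primer]:
    """Apply the 5' elimination rule; return survivors in input order."""
    primers = list(primers)
    lengths = {p.length for p in primers}
    if occ_index is None:
        occ_index = exact_occurrence_index(db, lengths)
    targets = _extended_targets(primers, occ_index)
    zone = params.five_prime_zone
    # grouped join on the exact 3' region (everything beyond the zone)
    by_suffix: dict[tuple[int, str], list[int]] = {}
    for i, p in enumerate(primers):
        z = min(zone, p.length)
        by_suffix.setdefault((p.length, p.primer_seq[z:]), []).append(i)
    eliminated: set[int] = set()
    for m in sorted(lengths):
        z = min(zone, m)
        for sid, w in iter_windows(db, m):
            bucket = by_suffix.get((m, w[z:]))
            if not bucket:
                continue
            for i in bucket:
                if i in eliminated or sid in targets[i]:
                    continue
                mism = sum(
                    1 for a, b in zip(primers[i].primer_seq[:z], w[:z]) if a != b
                )
                if mism <= params.max_5p_mismatch:
                    eliminated.add(i)
                    logger.debug(
                        "5' rule removes %s (off-target sid %d)",
                        primers[i].primer_seq, sid,
                    )
    return [p for i, p in enumerate(primers) if i not in eliminated]


def general_filter(
    primers: Sequence[Primer],
    db: SequenceDB,
    k: int,
    occ_index: dict | None = None,
) -> list[Primer]:
    """One iteration of the general rule at Hamming radius ``k``.

    Removes every primer with an off-target window at distance <= k.
    Candidates come only from the seed-key join; verdicts are aggregated
    across all groups before removal.
    """
    primers = list(primers)
    if k < 0:
        raise ValueError("k must be >= 0")
    lengths = {p.length for p in primers}
    if occ_index is None:
        occ_index = exact_occurrence_index(db, lengths)
    targets = _extended_targets(primers, occ_index)
    if k == 0:
        # distance 0 = exact occurrence = target by definition; nothing fires
        return primers
    seed_index: dict[tuple[int, int, str], list[int]] = {}
    for i, p in enumerate(primers):
        for key in seed_decompose(p.primer_seq, k):
            seed_index.setdefault(
                (key.primer_len, key.seed_index, key.seed_seq), []
            ).append(i)
    eliminated: set[int] = set()
    bounds = {m: _block_bounds(m, k) for m in lengths if m >= k + 1}
    for m in sorted(bounds):
        for sid, w in iter_windows(db, m):
            for j, (lo, hi) in enumerate(bounds[m]):
                bucket = seed_index.get((m, j, w[lo:hi]))
                if not bucket:
                    continue
                for i in bucket:
                    if i in eliminated or sid in targets[i]:
                        continue
                    if _hamming_leq(primers[i].primer_seq, w, k):
                        eliminated.add(i)
                        logger.debug(
                            "general rule (k=%d) removes %s (off-target sid %d)",
                            k, primers[i].primer_seq, sid,
                        )
    return [p for i, p in enumerate(primers) if i not in eliminated]


def run_crosshyb(
    primers: Sequence[Primer], db: SequenceDB, params: CrossHybParams
) -> tuple[list[Primer], dict[str, int]]:
    """Full specificity screen: 5' rule, then general rule for k = 1..K.

    Returns (survivors, per-stage survivor counts).  The iterative
    schedule is kept for log interpretability; because elimination is an
    existential condition over off-target windows, a single pass at k = K
    yields the same set.
    """
    occ_index = exact_occurrence_index(db, {p.length for p in primers})
    counts: dict[str, int] = {}
    survivors = five_prime_filter(primers, db, params, occ_index)
    counts["after_5p_filter"] = len(survivors)
    for k in range(1, params.max_general_mismatch + 1):
        survivors = general_filter(survivors, db, k, occ_index)
        counts[f"after_general_k{k}"] = len(survivors)
    return survivors, counts


# ---------------------------------------------------------------------------
# brute-force reference (testing oracle)
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode("ascii").translate(
            bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
        ),
        dtype=np.uint8,
    )


def _window_matrices(db: SequenceDB, m: int) -> list[tuple[int, np.ndarray]]:
    """(sid, windows) per sequence per strand; windows is (n, m) uint8."""
    out = []
    for rec in db:
        if rec.length < m:
            continue
        for s in (rec.sequence, _revcomp_with_n(rec.sequence)):
            arr = _encode(s)
            wins = np.lib.stride_tricks.sliding_window_view(arr, m)
            out.append((rec.sid, wins))
    return out


def brute_force_general(
    primers: Sequence[Primer], db: SequenceDB, k: int
) -> list[Primer]:
    """Literal scan: remove primers with any off-target window at
    Hamming distance 1..k (distance-0 windows mark targets)."""
    primers = list(primers)
    lengths = {p.length for p in primers}
    occ_index = exact_occurrence_index(db, lengths)
    targets = _extended_targets(primers, occ_index)
    mats = {m: _window_matrices(db, m) for m in lengths}
    survivors = []
    for i, p in enumerate(primers):
        parr = _encode(p.primer_seq)
        hit = False
        for sid, wins in mats[p.length]:
            if sid in targets[i]:
                continue
            d = (wins != parr).sum(axis=1)
            if (d <= k).any():
                hit = True
                break
        if not hit:
            survivors.append(p)
    return survivors


def brute_force_crosshyb(
    primers: Sequence[Primer], db: SequenceDB, params: CrossHybParams
) -> list[Primer]:
    """Reference answer for the whole specificity screen.

    Scans every window of every off-target sequence on both strands and
    applies the 5' rule and the general rule (at the full radius K)
    literally.  Intended for desk-scale inputs.
    """
    primers = list(primers)
    lengths = {p.length for p in primers}
    occ_index = exact_occurrence_index(db, lengths)
    targets = _extended_targets(primers, occ_index)
    mats = {m: _window_matrices(db, m) for m in lengths}
    K = params.max_general_mismatch
    survivors = []
    for i, p in enumerate(primers):
        parr = _encode(p.primer_seq)
        z = min(params.five_prime_zone, p.length)
        hit = False
        for sid, wins in mats[p.length]:
            if sid in targets[i]:
                continue
            neq = wins != parr
            d = neq.sum(axis=1)
            if (d <= K).any():
                hit = True
                break
            zone_mm = neq[:, :z].sum(axis=1)
            suffix_exact = ~neq[:, z:].any(axis=1) if z < p.length else d == 0
            if (suffix_exact & (zone_mm <= params.max_5p_mismatch)).any():
                hit = True
                break
        if not hit:
            survivors.append(p)
    return survivors
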