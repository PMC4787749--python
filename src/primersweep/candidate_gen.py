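"""Candidate generation: exhaustive windowed enumeration in both orientations.

For every sequence, every length in ``[min_len, max_len]`` and every start
offset, one forward candidate (the sense window itself) and one reverse
candidate (its reverse complement, tagged ``reverse``) are emitted.
Windows containing non-ACGT characters are skipped.  Candidates are
yielded lazily so downstream filters can run in bounded memory.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

from .sequence_db import SequenceDB, reverse_complement

__all__ = ["CandidateSite", "enumerate_candidates", "forward_site_count"]

FORWARD = "forward"
REVERSE = "reverse"


@dataclasses.dataclass(frozen=True)
class CandidateSite:
    """One oriented subsequence occurrence.

    ``start`` is the 0-based sense-strand offset of the window; for
    ``direction == "reverse"`` the primer sequence is the reverse
    complement of the sense window, written 5'->3'.
    """

    sid: int
    start: int
    length: int
    direction: str
    primer_seq: str


def _next_bad_index(seq: str) -> list[int]:
    """next_bad[i] = smallest j >= i with a non-ACGT base (len(seq) if none)."""
    n = len(seq)
    nb = [n] * (n + 1)
    for i in range(n - 1, -1, -1):
        nb[i] = i if seq[i] not in "ACGT" else nb[i + 1]
    return nb


def enumerate_candidates(
    db: SequenceDB, min_len: int, max_len: int
) -> Iterator[CandidateSite]:
    """Yield every candidate site of every sequence, both orientations.

    For a fully-ACGT sequence of length L the forward count is
    sum over l in [min_len, max_len] of (L - l + 1), and the reverse
    count equals it.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    for rec in db:
        seq = rec.sequence
        nb = _next_bad_index(seq)
        for length in range(min_len, max_len + 1):
            for start in range(0, rec.length - length + 1):
                if nb[start] < start + length:
                    continue
                window = seq[start : start + length]
                yield CandidateSite(rec.sid, start, length, FORWARD, window)
                yield CandidateSite(
                    rec.sid, start, length, REVERSE, reverse_complement(window)
                )


def forward_site_count(L: int, min_len: int, max_len: int) -> int:
    """Closed-form forward candidate count for an N-free sequence of length L."""
    return sum(max(0, L - l + 1) for l in range(min_len, max_len + 1))
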