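"""Sequence database: FASTA ingest, stable integer ids, base-level utilities.

Every downstream stage addresses sequences by a dense integer ``sid``
assigned in file order.  Coordinates are 0-based, half-open ``[start, end)``
on the sense strand throughout the package.

Ambiguity handling: sequences are upper-cased and ``U`` is mapped to ``T``
at ingest.  IUPAC ambiguity codes other than ``N`` are collapsed to ``N``.
Windows containing ``N`` are excluded from candidate generation, but the
full sequence is retained for off-target scanning, where ``N`` matches
nothing (always counts as a mismatch).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq as _BioSeq

__all__ = [
    "SequenceRecord",
    "SequenceDB",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "gc_content",
    "max_contiguous_run",
]

_ACGT = frozenset("ACGT")
_IUPAC_AMBIG = set("RYSWKMBDHVN")
_RC_TABLE = str.maketrans("ACGT", "TGCA")


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One database entry with a stable integer id.

    ``sid`` values are dense (0..n-1) within a :class:`SequenceDB`;
    ``sequence`` is upper-case over the alphabet {A, C, G, T, N}.
    """

    sid: int
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if self.sid < 0:
            raise ValueError(f"sid must be >= 0, got {self.sid}")
        bad = set(self.sequence) - _ACGT - {"N"}
        if bad:
            raise ValueError(
                f"record {self.accession!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class SequenceDB:
    """Ordered, sid-indexed collection of :class:`SequenceRecord`."""

    def __init__(self, records: Iterable[SequenceRecord], name: str = "") -> None:
        self.records: list[SequenceRecord] = list(records)
        self.name = name
        if not self.records:
            raise ValueError("empty database")
        sids = [r.sid for r in self.records]
        if sids != list(range(len(self.records))):
            raise ValueError("sids must be dense 0..n-1 in record order")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, sid: int) -> SequenceRecord:
        return self.records[sid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceDB):
            return NotImplemented
        return self.records == other.records

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[str], name: str = "", accessions: Iterable[str] | None = None
    ) -> "SequenceDB":
        seqs = list(seqs)
        accs = list(accessions) if accessions is not None else [
            f"seq{i}" for i in range(len(seqs))
        ]
        return cls(
            [
                SequenceRecord(i, acc, _normalize(s, acc))
                for i, (acc, s) in enumerate(zip(accs, seqs))
            ],
            name=name,
        )


def _normalize(raw: str, accession: str) -> str:
    """Upper-case, U->T, non-N IUPAC ambiguity codes -> N; reject junk."""
    s = raw.upper().replace("U", "T")
    out = []
    for ch in s:
        if ch in _ACGT:
            out.append(ch)
        elif ch in _IUPAC_AMBIG:
            out.append("N")
        else:
            raise ValueError(f"record {accession!r}: invalid base {ch!r}")
    return "".join(out)


def read_fasta(path: str | Path, name: str | None = None) -> SequenceDB:
    """Read a multi-FASTA file into a :class:`SequenceDB`.

    sids are assigned in file order starting at 0.  The accession is the
    first whitespace-delimited token of the header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        with open(path) as fh:
            for sid, rec in enumerate(SeqIO.parse(fh, "fasta")):
                records.append(
                    SequenceRecord(sid, rec.id, _normalize(str(rec.seq), rec.id))
                )
    except ValueError as exc:  # malformed FASTA from the Biopython parser
        raise ValueError(f"parse error in {path}: {exc}") from exc
    if not records:
        raise ValueError(f"empty database: {path} contains no FASTA records")
    return SequenceDB(records, name=name if name is not None else path.stem)


def write_fasta(db: SequenceDB, path: str | Path) -> None:
    """Write a database back to FASTA (accession as the full header)."""
    recs = [
        _BioRecord(_BioSeq(r.sequence), id=r.accession, description="")
        for r in db
    ]
    SeqIO.write(recs, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string, 5'->3'."""
    if set(seq) - _ACGT:
        raise ValueError(f"invalid base in {seq!r}: only ACGT allowed")
    return seq.translate(_RC_TABLE)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage: 100 * (#G + #C) / length."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def max_contiguous_run(seq: str) -> int:
    """Length of the longest run of one identical base."""
    if not seq:
        raise ValueError("max_contiguous_run of empty sequence")
    best = run = 1
    prev = seq[0]
    for ch in seq[1:]:
        if ch == prev:
            run += 1
            if run > best:
                best = run
        else:
            run = 1
            prev = ch
    return best
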