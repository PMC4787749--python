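"""Single-primer filtering and collapse of sites into unique primers.

Six per-primer constraints are applied to each candidate (length was
already fixed at enumeration): melting temperature, GC content,
self-complementarity, 3'-end self-complementarity, longest contiguous
run, and 3'-end free energy.  All range checks are inclusive on both
ends.  Surviving sites with an identical (sequence, direction) key are
collapsed into one :class:`Primer` carrying its occurrence list and the
set of sequences it hits exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from .candidate_gen import CandidateSite
from .sequence_db import gc_content, max_contiguous_run
from .thermo import (
    ThermoParams,
    delta_g_3prime,
    end_complementarity,
    melting_temperature,
    self_complementarity,
)

__all__ = ["SingleConstraints", "SingleVerdict", "Primer", "check_single",
           "primer_metrics", "collapse_to_primers"]


@dataclasses.dataclass
class SingleConstraints:
    """Per-primer thresholds.  ``min_dg_3p`` is a lower bound in kcal/mol:
    the 3'-end window must not be more stable (more negative) than it.

    The defaults are a conventional qPCR profile; every value is
    overridable through the run configuration.
    """

    min_len: int = 19
    max_len: int = 24
    min_tm: float = 60.0
    max_tm: float = 63.0
    min_gc: float = 35.0
    max_gc: float = 65.0
    max_self_comp: int = 12
    max_3p_self_comp: int = 8
    max_contiguous: int = 4
    min_dg_3p: float = -9.0

    def __post_init__(self) -> None:
        for lo, hi, name in [
            (self.min_len, self.max_len, "length"),
            (self.min_tm, self.max_tm, "tm"),
            (self.min_gc, self.max_gc, "gc"),
        ]:
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclasses.dataclass(frozen=True)
class SingleVerdict:
    passed: bool
    metrics: dict
    failures: tuple[str, ...]


_METRIC_NAMES = ("tm", "gc", "self_comp", "end_self_comp", "max_run", "dg_3p")


def primer_metrics(seq: str, params: ThermoParams) -> dict:
    """All six filterable metrics of a primer sequence."""
    return {
        "tm": melting_temperature(seq, params),
        "gc": gc_content(seq),
        "self_comp": self_complementarity(seq).score,
        "end_self_comp": end_complementarity(seq, seq).score,
        "max_run": max_contiguous_run(seq),
        "dg_3p": delta_g_3prime(seq, params.dg_window, params),
    }


def check_single(
    seq: str, c: SingleConstraints, params: ThermoParams
) -> SingleVerdict:
    """Evaluate all six predicates; report the full verdict vector."""
    m = primer_metrics(seq, params)
    failures = []
    if not (c.min_tm <= m["tm"] <= c.max_tm):
        failures.append("tm")
    if not (c.min_gc <= m["gc"] <= c.max_gc):
        failures.append("gc")
    if m["self_comp"] > c.max_self_comp:
        failures.append("self_comp")
    if m["end_self_comp"] > c.max_3p_self_comp:
        failures.append("end_self_comp")
    if m["max_run"] > c.max_contiguous:
        failures.append("contiguous")
    if m["dg_3p"] < c.min_dg_3p:
        failures.append("dg_3p")
    return SingleVerdict(not failures, m, tuple(failures))


def _passes_fast(seq: str, c: SingleConstraints, params: ThermoParams) -> dict | None:
    """Cheapest-first evaluation with early exit; returns metrics iff pass."""
    gc = gc_content(seq)
    if not (c.min_gc <= gc <= c.max_gc):
        return None
    run = max_contiguous_run(seq)
    if run > c.max_contiguous:
        return None
    tm = melting_temperature(seq, params)
    if not (c.min_tm <= tm <= c.max_tm):
        return None
    dg = delta_g_3prime(seq, params.dg_window, params)
    if dg < c.min_dg_3p:
        return None
    sc = self_complementarity(seq).score
    if sc > c.max_self_comp:
        return None
    esc = end_complementarity(seq, seq).score
    if esc > c.max_3p_self_comp:
        return None
    return {"tm": tm, "gc": gc, "self_comp": sc, "end_self_comp": esc,
            "max_run": run, "dg_3p": dg}


@dataclasses.dataclass
class Primer:
    """A unique 5'->3' primer string with its occurrences and metrics.

    ``occurrences`` are (sid, start, length) triples on the sense strand,
    sorted by (sid, start); ``target_sids`` is the set of sids appearing
    in the occurrence list.
    """

    primer_seq: str
    direction: str
    occurrences: list[tuple[int, int, int]]
    target_sids: frozenset[int]
    tm: float
    gc: float
    self_comp: int
    end_self_comp: int
    max_run: int
    dg_3p: float

    @property
    def length(self) -> int:
        return len(self.primer_seq)

    def key(self) -> tuple[str, str]:
        return (self.primer_seq, self.direction)


def collapse_to_primers(
    passing_sites: Iterable[tuple[CandidateSite, dict]],
) -> list[Primer]:
    """Group passing (site, metrics) by (sequence, direction) into Primers.

    Output is sorted by (direction, primer_seq) and each occurrence list
    by (sid, start) so the whole pipeline stays deterministic.
    """
    groups: dict[tuple[str, str], tuple[dict, list[tuple[int, int, int]]]] = {}
    for site, metrics in passing_sites:
        key = (site.primer_seq, site.direction)
        if key not in groups:
            groups[key] = (metrics, [])
        groups[key][1].append((site.sid, site.start, site.length))
    primers = []
    for (seq, direction), (metrics, occs) in sorted(groups.items()):
        occs.sort()
        primers.append(
            Primer(
                primer_seq=seq,
                direction=direction,
                occurrences=occs,
                target_sids=frozenset(sid for sid, _, _ in occs),
                **metrics,
            )
        )
    return primers


def filter_candidates(
    sites: Iterable[CandidateSite], c: SingleConstraints, params: ThermoParams
) -> list[Primer]:
    """Run the six single filters over a candidate stream and collapse.

    Metrics are computed once per unique (sequence, direction) string and
    reused for repeat occurrences.
    """
    cache: dict[str, dict | None] = {}
    passing: list[tuple[CandidateSite, dict]] = []
    for site in sites:
        m = cache.get(site.primer_seq, "miss")
        if m == "miss":
            m = _passes_fast(site.primer_seq, c, params)
            cache[site.primer_seq] = m
        if m is not None:
            passing.append((site, m))
    return collapse_to_primers(passing)
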