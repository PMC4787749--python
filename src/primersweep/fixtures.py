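"""Synthetic database generator with planted primer pairs and decoys.

Each planted pair gets its own host sequence: an engineered forward site
and reverse site separated so the amplicon length sits at the midpoint
of the product-size range.  Primers are built by rejection sampling so
they pass every single and pair constraint with near-minimal penalty
(composition at the GC midpoint, Tm close to the Tm midpoint, G/C on
both termini, low complementarity scores, an AT-leaning 3' interior for
a mild 3'-end dG).  Backgrounds, flanks and spacers are drawn AT-rich by
default so incidental background windows rarely survive the GC/Tm
filters and the planted pair ranks first for its sequence.

Decoys are copies of a planted forward primer carrying exactly ``h``
substitutions, embedded in a *different* sequence on the requested
strand.  Substitutions are placed at positions at or beyond the 5' zone,
so the 5' elimination rule never fires on them and the expected verdict
reduces to ``eliminated iff h <= K``.  The manifest records every
planted coordinate and verdict; its expectations are independently
confirmed against the brute-force specificity oracle in the test suite.

Substitution-only decoys (no indels) match the mismatch-count
cross-hybridization model; no attempt is made to emulate paralog
evolution or other realistic gene-family structure.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .candidate_gen import enumerate_candidates
from .crosshyb_filter import CrossHybParams
from .pair_builder import PairConstraints, build_pairs, pair_scores
from .ranking import rank_pairs
from .sequence_db import SequenceDB, reverse_complement, write_fasta
from .single_filter import SingleConstraints, check_single, filter_candidates
from .thermo import ThermoParams, melting_temperature

__all__ = ["FixtureSpec", "generate_db", "save_fixture"]

_MAX_ATTEMPTS = 50_000


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic database.

    ``seq_length`` is either an exact length or an inclusive (lo, hi)
    range; ``decoy_mismatches`` lists the Hamming distance of one decoy
    copy per planted pair each; ``background_gc`` is the G+C fraction of
    background/flank/spacer bases (AT-rich by default, see module docs).
    """

    n_sequences: int = 6
    seq_length: int | tuple[int, int] = (160, 240)
    n_planted_pairs: int = 1
    decoy_mismatches: tuple[int, ...] = ()
    decoy_strand: str = "sense"
    rng_seed: int = 0
    background_gc: float = 0.30

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if any(h < 0 for h in self.decoy_mismatches):
            raise ValueError("decoy mismatch distances must be >= 0")
        if self.decoy_strand not in ("sense", "antisense", "both"):
            raise ValueError(f"bad decoy_strand {self.decoy_strand!r}")
        if self.n_planted_pairs > 0 and self.decoy_mismatches and (
            self.n_sequences <= self.n_planted_pairs
        ):
            raise ValueError("decoys need at least one non-planted sequence")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


def _engineer_primer(
    rng: np.random.Generator,
    c: SingleConstraints,
    tp: ThermoParams,
    tm_tol: float = 0.3,
) -> str:
    """Rejection-sample one primer passing all single constraints with
    near-minimal penalty components."""
    tm_mid = (c.min_tm + c.max_tm) / 2.0
    gc_mid = (c.min_gc + c.max_gc) / 200.0  # fraction
    len_mid = (c.min_len + c.max_len) / 2.0
    # (length, GC count) combos ordered by how much length+GC penalty they
    # would add, so the first passing sample is near penalty-optimal
    combos = []
    for length in range(c.min_len, c.max_len + 1):
        for g in range(2, length + 1):
            len_pen = abs(length - len_mid) / max((c.max_len - c.min_len) / 2.0, 1e-9)
            gc_pen = abs(100.0 * g / length - (c.min_gc + c.max_gc) / 2.0)
            combos.append((len_pen + gc_pen / 15.0, length, g))
    combos.sort()
    del gc_mid
    fail_counts: dict[str, int] = {}
    attempts_per_combo = max(200, _MAX_ATTEMPTS // len(combos))
    total = 0
    for _, length, g_target in combos:
        interior = length - 2  # both termini fixed to G/C
        g_interior = g_target - 2
        if g_interior < 0 or g_interior > interior:
            continue
        for _ in range(attempts_per_combo):
            total += 1
            if total > _MAX_ATTEMPTS:
                break
            pool = ["G" if rng.random() < 0.5 else "C" for _ in range(g_interior)]
            pool += ["A" if rng.random() < 0.5 else "T" for _ in range(interior - g_interior)]
            pool = [pool[i] for i in rng.permutation(interior)]
            seq = (
                ("G" if rng.random() < 0.5 else "C")
                + "".join(pool)
                + ("G" if rng.random() < 0.5 else "C")
            )
            tm = melting_temperature(seq, tp)
            if abs(tm - tm_mid) > tm_tol:
                fail_counts["tm"] = fail_counts.get("tm", 0) + 1
                continue
            verdict = check_single(seq, c, tp)
            if not verdict.passed:
                for f in verdict.failures:
                    fail_counts[f] = fail_counts.get(f, 0) + 1
                continue
            m = verdict.metrics
            if m["self_comp"] > max(2, c.max_self_comp - 2):
                fail_counts["self_comp_margin"] = (
                    fail_counts.get("self_comp_margin", 0) + 1
                )
                continue
            if m["end_self_comp"] > max(1, c.max_3p_self_comp - 2):
                fail_counts["end_self_comp_margin"] = (
                    fail_counts.get("end_self_comp_margin", 0) + 1
                )
                continue
            if m["max_run"] > 3:
                fail_counts["run_margin"] = fail_counts.get("run_margin", 0) + 1
                continue
            return seq
        if total > _MAX_ATTEMPTS:
            break
    worst = max(fail_counts, key=fail_counts.get) if fail_counts else "unknown"
    raise RuntimeError(
        f"primer engineering exceeded {_MAX_ATTEMPTS} attempts; "
        f"most frequent blocker: {worst} (constraints too tight?)"
    )


def _single_pen(seq: str, c: SingleConstraints, tp: ThermoParams) -> float:
    """Seven-component penalty of one primer (used to pick best-of-N)."""
    from .ranking import component_penalty

    m = check_single(seq, c, tp).metrics
    return (
        component_penalty(len(seq), "range", c.min_len, c.max_len)
        + component_penalty(m["tm"], "range", c.min_tm, c.max_tm)
        + component_penalty(m["gc"], "range", c.min_gc, c.max_gc)
        + component_penalty(m["self_comp"], "cap", cap=c.max_self_comp)
        + component_penalty(m["end_self_comp"], "cap", cap=c.max_3p_self_comp)
        + component_penalty(m["max_run"], "cap", cap=c.max_contiguous)
        + component_penalty(abs(m["dg_3p"]), "cap", cap=abs(c.min_dg_3p))
    )


def _engineer_best_primer(
    rng: np.random.Generator,
    c: SingleConstraints,
    tp: ThermoParams,
    n_best: int = 12,
) -> str:
    """Sample several passing primers and keep the lowest-penalty one."""
    best_seq, best_pen = None, float("inf")
    for _ in range(n_best):
        seq = _engineer_primer(rng, c, tp)
        pen = _single_pen(seq, c, tp)
        if pen < best_pen:
            best_seq, best_pen = seq, pen
    assert best_seq is not None
    return best_seq


def _planted_is_rank1(
    seq: str, f: str, r: str, start_f: int, start_r: int,
    c: SingleConstraints, pc: PairConstraints, tp: ThermoParams,
) -> bool:
    """Run the per-sequence design stages on the host sequence alone and
    check the planted pair comes out rank 1.

    Pairing and penalties are per-sequence quantities and a planted
    primer's variants occur nowhere else, so this single-sequence check
    carries over to the full database.
    """
    db1 = SequenceDB.from_sequences([seq])
    primers = filter_candidates(
        enumerate_candidates(db1, c.min_len, c.max_len), c, tp
    )
    pairs = rank_pairs(build_pairs(primers, db1, pc, tp), c, pc)
    top = [p for p in pairs if p.rank == 1]
    if not top:
        return False
    t = top[0]
    return (
        t.start_f == start_f
        and t.start_r == start_r
        and t.forward.primer_seq == f
        and t.reverse.primer_seq == r
    )


_PAD = 6  # homopolymer pad around planted sites; > max_contiguous kills
          # most windows that straddle a planted primer boundary


def _padded(n: int, base: str, rng: np.random.Generator, gc: float) -> str:
    """Background stretch of length n ending in a homopolymer pad."""
    p = min(_PAD, n)
    return _rand_bases(rng, n - p, gc) + base * p


def _assemble_host(
    rng: np.random.Generator,
    gc: float,
    f: str,
    r: str,
    product: int,
    L: int,
    start_f: int,
) -> str:
    """[bg..AAAAAA] f [TTTTTT..bg..AAAAAA] revcomp(r) [TTTTTT..bg]."""
    spacer = product - len(f) - len(r)
    p1 = min(_PAD, spacer // 2)
    p2 = min(_PAD, spacer - p1)
    mid = "T" * p1 + _rand_bases(rng, spacer - p1 - p2, gc) + "A" * p2
    tail_n = L - start_f - product
    p3 = min(_PAD, tail_n)
    tail = "T" * p3 + _rand_bases(rng, tail_n - p3, gc)
    return _padded(start_f, "A", rng, gc) + f + mid + reverse_complement(r) + tail


def _plant_host(
    rng: np.random.Generator,
    spec: "FixtureSpec",
    c: SingleConstraints,
    pc: PairConstraints,
    tp: ThermoParams,
    product: int,
    lo_len: int,
    hi_len: int,
) -> tuple[str, str, str, int, int]:
    """Engineer one host sequence whose planted pair is rank 1.

    Draws a pool of low-penalty primers, walks (forward, reverse) combos
    in ascending estimated full-pair penalty, assembles the host sequence
    (planted sites padded with homopolymers so boundary-straddling
    variant windows fail the contiguous-run filter) and keeps the first
    combo whose planted pair tops the per-sequence ranking.
    Returns (sequence, forward, reverse, start_f, start_r).
    """
    min_needed = product + 4
    if hi_len < min_needed:
        raise ValueError(
            f"seq_length ({lo_len}, {hi_len}) cannot host product size {product}"
        )
    for _pool_round in range(4):
        pool = sorted(
            {_engineer_primer(rng, c, tp) for _ in range(14)},
            key=lambda s: _single_pen(s, c, tp),
        )
        pens = {s: _single_pen(s, c, tp) for s in pool}
        scored: list[tuple[float, int, int]] = []
        for i in range(len(pool)):
            for j in range(len(pool)):
                if i == j:
                    continue
                f, r = pool[i], pool[j]
                if product - len(f) - len(r) < 0:
                    continue
                if abs(len(f) - len(r)) > pc.max_len_diff:
                    continue
                tm_diff = abs(
                    melting_temperature(f, tp) - melting_temperature(r, tp)
                )
                if tm_diff > pc.max_tm_diff:
                    continue
                pcomp, epcomp = pair_scores(f, r)
                if pcomp > pc.max_pair_comp or epcomp > pc.max_3p_pair_comp:
                    continue
                est = (
                    pens[f] + pens[r]
                    + (pcomp / pc.max_pair_comp if pc.max_pair_comp else 0.0)
                    + (epcomp / pc.max_3p_pair_comp if pc.max_3p_pair_comp else 0.0)
                    + (tm_diff / pc.max_tm_diff if pc.max_tm_diff else 0.0)
                    + (abs(len(f) - len(r)) / pc.max_len_diff
                       if pc.max_len_diff else 0.0)
                )
                scored.append((est, i, j))
        scored.sort()
        for est, i, j in scored[:40]:
            f, r = pool[i], pool[j]
            L = int(rng.integers(max(lo_len, min_needed), hi_len + 1))
            start_f = int(rng.integers(1, L - product))
            start_r = start_f + product - len(r)
            seq = _assemble_host(rng, spec.background_gc, f, r, product, L, start_f)
            if _planted_is_rank1(seq, f, r, start_f, start_r, c, pc, tp):
                return seq, f, r, start_f, start_r
    raise RuntimeError(
        "could not assemble a host sequence whose planted pair ranks first; "
        "constraint profile leaves no penalty headroom"
    )


def _mutate(rng: np.random.Generator, seq: str, h: int, lo: int) -> str:
    """Exactly h substitutions at distinct positions in [lo, len)."""
    if h == 0:
        return seq
    if len(seq) - lo < h:
        raise ValueError(f"cannot place {h} mismatches in positions [{lo}, {len(seq)})")
    positions = rng.choice(np.arange(lo, len(seq)), size=h, replace=False)
    out = list(seq)
    for pos in positions:
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


def generate_db(
    spec: FixtureSpec,
    c: SingleConstraints | None = None,
    pc: PairConstraints | None = None,
    tp: ThermoParams | None = None,
    xh: CrossHybParams | None = None,
) -> tuple[SequenceDB, pd.DataFrame]:
    """Build a synthetic database and its plant manifest.

    Returns ``(db, manifest)``; the manifest has one row per planted
    element (forward site, reverse site, decoy copy) with columns
    pair_index, role, sid, start, length, strand, primer_seq,
    mismatches, expected_verdict.  The verdict states whether the
    planted forward primer survives the specificity screen at
    K = ``xh.max_general_mismatch``.
    """
    c = c or SingleConstraints()
    pc = pc or PairConstraints()
    tp = tp or ThermoParams()
    xh = xh or CrossHybParams()
    rng = np.random.default_rng(spec.rng_seed)

    if isinstance(spec.seq_length, int):
        lo_len = hi_len = spec.seq_length
    else:
        lo_len, hi_len = spec.seq_length

    product = (pc.min_product + pc.max_product) // 2
    rows: list[dict] = []
    sequences: list[str] = [""] * spec.n_sequences

    planted: list[tuple[str, str]] = []
    for i in range(spec.n_planted_pairs):
        seq, f, r, start_f, start_r = _plant_host(
            rng, spec, c, pc, tp, product, lo_len, hi_len
        )
        planted.append((f, r))
        sequences[i] = seq
        eliminated = any(h <= xh.max_general_mismatch for h in spec.decoy_mismatches)
        verdict = "eliminated" if eliminated else "retained"
        rows.append(dict(pair_index=i, role="forward", sid=i, start=start_f,
                         length=len(f), strand="sense", primer_seq=f,
                         mismatches=0, expected_verdict=verdict))
        rows.append(dict(pair_index=i, role="reverse", sid=i, start=start_r,
                         length=len(r), strand="sense", primer_seq=r,
                         mismatches=0, expected_verdict="retained"))

    # decoys: one copy per (pair, h), each in a non-planted sequence
    decoy_content: dict[int, list[tuple[int, str, str, int]]] = {}
    n_bg = spec.n_sequences - spec.n_planted_pairs
    counter = 0
    for i, (f, _r) in enumerate(planted):
        for h in spec.decoy_mismatches:
            mutated = _mutate(rng, f, h, min(xh.five_prime_zone, len(f)))
            if spec.decoy_strand == "both":
                strand = "sense" if counter % 2 == 0 else "antisense"
            else:
                strand = spec.decoy_strand
            target_sid = spec.n_planted_pairs + (counter % n_bg)
            decoy_content.setdefault(target_sid, []).append((i, mutated, strand, h))
            counter += 1

    for sid in range(spec.n_planted_pairs, spec.n_sequences):
        L = int(rng.integers(lo_len, hi_len + 1))
        seq = _rand_bases(rng, L, spec.background_gc)
        for pair_index, mutated, strand, h in decoy_content.get(sid, []):
            insert = mutated if strand == "sense" else reverse_complement(mutated)
            if len(seq) < len(insert) + 2:
                raise ValueError("sequence too short to host a decoy")
            pos = int(rng.integers(1, len(seq) - len(insert)))
            seq = seq[:pos] + insert + seq[pos + len(insert):]
            rows.append(dict(
                pair_index=pair_index, role="decoy", sid=sid, start=pos,
                length=len(insert), strand=strand, primer_seq=mutated,
                mismatches=h,
                expected_verdict=(
                    "eliminated" if h <= xh.max_general_mismatch else "retained"
                ),
            ))
        sequences[sid] = seq

    db = SequenceDB.from_sequences(
        sequences,
        name=f"fixture_seed{spec.rng_seed}",
        accessions=[f"synthetic_{i:03d}" for i in range(spec.n_sequences)],
    )
    manifest = pd.DataFrame(
        rows,
        columns=["pair_index", "role", "sid", "start", "length", "strand",
                 "primer_seq", "mismatches", "expected_verdict"],
    )
    return db, manifest


def save_fixture(
    db: SequenceDB, manifest: pd.DataFrame, fasta_path: str | Path,
    manifest_path: str | Path,
) -> None:
    """Write the FASTA and the TSV manifest side by side."""
    write_fasta(db, fasta_path)
    manifest.to_csv(manifest_path, sep="\t", index=False)
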