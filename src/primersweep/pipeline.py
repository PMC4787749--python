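"""End-to-end orchestration: enumerate, filter, pair, rank, report.

The seven-stage flow mirrors a map/shuffle/reduce dataflow as explicit
group-by stages over iterators: candidate windows are streamed, single
filtering collapses identical primer strings across sequences, the
specificity screen joins primers to off-target windows through shared
seed keys, pairing groups survivors per source sequence, and ranking
sorts within each sequence.

``run_pipeline`` is the production path; ``run_oracle`` runs the same
contract entirely on the naive reference implementations and exists for
verification.  Both quantize penalties to 1e-12 before ranking so that
analytically-tied pairs break ties on coordinates identically in either
path.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import oracle as _oracle
from .candidate_gen import enumerate_candidates
from .crosshyb_filter import CrossHybParams, brute_force_crosshyb, run_crosshyb
from .pair_builder import PairConstraints, PrimerPair, build_pairs, pair_scores
from .ranking import PenaltyWeights, rank_pairs
from .sequence_db import SequenceDB, read_fasta, reverse_complement
from .single_filter import SingleConstraints, filter_candidates, primer_metrics
from .thermo import ThermoParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_oracle",
           "pairs_to_table", "write_table", "check_table", "load_config"]

TABLE_COLUMNS = [
    "sid", "accession", "rank", "forward_seq", "reverse_seq", "start_f",
    "start_r", "product_size", "tm_f", "tm_r", "gc_f", "gc_r", "penalty",
    "covered_sids",
]

_PENALTY_DECIMALS = 12


@dataclasses.dataclass
class RunConfig:
    """Validated bundle of all pipeline inputs."""

    fasta: str | Path | None = None
    db: SequenceDB | None = None
    single: SingleConstraints = dataclasses.field(default_factory=SingleConstraints)
    crosshyb: CrossHybParams = dataclasses.field(default_factory=CrossHybParams)
    pair: PairConstraints = dataclasses.field(default_factory=PairConstraints)
    weights: PenaltyWeights = dataclasses.field(default_factory=PenaltyWeights)
    thermo: ThermoParams = dataclasses.field(default_factory=ThermoParams)
    top_n: int | None = None
    output: str | Path | None = None

    def resolve_db(self) -> SequenceDB:
        if self.db is not None:
            return self.db
        if self.fasta is None:
            raise ValueError("config must provide a FASTA path or a SequenceDB")
        return read_fasta(self.fasta)


_SECTIONS = {
    "single": SingleConstraints,
    "crosshyb": CrossHybParams,
    "pair": PairConstraints,
    "weights": PenaltyWeights,
}
_TOP_KEYS = {"fasta", "top_n", "output", "single", "crosshyb", "pair", "weights",
             "thermo"}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("fasta", "top_n", "output"):
        if key in raw:
            kwargs[key] = raw[key]
    for section, cls in _SECTIONS.items():
        if section in raw:
            fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(raw[section]) - fields
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            kwargs[section] = cls(**raw[section])
    if "thermo" in raw:
        fields = {f.name for f in dataclasses.fields(ThermoParams)}
        bad = set(raw["thermo"]) - fields
        if bad:
            raise ValueError(f"unknown keys in [thermo]: {sorted(bad)}")
        kwargs["thermo"] = ThermoParams(**raw["thermo"])
    return RunConfig(**kwargs)


@dataclasses.dataclass
class PipelineResult:
    pairs: list[PrimerPair]
    table: pd.DataFrame
    report: dict


def _quantize(pairs: list[PrimerPair]) -> None:
    for p in pairs:
        p.penalty = round(p.penalty, _PENALTY_DECIMALS)


def _rerank_quantized(pairs: list[PrimerPair]) -> list[PrimerPair]:
    by_sid: dict[int, list[PrimerPair]] = {}
    for p in pairs:
        by_sid.setdefault(p.sid, []).append(p)
    out = []
    for sid in sorted(by_sid):
        group = sorted(by_sid[sid], key=lambda q: (q.penalty,) + q.sort_key())
        for rank, p in enumerate(group, start=1):
            p.rank = rank
        out.extend(group)
    return out


def pairs_to_table(pairs: list[PrimerPair], db: SequenceDB) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "sid": p.sid,
            "accession": db[p.sid].accession,
            "rank": p.rank,
            "forward_seq": p.forward.primer_seq,
            "reverse_seq": p.reverse.primer_seq,
            "start_f": p.start_f,
            "start_r": p.start_r,
            "product_size": p.product_size,
            "tm_f": round(p.forward.tm, 4),
            "tm_r": round(p.reverse.tm, 4),
            "gc_f": round(p.forward.gc, 4),
            "gc_r": round(p.reverse.gc, 4),
            "penalty": p.penalty,
            "covered_sids": ";".join(
                db[s].accession for s in sorted(p.covered_sids)
            ),
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all seven stages; always succeeds on valid input, even
    when zero pairs survive (an empty table is a valid outcome)."""
    db = cfg.resolve_db()
    report: dict = {"n_sequences": len(db)}

    sites = list(enumerate_candidates(db, cfg.single.min_len, cfg.single.max_len))
    report["candidates"] = len(sites)
    logger.info("candidate generation: %d sites", len(sites))

    primers = filter_candidates(sites, cfg.single, cfg.thermo)
    report["after_single_filter"] = len(primers)
    logger.info("single filtering: %d unique primers", len(primers))

    survivors, xh_counts = run_crosshyb(primers, db, cfg.crosshyb)
    report.update(xh_counts)
    logger.info("specificity screen: %d primers survive", len(survivors))

    pairs = build_pairs(survivors, db, cfg.pair, cfg.thermo)
    report["pairs_built"] = len(pairs)

    pairs = rank_pairs(pairs, cfg.single, cfg.pair, cfg.weights)
    _quantize(pairs)
    pairs = _rerank_quantized(pairs)
    report["pairs_ranked"] = len(pairs)

    if cfg.top_n is not None:
        pairs = [p for p in pairs if p.rank <= cfg.top_n]
        report["pairs_reported"] = len(pairs)

    table = pairs_to_table(pairs, db)
    if cfg.output is not None:
        write_table(table, cfg.output)
    _log_report(report)
    return PipelineResult(pairs, table, report)


def run_oracle(cfg: RunConfig) -> PipelineResult:
    """Same contract as :func:`run_pipeline`, computed end to end with
    the naive reference implementations (desk-scale inputs only)."""
    db = cfg.resolve_db()
    report: dict = {"n_sequences": len(db)}
    sites = _oracle.naive_enumerate(db, cfg.single.min_len, cfg.single.max_len)
    report["candidates"] = len(sites)
    primers = _oracle.naive_single_filter(sites, cfg.single, cfg.thermo)
    report["after_single_filter"] = len(primers)
    survivors = brute_force_crosshyb(primers, db, cfg.crosshyb)
    report["after_crosshyb"] = len(survivors)
    pairs = _oracle.naive_build_pairs(survivors, db, cfg.pair, cfg.thermo)
    report["pairs_built"] = len(pairs)
    for p in pairs:
        p.penalty = _oracle.naive_pair_penalty(p, cfg.single, cfg.pair, cfg.weights)
    _quantize(pairs)
    pairs = _rerank_quantized(pairs)
    report["pairs_ranked"] = len(pairs)
    if cfg.top_n is not None:
        pairs = [p for p in pairs if p.rank <= cfg.top_n]
    table = pairs_to_table(pairs, db)
    if cfg.output is not None:
        write_table(table, cfg.output)
    return PipelineResult(pairs, table, report)


def _log_report(report: dict) -> None:
    for key, value in report.items():
        logger.info("report: %s = %s", key, value)


def check_table(
    table: pd.DataFrame, db: SequenceDB, cfg: RunConfig
) -> list[str]:
    """Soundness audit of an output table: recompute every single and
    pair constraint from scratch; return a list of violation messages
    (empty = clean)."""
    violations: list[str] = []
    c, pc, tp = cfg.single, cfg.pair, cfg.thermo
    for idx, row in table.iterrows():
        tag = f"row {idx} (sid {row.sid})"
        fseq, rseq = row.forward_seq, row.reverse_seq
        seq = db[int(row.sid)].sequence
        start_f, start_r = int(row.start_f), int(row.start_r)
        product = int(row.product_size)
        amplicon = seq[start_f : start_f + product]
        if not amplicon.startswith(fseq):
            violations.append(f"{tag}: forward primer not at start_f")
        if not amplicon.endswith(reverse_complement(rseq)):
            violations.append(f"{tag}: reverse site mismatch at amplicon end")
        if start_f + len(fseq) > start_r:
            violations.append(f"{tag}: overlapping binding sites")
        for label, s in (("forward", fseq), ("reverse", rseq)):
            if not (c.min_len <= len(s) <= c.max_len):
                violations.append(f"{tag}: {label} length out of range")
            m = primer_metrics(s, tp)
            if not (c.min_tm <= m["tm"] <= c.max_tm):
                violations.append(f"{tag}: {label} Tm {m['tm']:.2f} out of range")
            if not (c.min_gc <= m["gc"] <= c.max_gc):
                violations.append(f"{tag}: {label} GC out of range")
            if m["self_comp"] > c.max_self_comp:
                violations.append(f"{tag}: {label} self-complementarity")
            if m["end_self_comp"] > c.max_3p_self_comp:
                violations.append(f"{tag}: {label} 3'-end self-complementarity")
            if m["max_run"] > c.max_contiguous:
                violations.append(f"{tag}: {label} contiguous run")
            if m["dg_3p"] < c.min_dg_3p:
                violations.append(f"{tag}: {label} 3'-end dG too stable")
        fm = primer_metrics(fseq, tp)
        rm = primer_metrics(rseq, tp)
        if abs(len(fseq) - len(rseq)) > pc.max_len_diff:
            violations.append(f"{tag}: length difference")
        if abs(fm["tm"] - rm["tm"]) > pc.max_tm_diff:
            violations.append(f"{tag}: Tm difference")
        if not (pc.min_product <= product <= pc.max_product):
            violations.append(f"{tag}: product size out of range")
        pcomp, epcomp = pair_scores(fseq, rseq)
        if pcomp > pc.max_pair_comp:
            violations.append(f"{tag}: pair-complementarity")
        if epcomp > pc.max_3p_pair_comp:
            violations.append(f"{tag}: 3'-end pair-complementarity")
    return violations
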