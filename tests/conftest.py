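"""Shared fixtures: constraint profiles and a bank of seeded synthetic
databases reused across the equivalence and audit tests.

The test profile deliberately differs from the library defaults (the
suite must not depend on them): the Tm window is centered where
mid-GC 20-24-mers actually melt, and product sizes fit the 100-300 bp
synthetic sequences.
"""

from __future__ import annotations

import pytest

from primersweep import (
    CrossHybParams,
    FixtureSpec,
    PairConstraints,
    RunConfig,
    SingleConstraints,
    ThermoParams,
    generate_db,
    run_oracle,
    run_pipeline,
)

N_BANK = 20


def make_single() -> SingleConstraints:
    return SingleConstraints(
        min_len=19, max_len=24, min_tm=58.0, max_tm=62.0,
        min_gc=35.0, max_gc=65.0, max_self_comp=12, max_3p_self_comp=8,
        max_contiguous=4, min_dg_3p=-9.0,
    )


def make_pair() -> PairConstraints:
    return PairConstraints(
        max_len_diff=3, max_tm_diff=2.0, min_product=70, max_product=140,
        max_pair_comp=12, max_3p_pair_comp=8,
    )


@pytest.fixture(scope="session")
def single_c() -> SingleConstraints:
    return make_single()


@pytest.fixture(scope="session")
def pair_c() -> PairConstraints:
    return make_pair()


@pytest.fixture(scope="session")
def tp() -> ThermoParams:
    return ThermoParams()


@pytest.fixture(scope="session")
def xh() -> CrossHybParams:
    return CrossHybParams()  # 5' zone 4/4 mismatches, K = 2


_DECOY_CYCLE = [(), (1,), (2,), (3,), (2, 3)]
_STRAND_CYCLE = ["sense", "antisense", "both"]


def bank_spec(seed: int) -> FixtureSpec:
    return FixtureSpec(
        n_sequences=5 + (seed * 3) % 16,
        seq_length=(100, 300),
        n_planted_pairs=1,
        decoy_mismatches=_DECOY_CYCLE[seed % len(_DECOY_CYCLE)],
        decoy_strand=_STRAND_CYCLE[seed % len(_STRAND_CYCLE)],
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def bank(single_c, pair_c, tp, xh):
    """20 seeded synthetic databases (5-20 sequences x 100-300 bp) with
    one planted pair each and a rotating decoy layout."""
    entries = []
    for seed in range(N_BANK):
        spec = bank_spec(seed)
        db, manifest = generate_db(spec, single_c, pair_c, tp, xh)
        cfg = RunConfig(db=db, single=single_c, pair=pair_c, thermo=tp,
                        crosshyb=xh)
        entries.append({"seed": seed, "spec": spec, "db": db,
                        "manifest": manifest, "cfg": cfg})
    return entries


@pytest.fixture(scope="session")
def bank_design(bank):
    """Production pipeline results for every bank database."""
    return {e["seed"]: run_pipeline(e["cfg"]) for e in bank}


@pytest.fixture(scope="session")
def bank_oracle(bank):
    """Brute-force reference pipeline results for every bank database."""
    return {e["seed"]: run_oracle(e["cfg"]) for e in bank}


def pair_key(p):
    return (p.sid, p.start_f, p.start_r, p.forward.primer_seq,
            p.reverse.primer_seq)
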