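"""Nearest-neighbor thermodynamics and ungapped complementarity scoring.

Duplex stability is modelled by summing per-stacked-dinucleotide enthalpy
and entropy terms plus duplex-initiation corrections for the two terminal
base pairs.  The melting temperature of a primer at total strand
concentration :math:`C_T` is

.. math::

    T_m = \\frac{\\Delta H \\times 1000}
               {\\Delta S + 0.368\\,(m-1)\\ln[\\mathrm{Na}^+] + R \\ln(C_T/4)}
          - 273.15

with :math:`\\Delta H` in kcal/mol, :math:`\\Delta S` in cal/(mol K),
R = 1.9872 cal/(mol K), and the entropy-based monovalent salt correction
applied per stack.  The shipped parameter table is the unified DNA/DNA
set (see ``data/nn_unified.tsv``); any table with the same layout can be
swapped in through :class:`ThermoParams`.

Complementarity scores are integer counts of Watson-Crick complementary
positions in the best ungapped anti-parallel alignment register.  They
deliberately use no partial weights so that thresholds stay interpretable
and an exhaustive-register oracle can check them exactly.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import NamedTuple

__all__ = [
    "ThermoParams",
    "ComplementarityScore",
    "load_nn_table",
    "melting_temperature",
    "delta_g_3prime",
    "self_complementarity",
    "end_complementarity",
    "pair_complementarity",
]

R_GAS = 1.9872  # cal / (mol K)
_ACGT = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_NN_TABLE = "nn_unified.tsv"


def load_nn_table(path: str | Path | None = None):
    """Load a nearest-neighbor table (stack/terminal, dH, dS per line).

    Returns ``(nn_dh, nn_ds, init_dh, init_ds)`` dicts.  ``None`` loads the
    packaged unified table.
    """
    if path is None:
        text = (
            resources.files("primersweep").joinpath("data", DEFAULT_NN_TABLE)
        ).read_text()
    else:
        text = Path(path).read_text()
    nn_dh: dict[str, float] = {}
    nn_ds: dict[str, float] = {}
    init_dh: dict[str, float] = {}
    init_ds: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split()
        if key.startswith("init_"):
            init_dh[key[5:]] = float(dh)
            init_ds[key[5:]] = float(ds)
        else:
            nn_dh[key] = float(dh)
            nn_ds[key] = float(ds)
    missing = {a + b for a in "ACGT" for b in "ACGT"} - nn_dh.keys()
    if missing:
        raise ValueError(f"NN table incomplete, missing stacks: {sorted(missing)}")
    if set(init_dh) != set("ACGT"):
        raise ValueError("NN table must define init_A/init_C/init_G/init_T")
    return nn_dh, nn_ds, init_dh, init_ds


def _default_tables():
    return load_nn_table(None)


@dataclasses.dataclass
class ThermoParams:
    """Thermodynamic model parameters.

    monovalent_salt in mol/L, primer_conc is the total oligo concentration
    C_T in mol/L (the ln term uses C_T/4, the non-self-complementary
    convention), temperature_for_dG in Kelvin.
    """

    nn_dh: dict = dataclasses.field(default_factory=dict)
    nn_ds: dict = dataclasses.field(default_factory=dict)
    init_dh: dict = dataclasses.field(default_factory=dict)
    init_ds: dict = dataclasses.field(default_factory=dict)
    monovalent_salt: float = 0.050
    primer_conc: float = 50e-9
    temperature_for_dG: float = 310.15
    dg_window: int = 5
    table_name: str = DEFAULT_NN_TABLE

    def __post_init__(self) -> None:
        if not self.nn_dh:
            self.nn_dh, self.nn_ds, self.init_dh, self.init_ds = _default_tables()
        for a in "ACGT":
            for b in "ACGT":
                st = a + b
                rc = _COMPLEMENT[b] + _COMPLEMENT[a]
                if not math.isclose(self.nn_dh[st], self.nn_dh[rc]):
                    raise ValueError(f"NN table violates strand symmetry at {st}/{rc}")
        if self.monovalent_salt <= 0 or self.primer_conc <= 0:
            raise ValueError("salt and primer concentrations must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoParams":
        return cls(**d)


class ComplementarityScore(NamedTuple):
    """Best ungapped anti-parallel complementarity count and its register."""

    score: int
    offset: int


def _check_acgt(seq: str, minlen: int = 1) -> None:
    if len(seq) < minlen:
        raise ValueError(f"sequence too short (need >= {minlen}): {seq!r}")
    if set(seq) - _ACGT:
        raise ValueError(f"non-ACGT character in {seq!r}")


def melting_temperature(seq: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius."""
    if params is None:
        params = ThermoParams()
    _check_acgt(seq, minlen=2)
    dh = params.init_dh[seq[0]] + params.init_dh[seq[-1]]
    ds = params.init_ds[seq[0]] + params.init_ds[seq[-1]]
    nn_dh, nn_ds = params.nn_dh, params.nn_ds
    for i in range(len(seq) - 1):
        st = seq[i : i + 2]
        dh += nn_dh[st]
        ds += nn_ds[st]
    ds += 0.368 * (len(seq) - 1) * math.log(params.monovalent_salt)
    ct4 = params.primer_conc / 4.0
    return (dh * 1000.0) / (ds + R_GAS * math.log(ct4)) - 273.15


def delta_g_3prime(
    seq: str, window: int | None = None, params: ThermoParams | None = None
) -> float:
    """Stacking free energy (kcal/mol) of the 3'-terminal window.

    Sums dG = dH - T*dS over the stacks fully inside the last ``window``
    bases, with the salt-corrected entropy, at ``params.temperature_for_dG``.
    No initiation terms are included, so ``window = len(seq)`` gives the
    whole-duplex stacking dG under the same definition.  More negative
    means a more stable 3' end.
    """
    if params is None:
        params = ThermoParams()
    if window is None:
        window = params.dg_window
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    _check_acgt(seq, minlen=2)
    tail = seq[-window:]
    T = params.temperature_for_dG
    salt_ds = 0.368 * math.log(params.monovalent_salt)
    dg = 0.0
    for i in range(len(tail) - 1):
        st = tail[i : i + 2]
        dg += params.nn_dh[st] - T * (params.nn_ds[st] + salt_ds) / 1000.0
    return dg


def pair_complementarity(seq1: str, seq2: str) -> ComplementarityScore:
    """Best Watson-Crick complementary-position count over all ungapped
    anti-parallel registers of seq1 against seq2."""
    _check_acgt(seq1)
    _check_acgt(seq2)
    return _best_register(seq1, seq2, anchor_3p=False)


def self_complementarity(seq: str) -> ComplementarityScore:
    """Self-annealing score: ``pair_complementarity(seq, seq)``."""
    _check_acgt(seq)
    return _best_register(seq, seq, anchor_3p=False)


def end_complementarity(seq1: str, seq2: str) -> ComplementarityScore:
    """Like :func:`pair_complementarity` but restricted to registers in
    which the 3'-terminal base of ``seq1`` is paired."""
    _check_acgt(seq1)
    _check_acgt(seq2)
    return _best_register(seq1, seq2, anchor_3p=True)


def _best_register(seq1: str, seq2: str, anchor_3p: bool) -> ComplementarityScore:
    # Anti-parallel alignment: lay seq2 reversed (3'->5') under seq1 and
    # slide.  At shift s, column i of seq1 faces r2[i - s].
    n1, n2 = len(seq1), len(seq2)
    r2 = seq2[::-1]
    comp1 = [_COMPLEMENT[c] for c in seq1]
    if anchor_3p:
        # the column of seq1's last base must lie inside the overlap
        shifts = range(max(n1 - n2, -(n2 - 1)), n1)
    else:
        shifts = range(-(n2 - 1), n1)
    best, best_s = -1, 0
    for s in shifts:
        lo = max(0, s)
        hi = min(n1, s + n2)
        if anchor_3p and not (lo <= n1 - 1 < hi):
            continue
        score = 0
        for i in range(lo, hi):
            if comp1[i] == r2[i - s]:
                score += 1
        if score > best:
            best, best_s = score, s
    if best < 0:
        raise ValueError("no valid alignment register")
    return ComplementarityScore(best, best_s)
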