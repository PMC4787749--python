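# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `primersweep`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Thermodynamic model

Duplex stability uses the nearest-neighbor model: enthalpy and entropy are
sums of per-stacked-dinucleotide terms plus initiation corrections for the
two terminal base pairs. The shipped table (`data/nn_unified.tsv`) is the
unified DNA/DNA parameter set at 1 M NaCl (ΔH in kcal/mol, ΔS in
cal/mol·K, terminal A·T initiation +2.3/+4.1, terminal G·C +0.1/−2.8). Any
table in the same three-column layout can be swapped in via
`ThermoParams`; construction validates that all 16 stacks are present and
satisfy the strand-symmetry identity (a stack equals its reverse-complement
stack).

Melting temperature:

    Tm = 1000·ΔH / (ΔS + 0.368·(m−1)·ln[Na+] + R·ln(C_T/4)) − 273.15

* Monovalent salt correction is entropy-based, 0.368·ln[Na⁺] per stack.
* Defaults: [Na⁺] = 50 mM, total oligo concentration C_T = 50 nM with the
  C_T/4 convention for non-self-complementary duplexes, R = 1.9872
  cal/(mol·K). These are conventional qPCR assay values; the model source
  does not pin concentrations, so both are configuration-exposed.
* The implementation is regression-tested against constants produced by an
  independent hand summation of the table, and cross-checked against
  Biopython's `Tm_NN` with the same table and corrections (agreement to
  < 0.01 °C; the residual comes from Biopython's R = 1.987).

3′-end stability: ΔG = Σ (ΔH − T·ΔS_salt-corrected) over the stacks fully
inside the 3′-terminal window, at T = 310.15 K, default window 5 bases.
No initiation terms are included, so the window = m case is exactly the
whole-duplex stacking ΔG under the same definition. The constraint
`min_dg_3p` is a lower bound: a 3′ end more negative (more stable) than it
fails, since over-stable 3′ ends promote mispriming. Treating the ΔG
filter as a 3′-window quantity rather than whole-duplex free energy was a
design choice; the whole-duplex alternative is available by setting the
window to the primer length.

## Complementarity scoring

Self-, pair- and 3′-end complementarity are integer counts of Watson–Crick
complementary positions in the best ungapped anti-parallel register — no
gaps, no partial weights, no mismatch penalties. This makes thresholds
directly interpretable ("at most s complementary bases") and lets an
exhaustive all-registers oracle check the implementation exactly. The
3′-end variant restricts the maximization to registers in which the
anchored primer's 3′-terminal base is paired; for a pair, the score is the
larger of the two anchor orders, since either extendable 3′ end can prime
a dimer.

Because the count scheme has no negative terms, its scale differs from
Primer3-style local-alignment scores: random Tm-passing 20–24-mers score
a median of 8–10 against themselves. The shipped defaults
(`max_self_comp` 12, `max_3p_self_comp` 8, and the same for pairs) were
calibrated to that scale so the default profile is satisfiable; profiles
ported from alignment-scored tools must be rescaled, not copied.

## Candidate generation and coordinates

Coordinates are 0-based, half-open `[start, end)` on the sense strand
everywhere. Reverse candidates are generated by reverse-complementing the
sense window, keeping a single coordinate system; product size is
`(start_r + len_r) − start_f`, the standard amplicon length from the
forward primer's 5′ end through the far end of the reverse binding site.
Overlapping forward/reverse binding sites are rejected.

Sequences are upper-cased at ingest with U→T; IUPAC ambiguity codes
collapse to N. Windows containing N are excluded from candidate
generation, but full sequences (N included) are retained for off-target
scanning where N matches nothing — the conservative choice for
specificity, since the filters are defined only over ACGT.

## Specificity screen

A sequence is a *target* of a primer if the primer string occurs in it
exactly on either strand; all other sequences are off-target. An exact
duplicate elsewhere therefore marks an additional target (the primer is
multi-target), never an elimination — the only reading under which both
single-target and multi-target primers can be reported.

Two elimination rules, both scanning both strands of every off-target
sequence:

* **5′ rule** (default zone 4, up to 4 mismatches): eliminates a primer
  when an off-target window is exact beyond the 5′ zone and differs in at
  most `max_5p_mismatch` places inside it. The mismatch budget and the
  zone width are separate knobs conflated by default, because the
  underlying rule ("up to four mismatches at the 5′ end") does not
  distinguish them.
* **General rule** (default K = 2): eliminates a primer with any off-target
  window at Hamming distance ≤ k, iterated k = 1..K. Candidate
  (primer, window) pairs are discovered only through shared pigeonhole
  seeds — k+1 contiguous blocks, the first k of length ⌊m/(k+1)⌋, the last
  absorbing the remainder (any contiguous partition preserves the bound) —
  and verified by a full Hamming count. Verdicts are aggregated across all
  seed groups before elimination, so the outcome is grouping-independent,
  and since elimination is an existential condition, the iterative
  schedule equals a single pass at k = K (both are tested); the iteration
  is kept for interpretable per-k survivor logs.

`brute_force_crosshyb` applies both rules by scanning every window of
every off-target sequence literally (vectorized with numpy) and is the
oracle the seed-based path is tested against, exactly, for k = 0..4.

## Penalty and ranking

Nineteen components: seven per primer (length, Tm, GC,
self-complementarity, 3′-end self-complementarity, contiguous run, 3′ ΔG)
and five per pair (length difference, Tm difference, product size,
pair-complementarity, 3′-end pair-complementarity). Range-type components
(length, Tm, GC, product size) score `|v − mid| / half_width`; cap-type
components score `v / cap`; the ΔG component uses magnitudes,
`|ΔG| / |min_dg_3p|`, so less stable 3′ ends score lower. All components
clamp to [0, 1]; degenerate ranges and zero caps score 0. Weights default
to 1 and are configuration-exposed; no attempt is made to reproduce any
particular external tool's numeric weighting, only the additive
normalized-per-constraint shape.

Ranks are dense (1..n) within each source sequence, ascending by penalty.
Penalties are quantized to 1e−12 before ranking so that analytically tied
pairs break ties identically in the production and reference paths; ties
then break by (start_f, start_r, forward string, reverse string), making
output order independent of input order.

## Synthetic databases

The fixture generator exists so every stage is testable without external
downloads. It emulates: (a) background sequence as i.i.d. bases with a
configurable GC fraction (default 0.30, AT-leaning); (b) one engineered
primer pair per host sequence, placed so the amplicon sits at the
product-size midpoint; (c) decoys — copies of a planted forward primer
with exactly h substitutions — embedded in other sequences on either
strand.

Planted primers are built by rejection sampling over (length, GC-count)
compositions ordered by penalty impact, with G/C termini, Tm within
0.3 °C of the window midpoint, and margins on the complementarity/run
scores; the final (forward, reverse) combo is chosen by walking candidate
combos in ascending estimated pair penalty and keeping the first whose
planted pair ranks first in a single-sequence dry run of the design
stages. Planted sites are flanked by 6-base homopolymer pads, so windows
straddling a site boundary fail the contiguous-run filter — this thins the
cloud of near-variant competitors that any good primer site necessarily
generates. Decoy substitutions are placed at positions at or beyond the 5′
zone, so the 5′ rule never fires on them and the expected verdict is
simply h ≤ K; the manifest records coordinates and verdicts, which the
test suite confirms against the brute-force oracle (an independent code
path).

What the generator does **not** emulate: paralog families with realistic
evolutionary divergence, splice isoforms, repeat structure, biased
composition along a sequence, or indel-type similarity. Passing tests
demonstrate algorithmic correctness of filtering, screening and ranking —
not wet-lab primer performance on real transcriptomes.

## Problem sizes and numerics

The verification suite runs on seeded banks of 5–20 sequences of
100–300 bp — large enough that every stage (including the seed join and
both strands) is exercised, small enough that the literal brute-force
reference stays cheap; `scripts/acceptance.py` uses six such databases
plus dedicated decoy sweeps. Determinism: the pipeline has no randomness;
fixture generation is fully determined by its integer seed; hypothesis
property tests run derandomized.

## Known limitations

* Cross-hybridization is mismatch-count based; no gapped/indel similarity
  and no thermodynamic off-target binding energy.
* No hairpin folding beyond the complementarity counts; no dangling-end or
  mismatch nearest-neighbor parameters.
* No exon–exon junction or genomic-context awareness (inputs are treated
  as mRNA/CDS-style sequences).
* Single-machine execution only; the grouped-join dataflow is preserved as
  explicit group-by stages, but there is no distributed backend.
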