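# primersweep

Exhaustive, specificity-checked design of ranked qPCR primer pairs over a
nucleotide FASTA database.

## The problem

Designing primers for quantitative PCR means satisfying many constraints at
once — length, melting temperature (Tm), GC content, self- and
pair-complementarity, 3′-end stability, product size — *and* verifying that
each primer cannot anneal to any off-target sequence in the database
(cross-hybridization). Tools that handle rich constraint profiles typically
skip the homology check, and vice versa, so panel-scale design (hundreds of
targets under one uniform profile) is tedious and error-prone.

`primersweep` takes the exhaustive route: it enumerates **every**
subsequence of every database sequence within the length window, in both
orientations, filters the candidates through thermodynamic and composition
constraints, eliminates any primer that resembles an off-target subsequence,
joins the survivors into forward/reverse pairs per source sequence, and
ranks the pairs by a normalized additive penalty so the top-1 pair per
target is the recommended choice. No multiple sequence alignment, no
heuristics, no missed primers.

## Method

The pipeline runs seven stages:

1. **Candidate generation** — all windows with `min_len ≤ ℓ ≤ max_len`,
   each emitted as a forward primer (the window) and a reverse primer (its
   reverse complement). Windows containing `N` are skipped.
2. **Single filtering** — six per-primer constraints: Tm, GC%,
   self-complementarity, 3′-end self-complementarity, longest contiguous
   run, and 3′-end ΔG. Tm follows the nearest-neighbor model,

   Tm = ΔH·1000 / (ΔS + 0.368(m−1)·ln[Na⁺] + R·ln(C_T/4)) − 273.15,

   with the unified ΔH/ΔS dinucleotide table shipped as a plain-text data
   file. Surviving identical strings collapse into unique primers carrying
   occurrence lists, which is what makes multi-target primers first-class.
3. **5′ cross-hybridization filtering** — a primer is eliminated if some
   off-target window matches it exactly beyond the 5′-terminal zone and
   differs by at most 4 bases inside the zone (a perfectly seated 3′ end
   primes regardless of 5′ mismatches).
4. **General cross-hybridization filtering** — a primer is eliminated if any
   off-target window of equal length is within Hamming distance k, run for
   k = 1..K. Candidate pairs are discovered by pigeonhole seed decomposition:
   a match with ≤ k mismatches must share one of the k+1 contiguous blocks
   of length ⌊m/(k+1)⌋ exactly, so only seed-sharing pairs are verified.
5. **Consolidation** — verdicts are aggregated over all seed groups before
   any primer is removed, so results are independent of the grouping.
6. **Pair filtering** — per source sequence, forward × reverse occurrences
   are joined under five constraints: length difference, Tm difference,
   product size `(start_r + len_r) − start_f`, pair-complementarity and
   3′-end pair-complementarity.
7. **Ranking** — each pair receives the weighted sum of 19 penalty
   components normalized to [0, 1] (range constraints score 0 at the
   midpoint, capped constraints score 0 at zero); pairs are ranked per
   sequence by ascending penalty with deterministic tie-breaking.

Every stage has a literal brute-force counterpart (`oracle`), and a
synthetic-database generator plants known-good pairs and controlled
near-duplicate decoys so the whole pipeline is verifiable offline.

## Worked example

Generate a 4-sequence synthetic database with one planted pair, design,
and audit the output (the constraint profile below is the one used
throughout the test suite):

```bash
primersweep fixtures --seed 5 --n-sequences 4 --pairs 1 \
    --out-fasta demo.fa --out-manifest demo_manifest.tsv --config profile.yaml
primersweep design demo.fa --config profile.yaml --out demo_pairs.tsv --top-n 2
primersweep check demo.fa demo_pairs.tsv --config profile.yaml
```

The design run prints per-stage survivor counts:

```
n_sequences: 4
candidates: 8940
after_single_filter: 66
after_5p_filter: 66
after_general_k1: 66
after_general_k2: 66
pairs_built: 173
pairs_ranked: 173
```

8940 oriented candidate windows collapse to 66 unique primers passing the
six single-primer constraints; nothing resembles an off-target here, so the
specificity screen removes none; the pair join yields 173 feasible pairs.
The ranked TSV puts the planted pair first for its sequence:

```
sid  accession      rank  forward_seq             reverse_seq             start_f  start_r  product_size  penalty
0    synthetic_000  1     GCAAATAACGCCACGACGCACC  GTGAACGCAACGCCAAAGTCCG  84       167      105           8.5435
0    synthetic_000  2     GCAAATAACGCCACGACGCACC  TGAACGCAACGCCAAAGTCCGT  84       166      104           8.6761
```

The rank-1 pair is exactly the planted one (manifest coordinates 84/167,
product 105 = the midpoint of the 70–140 bp window), and `check` re-derives
every constraint from scratch: `OK: 2 pairs, zero violations`. Re-running
`fixtures` with `--decoys 2,3` plants near-duplicate copies of the forward
primer at Hamming distances 2 and 3 in other sequences; the screen then
eliminates the planted primer at k = 2 (distance 2 ≤ K) exactly as the
manifest predicts, while the distance-3 decoy alone would leave it alive.

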