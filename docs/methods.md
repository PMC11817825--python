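# Methods

This note documents the models, algorithms, parameters and deliberate
design choices behind `aptamin`, and what its tests do and do not
establish.

## Thermodynamic model

A secondary structure is a nested (pseudoknot-free) set of Watson–Crick
pairs. Its free energy is the sum over loop faces of the unique loop
decomposition:

| face | energy term |
| --- | --- |
| stack | tabulated ΔG°37 of the dinucleotide step |
| hairpin (u ≥ 3 unpaired) | length-initiation table entry |
| bulge, u = 1 | bulge(1) + the preserved flanking stack |
| bulge, u > 1 | bulge(u) + terminal-AT penalties on both closing pairs |
| internal loop | interior(n1+n2) + min(cap, 0.3·\|n1−n2\|) + terminal-AT penalties |
| multiloop | a + b·(#helices incl. closing) + c·(#unpaired) + per-helix terminal-AT |
| exterior loop | per-branch terminal-AT penalties only |

All arithmetic is int64 in hundredths of kcal/mol; floats appear only at
API boundaries. Hairpins shorter than 3 nt have no finite energy; they
are *representable* (the structure layer accepts any balanced
dot-bracket) but rejected by the energy layer — this split keeps
structure comparison general while the model stays strict.

### Parameter set provenance and omissions

`src/aptamin/data/dna_nn.par` is authored for this package in the
section-tagged `.par` dialect and contains, at 37 °C:

* the ten unified DNA Watson–Crick nearest-neighbor stacking free
  energies (the standard unified oligonucleotide ΔG°37 set; the 4×4
  pair-type matrix in the file is generated from them by strand
  symmetry),
* hairpin/bulge/internal loop-length initiation tables on the published
  anchor values, filled in between anchors by Jacobson–Stockmayer
  logarithmic interpolation and rounded to 0.05 kcal/mol,
* long-loop extrapolation ΔG(n>30) = ΔG(30) + 1.50·ln(n/30) kcal/mol
  (≈ 2.44·RT at 310 K),
* terminal-AT penalty 0.05 kcal/mol per AT-closed helix end,
* loop-asymmetry (Ninio-style) penalty 0.3 kcal/mol per unpaired-length
  difference, capped at 3.0,
* multiloop coefficients a = 3.4, b = 0.4 per helix, c = 0.0 per
  unpaired base (classical efn2-style linear model).

**Deliberately absent** (no authoritative values could be carried into
this repository): terminal-mismatch tables, dangling-end tables
(the model is dangle-free, recorded as `dangle_model: "d0"` in output
metadata), 1×1/2×1/2×2 special internal-loop tables, tetraloop bonuses,
and G·T wobble pairs. These omissions shift *absolute* energies upward
by roughly 1–2 kcal/mol per helix end relative to engines shipping the
full DNA tables, and they disfavor multiloops (which lose the most from
missing branch dangles). Consequently the bundled Gol1 fixture folds
here at −12.08 kcal/mol into a two-hairpin state, whereas full-table
engines report ≈ −24.7 kcal/mol with a junction. Rankings *within* one
model (truncation landscapes, design batches) remain meaningful; users
needing absolute energies can load any complete file in the same
dialect via `load_parameter_set`. The parameter values were fixed
before any benchmark was folded and have not been adjusted since.

## Folding algorithm

Zuker-style dynamic programming: `V(i,j)` (best energy given pair
(i,j)), multiloop helpers `M` (≥1 branch) and `M1` (one branch starting
at i), exterior prefix array `W`. Bulge/internal loops are capped at 30
total unpaired bases (the standard MAXLOOP cutoff); hairpin loops use
the logarithmic extrapolation. Lonely pairs are permitted. The kernel
is numba-compiled; the first call in a process pays a few seconds of
JIT compilation.

Determinism: traceback tie-breaks are fixed — exterior and multiloop
arrays prefer a pairing branch over an unpaired base and the smallest 5′
index among equals; a closed pair resolves hairpin first, then interior
loops (smallest 5′ gap, innermost 3′ first), then multiloops. Identical
input gives bit-identical output. Every `FoldResult` is verified at
construction: the DP energy must equal the independent loop-sum
evaluation of the traced structure, so a traceback inconsistency can
never be returned silently.

Correctness oracle: for short sequences `enumerate_structures` generates
*every* model-valid structure and `exhaustive_mfe` scores them through
the loop-decomposition evaluator — a code path disjoint from the DP
recursions. The test suite asserts exact integer agreement on hundreds
of random sequences (n ≤ 16).

## Motif matching

A motif is a junction requirement: minimum helix count (closing helix
included; a three-way junction = 3), an optional balanced dot-bracket
fragment that must occur as an exact substructure at some offset, and
optional 1-based intervals that must remain unpaired. Any junction in
the structure may satisfy the spec (position drift allowed); `near`
optionally pins the junction's closing pair. After trimming,
coordinates are shifted with `MotifSpec.shifted`; a designated segment
that falls off the sequence makes the motif unsatisfiable.

## Truncation scan

Full (trim5, trim3) grid (defaults n/2 per side), every candidate
refolded and motif-tested. The selected minimal candidate maximizes
total trim among preserving rows; ties break by lower energy, then
smaller trim5. A `min_energy` criterion is also available. The grid
subsumes one-end-at-a-time scanning and is cheap at aptamer scale
(seconds for a 60-nt parent).

## Inverse folding

Seeded adaptive walk. Initialization draws, for each target pair, a
uniformly random allowed complementary pair consistent with the IUPAC
constraints (jointly for the two positions), and a uniform allowed base
elsewhere. Each step picks a position implicated in a defective pair
(symmetric difference between current MFE structure and target),
resamples it (jointly with its partner when the target pairs it), and
accepts iff the base-pair distance does not increase. Success means
distance 0; `max_steps` defaults to 50·n and unconverged runs are
recorded as failures, with restarts supplied by the batch, not by the
run. Infeasible constraints (a paired position pair admitting no
allowed base pair) are rejected before searching.

Batches derive per-run seeds from the master seed via
`numpy.random.SeedSequence` (masked below 2³¹), deduplicate successful
sequences by exact string identity, score by MFE, screen for canonical
G-quadruplex motifs, and rank the unflagged designs by MFE ascending
with lexicographic tie-break. An identical master seed reproduces a
batch byte for byte. Note the walk stops at its first exact solution —
it samples compatible sequences rather than optimizing their energy —
so the best-of-batch energy improves with the number of runs, not with
step count.

## G-quadruplex screen

Canonical rule: four G-runs of ≥ `min_run` (default 3) separated by
loops of 1–7 bases, reported as maximal non-overlapping matches,
greedily from the 5′ end. This is a sequence-level *filter*; no attempt
is made to model quadruplex thermodynamics or i-motifs.
`pseudoknot_certificate` certifies nestedness for imported structures;
structures built by this package are nested by construction.

## Synthetic parents (the stated test world)

`make_synthetic_aptamer` emits a three-way junction: closing stem,
two branch hairpins, GC-only stems, adenine-only loops/junction runs
and terminal padding. Because A·A pairs are impossible and A cannot
pair G or C, no spurious pair involving unpaired regions exists, and
the generator refolds its candidate (retrying seeded stem sequences, up
to 50 attempts) until the designed structure *is* the MFE structure.
Defaults state a U2-like world: 5/5/5-bp stems, 4-nt loops, 4 unpaired
junction bases, 6 nt of 5′ and 11 nt of 3′ padding → a 59-nt parent
whose correct truncation answer is exactly (6, 11).

What the generator does **not** emulate: mixed-composition stems with
competing registers, near-isoenergetic alternative folds, wobble
content, or poly-T tracts of real SELEX parents. A green
fixture-recovery test therefore establishes that the scan recovers
planted geometry under unambiguous thermodynamics — not that truncation
of an arbitrary natural aptamer is uniquely determined.

## Known limitations

* Absolute energies are systematically less negative than full-table
  DNA engines (see parameter omissions above); headline literature
  energies for Gol1-class aptamers are not reproduced numerically.
* No partition function, suboptimal enumeration (beyond the test
  oracle), co-folding, temperature rescaling, or RNA parameters.
* Inverse folding targets the MFE structure only (no ensemble-defect
  objective).
* The disallow-lonely-pairs variant of the DP is not implemented.
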