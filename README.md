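# aptamin

In-silico minimization and redesign of single-stranded DNA aptamers.

Aptamers selected by cell-SELEX (such as the anti-EGFR/EGFRvIII U2 family)
are often longer than their functional core and carry poly-T stretches
that destabilize the fold. `aptamin` implements the computational
workflow that turns such a parent into a short, stabilized variant while
preserving the structural element believed to do the recognition — a
multiloop (three-way junction):

1. **Fold** — minimum-free-energy (MFE) secondary structure of ssDNA
   under a nearest-neighbor thermodynamic model, computed by a Zuker-style
   dynamic program in exact integer arithmetic (0.01 kcal/mol units):
   ΔG(S) = Σ over loop faces of S of ΔG(face), with tabulated
   Watson–Crick stacking terms, loop-length initiation penalties, and a
   linear multiloop model a + b·(helices) + c·(unpaired).
2. **Truncate** — scan all (trim5, trim3) end-trims, refold every
   candidate, and keep those whose *re-predicted* structure still
   contains the designated junction; preservation "on paper" is never
   trusted.
3. **Design** — constrained stochastic inverse folding: seeded adaptive
   walks that search for sequences whose MFE structure equals the
   minimized target (the design space is 4^(#pairs)); repeated runs are
   deduplicated and ranked by MFE.
4. **Restore & vary** — re-write the functional loop sequences into the
   best design, refold to confirm the junction survives, and emit
   junction-composition variants (e.g. AAAA/TTTT/ATAT).
5. **Screen** — reject designs containing canonical G-quadruplex motifs
   (G₃₊N₁₋₇G₃₊N₁₋₇G₃₊N₁₋₇G₃₊); pseudoknots are excluded by the nested
   folding model itself.

The package is a library: import it from Python (or run the short
scripts in `examples/`). There is no command-line tool.

## Worked example

```python
>>> from aptamin import gol1_sequence, mfe_fold
>>> fold = mfe_fold(gol1_sequence())
>>> print(fold.vienna())
>Gol1
GCCGGCGGCATTTTGACGCCGCCGCCGGCCGGCTGCTTATGCTGCTCCGGGGGGCATATATGGC
(((((((((...........)))))))))........(((((...........)))))...... (-12.08)
```

The bundled 64-nt Gol1 aptamer folds at −12.08 kcal/mol over 14 base
pairs under the bundled parameter set: each `(`/`)` pair in the
dot-bracket line is a predicted Watson–Crick pair, and the more negative
the energy, the more stable the fold. `examples/truncate_synthetic.py`
builds a 59-nt synthetic junction parent with 6/11 nt of terminal
padding and shows the truncation scan recovering exactly those trims
(126 grid points scanned, 84 junction-preserving, selected candidate
42 nt at −13.0 kcal/mol). `examples/design_batch.py` redesigns the Gol1
scaffold (30 runs → 27 unique designs, best −13.94 kcal/mol, i.e. more
stable than Gol1 itself).

**Energy-scale caveat.** The bundled parameter file carries unified DNA
Watson–Crick stacking and loop-initiation tables only; terminal-mismatch
and dangling-end refinements are not included. Absolute energies are
therefore systematically less negative than those from folding engines
shipping the full DNA parameter tables, and multiloop-containing states
are penalized relative to them. Relative comparisons within one
workflow (truncation landscapes, design rankings) are unaffected in
practice. See `docs/methods.md` for the full account.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the MFE of the bundled Gol1 sequence (t1) and
the lowest MFE among unique successful designs of a 100-run seeded
inverse-folding batch targeting Gol1's MFE structure (t2), writing both
to the given JSON path. The seed drives every stochastic component.
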