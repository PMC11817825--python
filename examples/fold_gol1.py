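"""Fold the bundled Gol1 aptamer and print its MFE structure.

The 64-nt Gol1 sequence is a minimized, redesigned anti-EGFR DNA
aptamer; its secondary-structure formation energy is the toolkit's most
basic readout.
"""

from aptamin import gol1_sequence, mfe_fold, decompose

gol1 = gol1_sequence()
result = mfe_fold(gol1)

print(result.vienna())
print()
print(f"MFE: {result.energy:.1f} kcal/mol over {result.structure.n_pairs()} "
      f"base pairs")
kinds = [l.kind for l in decompose(result.structure)]
print("loop faces:", ", ".join(sorted(set(kinds))))
print()
print("The dot-bracket line shows which bases pair; the parenthesized")
print("number is the predicted formation free energy -- more negative")
print("means a more stable fold under the bundled dangle-free DNA model.")
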