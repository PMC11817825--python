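"""Truncation scan of the published U2 parent aptamer (external input).

The U2 anti-EGFR aptamer sequence is published in the original
cell-SELEX selection literature but is not redistributed with this
package.  Supply it as a FASTA file:

    python examples/u2_truncation.py path/to/u2.fasta

For the published U2 the expected outcome is a minimal candidate with
6 nt trimmed from the 5' end and 11 nt from the 3' end; absolute
energies will differ from published values because the bundled
parameter set omits mismatch/dangle refinements (see docs/methods.md).
"""

import sys

from aptamin import MotifSpec, mfe_fold, read_fasta, truncation_scan

if len(sys.argv) != 2:
    sys.exit(__doc__)

(parent,) = read_fasta(sys.argv[1])
fold = mfe_fold(parent)
print(f"{parent.id}: {len(parent)} nt, MFE {fold.energy:.1f} kcal/mol")
print(fold.dotbracket)

landscape = truncation_scan(parent, MotifSpec(min_helices=3))
sel = landscape.selected
print(f"\nselected minimal candidate: trim5={sel.trim5}, trim3={sel.trim3}")
print(f"{len(sel.subsequence)} nt at {sel.fold.energy:.1f} kcal/mol")
print(sel.fold.dotbracket)
landscape.to_tsv(f"{parent.id}_landscape.tsv")
print(f"\nfull landscape written to {parent.id}_landscape.tsv")
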