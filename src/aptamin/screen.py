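"""Sequence-level screening of designs for G-quadruplex motifs.

Designed aptamers must avoid competing non-canonical folds.  Pseudoknots
cannot arise from this toolkit's nested-only folding model, but
G-quadruplexes are a sequence property invisible to it, so candidate
sequences are screened with the canonical G4 rule: four runs of at least
``min_run`` guanines separated by loops of 1-7 nucleotides
(G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from .structures import DnaSequence, PairTable


@dataclass(frozen=True)
class QuadruplexHit:
    """A canonical G-quadruplex motif occurrence (1-based, inclusive)."""

    start: int
    end: int
    g_runs: tuple[int, ...]
    loops: tuple[int, ...]
    motif: str


def g4_scan(seq: Union[DnaSequence, str], min_run: int = 3,
            loop_min: int = 1, loop_max: int = 7) -> list[QuadruplexHit]:
    """Scan for canonical G-quadruplex motifs.

    Returns maximal non-overlapping hits, greedily from the 5' end.
    A hit needs four G-runs of length >= ``min_run`` with the three
    intervening loops of ``loop_min``..``loop_max`` non-G-run bases.
    """
    if isinstance(seq, DnaSequence):
        res = seq.residues
    else:
        res = DnaSequence("query", seq).residues
    run = f"G{{{min_run},}}"
    loop = f".{{{loop_min},{loop_max}}}?"
    pat = re.compile(f"({run})({loop})({run})({loop})({run})({loop})({run})")
    hits: list[QuadruplexHit] = []
    pos = 0
    while True:
        m = pat.search(res, pos)
        if m is None:
            break
        g_runs = tuple(len(m.group(k)) for k in (1, 3, 5, 7))
        loops = tuple(len(m.group(k)) for k in (2, 4, 6))
        hits.append(QuadruplexHit(m.start() + 1, m.end(), g_runs, loops,
                                  m.group(0)))
        pos = m.end()  # non-overlapping, 5'-most greedy
    return hits


def pseudoknot_certificate(pt) -> bool:
    """True iff the pair set is free of crossing pairs.

    Structures built by this toolkit are nested by construction (the
    :class:`~aptamin.structures.PairTable` constructor rejects
    crossings), so this always holds for them; the function exists as an
    explicit assertion for structures imported from elsewhere, and so
    also accepts a raw 0-based partner list (-1 = unpaired) that may
    contain crossings.
    """
    partner = pt.partner if isinstance(pt, PairTable) else tuple(pt)
    open_stack: list[int] = []
    for i, p in enumerate(partner):
        if p > i:
            open_stack.append(p)
        elif p != -1:
            if not open_stack or open_stack[-1] != i:
                return False
            open_stack.pop()
    return not open_stack


def write_g4_bed(hits_by_seq: dict[str, list[QuadruplexHit]], path) -> None:
    """BED-like TSV of hits: sequence id, start, end (1-based inclusive),
    motif string."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tmotif\n")
        for sid, hits in hits_by_seq.items():
            for h in hits:
                fh.write(f"{sid}\t{h.start}\t{h.end}\t{h.motif}\n")
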