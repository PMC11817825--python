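"""File I/O: FASTA sequences, Vienna-style structure text, CT tables.

FASTA goes through Biopython; structure writers emit the plain-text
conventions of common folding software (dot-bracket line with the
energy in parentheses, and the connectivity-table format).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import FoldResult
from .structures import DnaSequence, StructureError


def read_fasta(path: Union[str, Path]) -> list[DnaSequence]:
    """Read a multi-record FASTA of DNA sequences.

    Lowercase is normalized to uppercase; a 'U' residue raises an error
    advising the DNA alphabet; empty files and duplicate ids raise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureError(f"{path}: no FASTA records found")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise StructureError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(DnaSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[DnaSequence], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_vienna(results: Union[FoldResult, Iterable[FoldResult]],
                 path: Union[str, Path]) -> None:
    """Vienna plain text: '>id' header, sequence line, dot-bracket line
    with the energy in parentheses, e.g. '(-24.70)'."""
    if isinstance(results, FoldResult):
        results = [results]
    with open(path, "w") as fh:
        for fr in results:
            fh.write(fr.vienna() + "\n")


def write_ct(fr: FoldResult, path: Union[str, Path]) -> None:
    """Connectivity-table (CT) format, 1-based."""
    n = len(fr.sequence)
    with open(path, "w") as fh:
        fh.write(f"{n}\tdG = {fr.energy:.2f}\t{fr.sequence.id}\n")
        for i in range(1, n + 1):
            partner = fr.structure.partner[i - 1] + 1  # 0 when unpaired
            nxt = i + 1 if i < n else 0
            fh.write(f"{i}\t{fr.sequence[i - 1]}\t{i - 1}\t{nxt}\t"
                     f"{partner}\t{i}\n")


def gol1_sequence() -> DnaSequence:
    """The bundled 64-nt Gol1 anti-EGFR aptamer sequence."""
    ref = resources.files("aptamin").joinpath("data/gol1.fasta")
    with resources.as_file(ref) as p:
        return read_fasta(p)[0]
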