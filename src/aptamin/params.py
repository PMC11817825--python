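"""Nearest-neighbor energy parameters for single-stranded DNA folding.

Parameters are read from a section-tagged plain-text file (the ``.par``
dialect used by folding software: ``# section`` headers, whitespace-
separated integer tables in hundredths of kcal/mol, ``INF`` for forbidden
states, ``/* ... */`` comments).  The bundled set ``dna_nn.par`` carries
unified DNA Watson-Crick stacking free energies and loop-length initiation
tables at 37 C; see the package methods note for provenance and for what
the reduced table set omits (mismatch/dangle refinements, wobble pairs).

All energies are handled as integers in 0.01 kcal/mol; conversion to
float happens only at API boundaries.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Union

#: sentinel for forbidden states, safely summable in int64 arithmetic
INF = 10_000_000

#: maximum tabulated loop length; longer loops use log extrapolation
MAX_TABULATED_LOOP = 30

#: maximum total unpaired span of a bulge/internal loop considered by the DP
MAXLOOP = 30

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParameterError(ValueError):
    """Malformed or incomplete parameter file."""


def _strip_comments(line: str) -> str:
    while "/*" in line:
        a = line.index("/*")
        b = line.find("*/", a)
        if b == -1:
            line = line[:a]
        else:
            line = line[:a] + line[b + 2:]
    return line.strip()


def _to_int(tok: str, lineno: int) -> int:
    if tok.upper() == "INF":
        return INF
    try:
        return int(tok)
    except ValueError:
        raise ParameterError(f"line {lineno}: malformed value {tok!r}") from None


@dataclass(frozen=True)
class EnergyParameterSet:
    """Loaded nearest-neighbor tables (integer hundredths of kcal/mol).

    pair_type maps an ordered base pair (5' base, 3' base) to a row index
    of ``stack``; pairs absent from the file cannot form.  The multiloop
    model is linear: a (closing offset) + b per helix (closing helix
    included) + c per unpaired base.
    """

    pairs: tuple[str, ...]
    stack: tuple[tuple[int, ...], ...]
    hairpin: tuple[int, ...]          # index = loop length, 0..30
    bulge: tuple[int, ...]
    interior: tuple[int, ...]
    ml_closing: int
    ml_per_helix: int
    ml_per_unpaired: int
    ninio_per_nt: int
    ninio_max: int
    terminal_at: int
    lxc: int                          # coefficient of ln(n/30) for long loops
    temperature: float
    source: str
    sha256: str
    dangle_model: str = "d0"

    @property
    def pair_type(self) -> dict[tuple[str, str], int]:
        return {(p[0], p[1]): i for i, p in enumerate(self.pairs)}

    def can_pair(self, a: str, b: str) -> bool:
        return (a, b) in self.pair_type

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> int:
        pt = self.pair_type
        return self.stack[pt[outer]][pt[inner]]

    def _long_loop(self, table: tuple[int, ...], length: int) -> int:
        if length <= MAX_TABULATED_LOOP:
            return table[length]
        return table[MAX_TABULATED_LOOP] + int(
            round(self.lxc * math.log(length / MAX_TABULATED_LOOP)))

    def hairpin_energy(self, length: int) -> int:
        """Hairpin initiation; INF below the 3-nt model minimum."""
        if length < 0:
            raise ParameterError("negative hairpin length")
        return self._long_loop(self.hairpin, length) if length >= 1 else INF

    def bulge_energy(self, length: int) -> int:
        return self._long_loop(self.bulge, length)

    def interior_energy(self, length: int) -> int:
        return self._long_loop(self.interior, length)

    def at_penalty(self, pair: tuple[str, str]) -> int:
        """Terminal AT/TA penalty applied at helix ends."""
        return self.terminal_at if "A" in pair else 0

    def pair_matrix(self) -> "np.ndarray":
        """4x4 int matrix over base indices: pair-type index + 1, or 0."""
        import numpy as np
        m = np.zeros((4, 4), dtype=np.int64)
        for (a, b), t in self.pair_type.items():
            m[BASE_INDEX[a], BASE_INDEX[b]] = t + 1
        return m


def _read_sections(text: str) -> dict[str, list[tuple[int, str]]]:
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comments(raw)
        if not line or line.startswith("##"):
            continue
        if line.startswith("#"):
            current = line[1:].strip()
            sections[current] = []
            continue
        if current is None:
            raise ParameterError(f"line {lineno}: data before any '# section' header")
        sections[current].append((lineno, line))
    return sections


def _flat_tokens(rows: list[tuple[int, str]]) -> list[tuple[int, str]]:
    out = []
    for lineno, line in rows:
        out.extend((lineno, tok) for tok in line.split())
    return out


def load_parameter_set(path: Union[str, Path]) -> EnergyParameterSet:
    """Load a ``.par``-dialect DNA nearest-neighbor parameter file.

    Raises :class:`ParameterError` naming the missing section or the
    malformed line.
    """
    path = Path(path)
    data = path.read_bytes()
    text = data.decode()
    sections = _read_sections(text)

    for required in ("pairs", "stack", "hairpin", "bulge", "interior",
                     "ML_params", "NINIO", "Misc", "END"):
        if required not in sections:
            raise ParameterError(f"{path.name}: missing section '# {required}'")

    pair_rows = _flat_tokens(sections["pairs"])
    pairs = tuple(tok for _, tok in pair_rows)
    for lineno, p in pair_rows:
        if len(p) != 2 or any(c not in BASES for c in p):
            raise ParameterError(f"line {lineno}: bad pair token {p!r}")
    npair = len(pairs)
    if npair == 0:
        raise ParameterError(f"{path.name}: empty 'pairs' section")

    toks = _flat_tokens(sections["stack"])
    if len(toks) != npair * npair:
        raise ParameterError(
            f"{path.name}: table 'stack' has {len(toks)} entries, "
            f"expected {npair * npair}")
    vals = [_to_int(t, ln) for ln, t in toks]
    stack = tuple(tuple(vals[r * npair:(r + 1) * npair]) for r in range(npair))

    def loop_table(name: str) -> tuple[int, ...]:
        toks = _flat_tokens(sections[name])
        if len(toks) != MAX_TABULATED_LOOP:
            raise ParameterError(
                f"{path.name}: table '{name}' has {len(toks)} entries, "
                f"expected {MAX_TABULATED_LOOP}")
        return (INF,) + tuple(_to_int(t, ln) for ln, t in toks)

    hairpin = loop_table("hairpin")
    bulge = loop_table("bulge")
    interior = loop_table("interior")

    ml = [_to_int(t, ln) for ln, t in _flat_tokens(sections["ML_params"])]
    if len(ml) != 3:
        raise ParameterError(f"{path.name}: 'ML_params' needs 3 values")
    ninio = [_to_int(t, ln) for ln, t in _flat_tokens(sections["NINIO"])]
    if len(ninio) != 2:
        raise ParameterError(f"{path.name}: 'NINIO' needs 2 values")
    misc = [_to_int(t, ln) for ln, t in _flat_tokens(sections["Misc"])]
    if len(misc) != 3:
        raise ParameterError(f"{path.name}: 'Misc' needs 3 values")

    return EnergyParameterSet(
        pairs=pairs, stack=stack,
        hairpin=hairpin, bulge=bulge, interior=interior,
        ml_closing=ml[0], ml_per_helix=ml[1], ml_per_unpaired=ml[2],
        ninio_per_nt=ninio[0], ninio_max=ninio[1],
        terminal_at=misc[0], lxc=misc[1], temperature=float(misc[2]),
        source=str(path), sha256=hashlib.sha256(data).hexdigest(),
    )


@lru_cache(maxsize=1)
def default_parameters() -> EnergyParameterSet:
    """The bundled DNA nearest-neighbor set at 37 C."""
    ref = resources.files("aptamin").joinpath("data/dna_nn.par")
    with resources.as_file(ref) as p:
        return load_parameter_set(p)
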