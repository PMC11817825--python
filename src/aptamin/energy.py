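"""Structure-given free-energy evaluation under the nearest-neighbor model.

A structure's energy is the sum of its loop-face terms:

* stack: tabulated stacking free energy of the two pairs;
* hairpin: loop-length initiation (minimum 3 unpaired bases);
* bulge: length term; a single-base bulge keeps the flanking stack,
  larger bulges instead pay terminal-AT penalties on both closing pairs;
* internal loop: length term + Ninio asymmetry penalty (capped) +
  terminal-AT penalties on both closing pairs;
* multiloop: linear model a + b*(number of helices, closing included)
  + c*(unpaired bases), plus terminal-AT penalties per helix end;
* exterior loop: terminal-AT penalties of its branches only.

The model is dangle-free; all arithmetic is integer hundredths of
kcal/mol, matching the folding DP bit for bit.
"""

from __future__ import annotations

from typing import Union

from .params import INF, EnergyParameterSet, default_parameters
from .structures import (DnaSequence, LoopRecord, PairTable, decompose)


class EnergyModelError(ValueError):
    """Structure incompatible with the energy model (disallowed pair,
    hairpin below the model minimum, ...)."""


def _pair_bases(seq: DnaSequence, pair: tuple[int, int]) -> tuple[str, str]:
    i, j = pair  # 1-based
    return seq[i - 1], seq[j - 1]


def _check_pair(seq: DnaSequence, pair: tuple[int, int],
                params: EnergyParameterSet) -> tuple[str, str]:
    bases = _pair_bases(seq, pair)
    if not params.can_pair(*bases):
        raise EnergyModelError(
            f"pair {bases[0]}{bases[1]} at positions {pair[0]}-{pair[1]} "
            f"is not allowed by the parameter set")
    return bases


def loop_energy(loop: LoopRecord, seq: DnaSequence,
                params: EnergyParameterSet) -> int:
    """Energy of one loop face in integer hundredths of kcal/mol."""
    if loop.kind == "exterior":
        e = 0
        for br in loop.branches:
            e += params.at_penalty(_check_pair(seq, br, params))
        return e

    closing = _check_pair(seq, loop.closing, params)
    ci, cj = loop.closing

    if loop.kind == "hairpin":
        u = len(loop.unpaired)
        if u < 3:
            raise EnergyModelError(
                f"hairpin closed by {ci}-{cj} has {u} unpaired bases "
                f"(model minimum is 3)")
        return params.hairpin_energy(u)

    if loop.kind in ("stack", "bulge", "internal"):
        (k, l), = loop.branches
        inner = _check_pair(seq, (k, l), params)
        n1, n2 = k - ci - 1, cj - l - 1
        if loop.kind == "stack":
            return params.stack_energy(closing, inner)
        if loop.kind == "bulge":
            u = n1 + n2
            if u == 1:
                return params.bulge_energy(1) + params.stack_energy(closing, inner)
            return (params.bulge_energy(u)
                    + params.at_penalty(closing) + params.at_penalty(inner))
        u = n1 + n2
        asym = min(params.ninio_max, params.ninio_per_nt * abs(n1 - n2))
        return (params.interior_energy(u) + asym
                + params.at_penalty(closing) + params.at_penalty(inner))

    if loop.kind == "multiloop":
        e = (params.ml_closing
             + params.ml_per_helix * (1 + len(loop.branches))
             + params.ml_per_unpaired * len(loop.unpaired)
             + params.at_penalty(closing))
        for br in loop.branches:
            e += params.at_penalty(_check_pair(seq, br, params))
        return e

    raise EnergyModelError(f"unknown loop kind {loop.kind!r}")


def eval_structure_energy(seq: Union[DnaSequence, str], pt: PairTable,
                          params: EnergyParameterSet | None = None) -> float:
    """Free energy (kcal/mol) of ``pt`` on ``seq``; exact integer sum
    converted at the boundary."""
    return eval_structure_energy_int(seq, pt, params) / 100.0


def eval_structure_energy_int(seq: Union[DnaSequence, str], pt: PairTable,
                              params: EnergyParameterSet | None = None) -> int:
    if isinstance(seq, str):
        seq = DnaSequence("seq", seq)
    if params is None:
        params = default_parameters()
    if len(seq) != pt.n:
        raise EnergyModelError(f"sequence length {len(seq)} != structure length {pt.n}")
    total = 0
    for loop in decompose(pt):
        e = loop_energy(loop, seq, params)
        if e >= INF:
            raise EnergyModelError(
                f"{loop.kind} loop at {loop.closing} has no finite energy")
        total += e
    return total
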