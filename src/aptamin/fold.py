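"""Minimum-free-energy folding of single-stranded DNA.

A Zuker-style dynamic program over the nearest-neighbor model of
:mod:`aptamin.energy`: V(i,j) is the best energy of the subsequence
[i..j] given that i pairs j; M/M1 are the usual multiloop helper arrays
(at least one branch / exactly one branch starting at i); W accumulates
the exterior loop over prefixes.  Bulge and internal loops are bounded
at 30 unpaired bases total (the standard MAXLOOP cutoff); hairpin loops
use logarithmic extrapolation beyond the tabulated 30.

All arithmetic is int64 hundredths of kcal/mol, so results are
bit-reproducible; the kernel is numba-compiled.  Traceback tie-breaks
are fixed (exterior/multiloop: prefer a pairing branch, then the
smallest 5' index; for a closed pair: hairpin, then innermost interior
loop with smallest 5' gap, then multiloop) so identical input gives
identical output.

The module also provides exhaustive structure enumeration for short
sequences, used as an independent oracle: the enumerator scores every
structure with :func:`aptamin.energy.eval_structure_energy_int`, a code
path disjoint from the DP recursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Optional, Union

import numpy as np
from numba import njit

from .params import (BASE_INDEX, INF, MAXLOOP, MAX_TABULATED_LOOP,
                     EnergyParameterSet, default_parameters)
from .structures import DnaSequence, PairTable, to_dotbracket
from .energy import EnergyModelError, eval_structure_energy_int

_INF = np.int64(INF)


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure and its free energy.

    ``energy_int`` is the exact integer energy in 0.01 kcal/mol;
    ``energy`` the kcal/mol float rendered from it.  The invariant
    ``energy_int == eval_structure_energy_int(sequence, structure)``
    is asserted at construction time by :func:`mfe_fold`.
    """

    sequence: DnaSequence
    structure: PairTable
    energy_int: int
    param_sha256: str = ""
    dangle_model: str = "d0"

    @property
    def energy(self) -> float:
        return self.energy_int / 100.0

    @property
    def dotbracket(self) -> str:
        return to_dotbracket(self.structure)

    def vienna(self) -> str:
        """Vienna-style plain text: header, sequence, structure (energy)."""
        return (f">{self.sequence.id}\n{self.sequence.residues}\n"
                f"{self.dotbracket} ({self.energy:.2f})")


# ---------------------------------------------------------------------------
# numba kernel

@njit(cache=True)
def _hairpin_e(u, hairpin, lxc):
    if u < 3:
        return _INF
    if u <= MAX_TABULATED_LOOP:
        return hairpin[u]
    return hairpin[MAX_TABULATED_LOOP] + np.int64(
        math.floor(lxc * math.log(u / MAX_TABULATED_LOOP) + 0.5))


@njit(cache=True)
def _il_e(n1, n2, pto, pti, stack, bulge, interior, at_pen, ninio, ninio_max):
    """Stack / bulge / internal-loop energy for outer pair type pto and
    inner pair type pti with n1, n2 unpaired on the two sides."""
    if n1 == 0 and n2 == 0:
        return stack[pto, pti]
    u = n1 + n2
    if n1 == 0 or n2 == 0:
        if u == 1:
            return bulge[1] + stack[pto, pti]
        return bulge[u] + at_pen[pto] + at_pen[pti]
    asym = ninio * abs(n1 - n2)
    if asym > ninio_max:
        asym = ninio_max
    return interior[u] + asym + at_pen[pto] + at_pen[pti]


@njit(cache=True)
def _fold_kernel(s, ptab, stack, at_pen, hairpin, bulge, interior,
                 ml_a, ml_b, ml_c, ninio, ninio_max, lxc):
    n = s.shape[0]
    V = np.full((n, n), _INF, np.int64)
    M = np.full((n, n), _INF, np.int64)
    M1 = np.full((n, n), _INF, np.int64)

    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            pt_ij = ptab[s[i], s[j]]
            if pt_ij > 0 and span >= 5:
                best = _hairpin_e(j - i - 1, hairpin, lxc)
                # interior loops (incl. stacks and bulges), bounded by MAXLOOP
                for k in range(i + 1, j - 4 + 1):
                    n1 = k - i - 1
                    if n1 > MAXLOOP:
                        break
                    lmin = j - 1 - (MAXLOOP - n1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k, l] >= _INF:
                            continue
                        e = _il_e(n1, j - l - 1, pt_ij, ptab[s[k], s[l]],
                                  stack, bulge, interior, at_pen,
                                  ninio, ninio_max) + V[k, l]
                        if e < best:
                            best = e
                # multiloop closed by (i, j): >= 2 branches inside
                for k in range(i + 2, j - 1):
                    if M[i + 1, k - 1] >= _INF or M1[k, j - 1] >= _INF:
                        continue
                    e = (ml_a + ml_b + at_pen[pt_ij]
                         + M[i + 1, k - 1] + M1[k, j - 1])
                    if e < best:
                        best = e
                if best < _INF:
                    V[i, j] = best
            # M1: exactly one branch starting at i, optional 3' unpaired tail
            v = _INF
            if pt_ij > 0 and V[i, j] < _INF:
                v = V[i, j] + ml_b + at_pen[pt_ij]
            if j - 1 >= i and M1[i, j - 1] < _INF:
                e = M1[i, j - 1] + ml_c
                if e < v:
                    v = e
            M1[i, j] = v
            # M: at least one branch anywhere in [i, j]
            m = M1[i, j]
            if i + 1 <= j and M[i + 1, j] < _INF:
                e = M[i + 1, j] + ml_c
                if e < m:
                    m = e
            for k in range(i + 1, j + 1):
                if M[i, k - 1] < _INF and M1[k, j] < _INF:
                    e = M[i, k - 1] + M1[k, j]
                    if e < m:
                        m = e
            if m < _INF:
                M[i, j] = m

    W = np.zeros(n + 1, np.int64)
    for j in range(n):
        w = W[j]
        for k in range(0, j - 3):
            if V[k, j] < _INF:
                e = W[k] + V[k, j] + at_pen[ptab[s[k], s[j]]]
                if e < w:
                    w = e
        W[j + 1] = w
    return V, M, M1, W


@njit(cache=True)
def _traceback(s, ptab, stack, at_pen, hairpin, bulge, interior,
               ml_a, ml_b, ml_c, ninio, ninio_max, lxc, V, M, M1, W):
    n = s.shape[0]
    partner = np.full(n, -1, np.int64)
    # task stack: mode (0=V, 1=M, 2=M1), i, j
    cap = 4 * n + 8
    st_mode = np.empty(cap, np.int64)
    st_i = np.empty(cap, np.int64)
    st_j = np.empty(cap, np.int64)
    top = 0

    # exterior loop: prefer a pairing branch, then the smallest 5' index
    j = n - 1
    while j >= 0:
        target = W[j + 1]
        paired = False
        for k in range(0, j - 3):
            if V[k, j] < _INF and W[k] + V[k, j] + at_pen[ptab[s[k], s[j]]] == target:
                st_mode[top] = 0
                st_i[top] = k
                st_j[top] = j
                top += 1
                j = k - 1
                paired = True
                break
        if not paired:
            j -= 1

    while top > 0:
        top -= 1
        mode, i, j = st_mode[top], st_i[top], st_j[top]
        if mode == 0:
            partner[i] = j
            partner[j] = i
            e = V[i, j]
            pt_ij = ptab[s[i], s[j]]
            if _hairpin_e(j - i - 1, hairpin, lxc) == e:
                continue
            done = False
            for k in range(i + 1, j - 4 + 1):
                n1 = k - i - 1
                if n1 > MAXLOOP or done:
                    break
                lmin = j - 1 - (MAXLOOP - n1)
                if lmin < k + 4:
                    lmin = k + 4
                for l in range(j - 1, lmin - 1, -1):
                    if V[k, l] < _INF and _il_e(
                            n1, j - l - 1, pt_ij, ptab[s[k], s[l]], stack,
                            bulge, interior, at_pen, ninio, ninio_max
                    ) + V[k, l] == e:
                        st_mode[top] = 0
                        st_i[top] = k
                        st_j[top] = l
                        top += 1
                        done = True
                        break
            if done:
                continue
            for k in range(i + 2, j - 1):
                if (M[i + 1, k - 1] < _INF and M1[k, j - 1] < _INF
                        and ml_a + ml_b + at_pen[pt_ij]
                        + M[i + 1, k - 1] + M1[k, j - 1] == e):
                    st_mode[top] = 1
                    st_i[top] = i + 1
                    st_j[top] = k - 1
                    top += 1
                    st_mode[top] = 2
                    st_i[top] = k
                    st_j[top] = j - 1
                    top += 1
                    break
        elif mode == 1:
            while True:
                e = M[i, j]
                if M1[i, j] == e:
                    st_mode[top] = 2
                    st_i[top] = i
                    st_j[top] = j
                    top += 1
                    break
                split = False
                for k in range(i + 1, j + 1):
                    if (M[i, k - 1] < _INF and M1[k, j] < _INF
                            and M[i, k - 1] + M1[k, j] == e):
                        st_mode[top] = 1
                        st_i[top] = i
                        st_j[top] = k - 1
                        top += 1
                        st_mode[top] = 2
                        st_i[top] = k
                        st_j[top] = j
                        top += 1
                        split = True
                        break
                if split:
                    break
                i += 1  # leading unpaired base
        else:  # M1
            while True:
                e = M1[i, j]
                pt_ij = ptab[s[i], s[j]]
                if pt_ij > 0 and V[i, j] < _INF and V[i, j] + ml_b + at_pen[pt_ij] == e:
                    st_mode[top] = 0
                    st_i[top] = i
                    st_j[top] = j
                    top += 1
                    break
                j -= 1  # trailing unpaired base
    return partner


# ---------------------------------------------------------------------------
# python surface

def _encode(seq: DnaSequence) -> np.ndarray:
    return np.array([BASE_INDEX[c] for c in seq.residues], dtype=np.int64)


@lru_cache(maxsize=4)
def _packed_tables(params: EnergyParameterSet):
    npair = len(params.pairs)
    stack = np.full((npair + 1, npair + 1), _INF, np.int64)
    for r in range(npair):
        for c in range(npair):
            stack[r + 1, c + 1] = params.stack[r][c]
    at_pen = np.zeros(npair + 1, np.int64)
    for i, p in enumerate(params.pairs):
        at_pen[i + 1] = params.terminal_at if "A" in p else 0
    return (params.pair_matrix(), stack, at_pen,
            np.array(params.hairpin, np.int64),
            np.array(params.bulge, np.int64),
            np.array(params.interior, np.int64))


def mfe_fold(seq: Union[DnaSequence, str],
             params: Optional[EnergyParameterSet] = None,
             max_n: int = 10_000) -> FoldResult:
    """Fold ``seq`` to its minimum-free-energy pseudoknot-free structure.

    Deterministic: identical input gives a bit-identical result.  The
    returned energy always satisfies
    ``energy_int == eval_structure_energy_int(seq, structure)``.
    """
    if isinstance(seq, str):
        seq = DnaSequence("seq", seq)
    if params is None:
        params = default_parameters()
    n = len(seq)
    if n > max_n:
        raise ValueError(f"sequence length {n} exceeds the configured maximum {max_n}")
    s = _encode(seq)
    ptab, stack, at_pen, hp, bu, il = _packed_tables(params)
    args = (s, ptab, stack, at_pen, hp, bu, il,
            np.int64(params.ml_closing), np.int64(params.ml_per_helix),
            np.int64(params.ml_per_unpaired), np.int64(params.ninio_per_nt),
            np.int64(params.ninio_max), np.int64(params.lxc))
    V, M, M1, W = _fold_kernel(*args)
    partner = _traceback(*args, V, M, M1, W)
    pt = PairTable(partner.tolist())
    energy = int(W[n])
    check = eval_structure_energy_int(seq, pt, params)
    if check != energy:
        raise EnergyModelError(
            f"internal inconsistency: DP energy {energy} != "
            f"loop-sum energy {check} for {seq.id}")
    return FoldResult(seq, pt, energy, params.sha256, params.dangle_model)


def mfe_energy(seq: Union[DnaSequence, str],
               params: Optional[EnergyParameterSet] = None) -> float:
    """Convenience: MFE in kcal/mol."""
    return mfe_fold(seq, params).energy


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle (short sequences)

def enumerate_structures(seq: Union[DnaSequence, str],
                         params: Optional[EnergyParameterSet] = None,
                         max_n: int = 24) -> Iterator[PairTable]:
    """Yield every model-valid pseudoknot-free structure of ``seq``.

    Model-valid: all pairs allowed by ``params``, hairpin loops >= 3
    unpaired bases.  Intended as a brute-force oracle for short
    sequences; the count grows exponentially, hence ``max_n``.
    """
    if isinstance(seq, str):
        seq = DnaSequence("seq", seq)
    if params is None:
        params = default_parameters()
    n = len(seq)
    if n > max_n:
        raise ValueError(f"enumeration limited to n <= {max_n}")
    res = seq.residues

    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i + 1 <= 0:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i, j - 1))  # j unpaired
        for k in range(i, j - 3):
            if params.can_pair(res[k], res[j]):
                for left in rec(i, k - 1):
                    for inner in rec(k + 1, j - 1):
                        out.append(left + inner + ((k, j),))
        memo[key] = out
        return out

    for pairset in rec(0, n - 1):
        partner = [-1] * n
        for a, b in pairset:
            partner[a], partner[b] = b, a
        yield PairTable(partner)


def exhaustive_mfe(seq: Union[DnaSequence, str],
                   params: Optional[EnergyParameterSet] = None,
                   max_n: int = 24) -> tuple[int, PairTable]:
    """Brute-force MFE: minimum of :func:`eval_structure_energy_int` over
    all enumerated structures.  Independent of the DP recursions."""
    if isinstance(seq, str):
        seq = DnaSequence("seq", seq)
    if params is None:
        params = default_parameters()
    best_e, best_pt = None, None
    for pt in enumerate_structures(seq, params, max_n=max_n):
        e = eval_structure_energy_int(seq, pt, params)
        if best_e is None or e < best_e:
            best_e, best_pt = e, pt
    assert best_e is not None and best_pt is not None
    return best_e, best_pt
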