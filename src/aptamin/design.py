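"""Constrained stochastic inverse folding (negative design).

Given a target dot-bracket structure, search sequence space for
sequences whose predicted MFE structure equals the target, subject to
positional IUPAC constraints.  The engine is a seeded adaptive walk:
start from a random constraint- and pairing-compatible sequence, then
repeatedly mutate positions that sit in defective faces (pairs of the
symmetric difference between the current MFE structure and the target),
accepting a mutation when it does not increase the base-pair distance.
Paired target positions are always mutated jointly as a complementary
pair, so the walk never leaves the pairing-compatible subspace.

Repeated seeded runs with deduplication stand in for the stochastic
restarts of classical inverse-folding tools; the design space of a
target grows as 4^(number of pairs) (each stem pair admits four
Watson-Crick choices), which motivates sampling over enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .fold import FoldResult, mfe_fold
from .params import EnergyParameterSet, default_parameters
from .screen import QuadruplexHit, g4_scan
from .structures import (DnaSequence, PairTable, StructureError,
                         base_pair_distance, to_dotbracket)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class DesignError(ValueError):
    """Infeasible constraints or invalid design input."""


@dataclass(frozen=True)
class SequenceConstraint:
    """Positional sequence constraints for a target of length n.

    ``allowed[i]`` (0-based internally) is the tuple of admissible bases
    at position i.  Named intervals (1-based, inclusive) may designate
    functional segments such as recognition loops or the junction.
    """

    length: int
    allowed: tuple[tuple[str, ...], ...]
    intervals: tuple[tuple[str, int, int], ...] = ()

    @classmethod
    def from_iupac(cls, code: str,
                   intervals: Sequence[tuple[str, int, int]] = ()) -> "SequenceConstraint":
        allowed = []
        for i, ch in enumerate(code.upper()):
            if ch not in IUPAC:
                raise DesignError(f"position {i + 1}: unknown IUPAC code {ch!r}")
            allowed.append(tuple(IUPAC[ch]))
        return cls(len(code), tuple(allowed), tuple(intervals))

    @classmethod
    def unconstrained(cls, length: int,
                      intervals: Sequence[tuple[str, int, int]] = ()) -> "SequenceConstraint":
        return cls(length, tuple(tuple("ACGT") for _ in range(length)),
                   tuple(intervals))

    @classmethod
    def fixing(cls, seq: DnaSequence) -> "SequenceConstraint":
        """Every position fixed to the given sequence."""
        return cls(len(seq), tuple((c,) for c in seq.residues))

    def __post_init__(self) -> None:
        if len(self.allowed) != self.length:
            raise DesignError("constraint length mismatch")
        for name, a, b in self.intervals:
            if not (1 <= a <= b <= self.length):
                raise DesignError(f"interval {name!r} [{a},{b}] outside 1..{self.length}")

    def allowed_at(self, i: int) -> tuple[str, ...]:
        """Admissible bases at 0-based position i."""
        return self.allowed[i]

    def satisfied_by(self, seq: Union[DnaSequence, str]) -> bool:
        res = seq.residues if isinstance(seq, DnaSequence) else seq
        return len(res) == self.length and all(
            res[i] in self.allowed[i] for i in range(self.length))

    def interval(self, name: str) -> tuple[int, int]:
        for nm, a, b in self.intervals:
            if nm == name:
                return a, b
        raise KeyError(name)


@dataclass(frozen=True)
class DesignRun:
    """Outcome of one seeded inverse-folding walk."""

    seed: int
    steps: int
    success: bool
    sequence: DnaSequence
    distance: int
    fold: FoldResult


@dataclass(frozen=True)
class ScoredDesign:
    """A unique successful design with its MFE score and G4 screen."""

    sequence: DnaSequence
    fold: FoldResult
    g4_hits: tuple[QuadruplexHit, ...]

    @property
    def g4_flagged(self) -> bool:
        return len(self.g4_hits) > 0


@dataclass(frozen=True)
class DesignBatch:
    """Deduplicated, ranked outcome of repeated inverse-folding runs.

    ``unique`` holds one entry per distinct successful sequence;
    ``ranking`` excludes G4-flagged designs and is sorted by MFE
    ascending, ties lexicographic by sequence.
    """

    target: PairTable
    constraints: SequenceConstraint
    n_runs: int
    master_seed: int
    runs: tuple[DesignRun, ...]
    unique: tuple[ScoredDesign, ...]
    ranking: tuple[ScoredDesign, ...]

    @property
    def n_success(self) -> int:
        return sum(1 for r in self.runs if r.success)

    @property
    def best(self) -> ScoredDesign:
        if not self.ranking:
            raise DesignError("batch has no rankable design")
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {
            "target": to_dotbracket(self.target),
            "n_runs": self.n_runs,
            "master_seed": self.master_seed,
            "n_success": self.n_success,
            "n_unique": len(self.unique),
            "runs": [{"seed": r.seed, "steps": r.steps, "success": r.success,
                      "distance": r.distance,
                      "sequence": r.sequence.residues} for r in self.runs],
            "ranking": [{"id": d.sequence.id, "sequence": d.sequence.residues,
                         "energy_kcal_mol": d.fold.energy,
                         "g4_flagged": d.g4_flagged} for d in self.ranking],
            "excluded_g4": [{"id": d.sequence.id, "sequence": d.sequence.residues}
                            for d in self.unique if d.g4_flagged],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------

def _check_feasible(target: PairTable, constraints: SequenceConstraint,
                    params: EnergyParameterSet) -> None:
    if target.n != constraints.length:
        raise DesignError(
            f"target length {target.n} != constraint length {constraints.length}")
    for i, j in target.pairs:
        opts = [(a, b) for a in constraints.allowed_at(i - 1)
                for b in constraints.allowed_at(j - 1) if params.can_pair(a, b)]
        if not opts:
            raise DesignError(
                f"constraints at paired positions {i},{j} admit no allowed pair")


def _pair_options(target: PairTable, constraints: SequenceConstraint,
                  params: EnergyParameterSet) -> dict[int, list]:
    opts = {}
    for i, j in target.pairs:
        opts[i - 1] = [(a, b) for a in constraints.allowed_at(i - 1)
                       for b in constraints.allowed_at(j - 1)
                       if params.can_pair(a, b)]
    return opts


def inverse_fold(target: PairTable, constraints: Optional[SequenceConstraint] = None,
                 seed: int = 0, max_steps: Optional[int] = None,
                 params: Optional[EnergyParameterSet] = None,
                 run_id: str = "design") -> DesignRun:
    """One seeded adaptive-walk inverse-folding run.

    Success iff the best candidate's MFE structure equals the target
    (base-pair distance 0).  Deterministic for a fixed seed.  Raises
    :class:`DesignError` before searching when the constraints are
    infeasible for the target.
    """
    if params is None:
        params = default_parameters()
    if constraints is None:
        constraints = SequenceConstraint.unconstrained(target.n)
    _check_feasible(target, constraints, params)
    n = target.n
    if max_steps is None:
        max_steps = 50 * n
    rng = np.random.default_rng(seed)
    pair_opts = _pair_options(target, constraints, params)
    partner = target.partner

    def random_pair(i: int) -> tuple[str, str]:
        o = pair_opts[i]
        return o[rng.integers(len(o))]

    # initial candidate: joint complementary choice at pairs, uniform elsewhere
    cur = [""] * n
    for i in range(n):
        p = partner[i]
        if p > i:
            a, b = random_pair(i)
            cur[i], cur[p] = a, b
        elif p == -1:
            opts = constraints.allowed_at(i)
            cur[i] = opts[rng.integers(len(opts))]

    def fold_of(residues: list[str]) -> FoldResult:
        return mfe_fold(DnaSequence(run_id, "".join(residues)), params)

    fr = fold_of(cur)
    dist = base_pair_distance(fr.structure, target)
    best = (dist, list(cur), fr)
    steps = 0
    while dist > 0 and steps < max_steps:
        steps += 1
        # positions implicated in defective pairs
        defects = sorted({p for ij in
                          set(fr.structure.pairs) ^ set(target.pairs)
                          for p in ij})
        pos = defects[rng.integers(len(defects))] - 1
        saved = list(cur)
        p = partner[pos]
        if p != -1:
            i = min(pos, p)
            a, b = random_pair(i)
            cur[i], cur[partner[i]] = a, b
        else:
            opts = constraints.allowed_at(pos)
            cur[pos] = opts[rng.integers(len(opts))]
        if cur == saved:
            continue
        fr2 = fold_of(cur)
        d2 = base_pair_distance(fr2.structure, target)
        if d2 <= dist:
            fr, dist = fr2, d2
            if d2 < best[0]:
                best = (d2, list(cur), fr2)
        else:
            cur = saved
    if dist < best[0]:
        best = (dist, list(cur), fr)
    d, residues, frb = best
    seq = DnaSequence(run_id, "".join(residues))
    return DesignRun(seed=int(seed), steps=steps, success=(d == 0),
                     sequence=seq, distance=d, fold=frb)


def run_design_batch(target: PairTable,
                     constraints: Optional[SequenceConstraint] = None,
                     n_runs: int = 1000, master_seed: int = 0,
                     params: Optional[EnergyParameterSet] = None,
                     max_steps: Optional[int] = None,
                     exclude_g4: bool = True) -> DesignBatch:
    """Repeat :func:`inverse_fold` ``n_runs`` times with per-run seeds
    derived from ``master_seed``, deduplicate successful sequences,
    score each by MFE, screen for G-quadruplex motifs and rank.

    Identical ``master_seed`` reproduces the batch exactly, including
    the ranking order.
    """
    if n_runs < 1:
        raise DesignError("n_runs must be >= 1")
    if params is None:
        params = default_parameters()
    if constraints is None:
        constraints = SequenceConstraint.unconstrained(target.n)
    # stable per-run seeds derived from the master seed, kept below 2^31
    seeds = (np.random.SeedSequence(master_seed).generate_state(n_runs)
             & np.uint32(0x7FFFFFFF))
    runs = []
    for k, s in enumerate(seeds):
        runs.append(inverse_fold(target, constraints, seed=int(s),
                                 max_steps=max_steps, params=params,
                                 run_id=f"design_{k:04d}"))
    seen: dict[str, DesignRun] = {}
    for r in runs:
        if r.success and r.sequence.residues not in seen:
            seen[r.sequence.residues] = r
    unique = []
    for res, r in seen.items():
        hits = tuple(g4_scan(r.sequence)) if exclude_g4 else ()
        unique.append(ScoredDesign(r.sequence, r.fold, hits))
    ranking = tuple(sorted((d for d in unique if not d.g4_flagged),
                           key=lambda d: (d.fold.energy_int, d.sequence.residues)))
    return DesignBatch(target, constraints, n_runs, int(master_seed),
                       tuple(runs), tuple(unique), ranking)


def minimize_design(run: DesignRun, spec, params=None, **scan_kwargs):
    """Re-truncate a successful design: the paper's per-design
    minimization step.  Returns the minimal motif-preserving
    :class:`~aptamin.truncate.TruncationCandidate`."""
    from .truncate import truncation_scan
    if not run.success:
        raise DesignError("cannot minimize an unsuccessful design run")
    return truncation_scan(run.sequence, spec, params, **scan_kwargs).selected


@dataclass(frozen=True)
class RestoredDesign:
    """A design after loop-sequence restoration, refolded."""

    sequence: DnaSequence
    fold: FoldResult
    structure_preserved: bool


def restore_loop_sequences(design: DnaSequence,
                           edits: Sequence[tuple[int, int, str]],
                           target: PairTable,
                           params: Optional[EnergyParameterSet] = None) -> RestoredDesign:
    """Overwrite designated loop intervals with their original
    (functional) sequences and refold.

    ``edits`` are (start, end, replacement) with 1-based inclusive
    coordinates; every edited position must be unpaired in ``target``
    (loops are recognition elements precisely because they are
    single-stranded).  The returned flag records whether the edited
    sequence still folds exactly to ``target``.
    """
    if params is None:
        params = default_parameters()
    if len(design) != target.n:
        raise DesignError("design length != target length")
    residues = list(design.residues)
    for start, end, repl in edits:
        if not (1 <= start <= end <= target.n):
            raise DesignError(f"edit interval [{start},{end}] out of range")
        if end - start + 1 != len(repl):
            raise DesignError(
                f"edit interval [{start},{end}] has length {end - start + 1} "
                f"but replacement {repl!r} has length {len(repl)}")
        for p in range(start, end + 1):
            if target.partner[p - 1] != -1:
                raise DesignError(
                    f"edit position {p} is paired in the target structure")
        residues[start - 1:end] = list(repl.upper())
    seq = DnaSequence(f"{design.id}_restored", "".join(residues))
    fr = mfe_fold(seq, params)
    preserved = base_pair_distance(fr.structure, target) == 0
    return RestoredDesign(seq, fr, preserved)


def junction_variants(seq: DnaSequence, junction: tuple[int, int],
                      compositions: Sequence[str]) -> list[DnaSequence]:
    """One variant per junction composition (e.g. AAAA / TTTT / ATAT),
    all other positions untouched."""
    start, end = junction
    if not (1 <= start <= end <= len(seq)):
        raise DesignError(f"junction [{start},{end}] out of range")
    width = end - start + 1
    out = []
    for comp in compositions:
        if len(comp) != width:
            raise DesignError(
                f"composition {comp!r} has length {len(comp)}, junction has {width}")
        residues = (seq.residues[:start - 1] + comp.upper() + seq.residues[end:])
        out.append(DnaSequence(f"{seq.id}_{comp.upper()}", residues))
    return out


def design_space_size(target: PairTable) -> int:
    """4 raised to the number of base pairs: each stem pair admits four
    Watson-Crick realizations."""
    return 4 ** target.n_pairs()
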