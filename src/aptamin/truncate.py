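"""Sliding-window truncation of a parent aptamer.

Enumerates 5'/3' end trims on a grid, refolds every candidate
subsequence, and tests whether the designated multiloop motif survives
in the refolded structure.  Refolding is the point: a trim that looks
harmless "on paper" (the motif's positions untouched) can still collapse
the structure into something entirely different, so preservation is
always judged on the re-predicted MFE structure, never on the parent's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fold import FoldResult, mfe_fold
from .params import EnergyParameterSet, default_parameters
from .structures import (DnaSequence, MotifMatch, MotifSpec, StructureError,
                         matches_motif, to_dotbracket)


@dataclass(frozen=True)
class TruncationCandidate:
    """One grid point: trim5/trim3 bases removed, the refolded
    subsequence, and whether the motif survived."""

    trim5: int
    trim3: int
    subsequence: DnaSequence
    fold: FoldResult
    motif_preserved: bool
    match: Optional[MotifMatch]

    @property
    def total_trim(self) -> int:
        return self.trim5 + self.trim3


@dataclass(frozen=True)
class TruncationLandscape:
    """All candidates of a truncation scan, sorted by total trim then
    trim5, plus the selected minimal motif-preserving candidate."""

    parent: DnaSequence
    spec: MotifSpec
    candidates: tuple[TruncationCandidate, ...]
    selected: TruncationCandidate

    @property
    def preserving(self) -> tuple[TruncationCandidate, ...]:
        return tuple(c for c in self.candidates if c.motif_preserved)

    def to_frame(self):
        """Landscape as a pandas DataFrame (one row per grid point)."""
        import pandas as pd
        return pd.DataFrame([
            {"trim5": c.trim5, "trim3": c.trim3,
             "length": len(c.subsequence),
             "energy_kcal_mol": c.fold.energy,
             "motif_preserved": c.motif_preserved,
             "dotbracket": c.fold.dotbracket}
            for c in self.candidates])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def truncation_scan(parent: DnaSequence, spec: MotifSpec,
                    params: Optional[EnergyParameterSet] = None,
                    max_trim5: Optional[int] = None,
                    max_trim3: Optional[int] = None,
                    min_length: int = 8) -> TruncationLandscape:
    """Fold and motif-test every (trim5, trim3) combination on the grid.

    Default maximum trims are n/2 on each side.  Raises
    :class:`StructureError` if the untrimmed parent already lacks the
    motif.  Deterministic.
    """
    if params is None:
        params = default_parameters()
    n = len(parent)
    if max_trim5 is None:
        max_trim5 = n // 2
    if max_trim3 is None:
        max_trim3 = n // 2

    rows: list[TruncationCandidate] = []
    for t5 in range(0, max_trim5 + 1):
        for t3 in range(0, max_trim3 + 1):
            if n - t5 - t3 < min_length:
                continue
            sub = parent.subsequence(t5, n - t3,
                                     id=f"{parent.id}_t5={t5}_t3={t3}")
            fr = mfe_fold(sub, params)
            sub_spec = spec.shifted(t5, len(sub))
            if sub_spec is None:
                ok, match = False, None
            else:
                ok, match = matches_motif(fr.structure, sub_spec)
            rows.append(TruncationCandidate(t5, t3, sub, fr, ok, match))

    rows.sort(key=lambda c: (c.total_trim, c.trim5))
    root = rows[0]
    assert root.trim5 == 0 and root.trim3 == 0
    if not root.motif_preserved:
        raise StructureError(
            f"parent {parent.id!r} lacks the required motif even untrimmed")
    selected = select_minimal_rows(rows)
    return TruncationLandscape(parent, spec, tuple(rows), selected)


def select_minimal_rows(rows) -> TruncationCandidate:
    preserving = [c for c in rows if c.motif_preserved]
    if not preserving:
        raise StructureError("no motif-preserving truncation candidate")
    # shortest surviving sequence; ties by lower energy, then smaller trim5
    return min(preserving,
               key=lambda c: (-c.total_trim, c.fold.energy_int, c.trim5))


def select_minimal(landscape: TruncationLandscape,
                   criterion: str = "max_trim") -> TruncationCandidate:
    """Select the minimal motif-preserving candidate.

    ``max_trim`` (default): maximal total trim among preserving rows,
    ties broken by lower folding energy, then smaller trim5.
    ``min_energy``: lowest folding energy among preserving rows.
    """
    preserving = list(landscape.preserving)
    if not preserving:
        raise StructureError("no motif-preserving truncation candidate")
    if criterion == "max_trim":
        return select_minimal_rows(preserving)
    if criterion == "min_energy":
        return min(preserving,
                   key=lambda c: (c.fold.energy_int, -c.total_trim, c.trim5))
    raise ValueError(f"unknown criterion {criterion!r}")


def plot_landscape(landscape: TruncationLandscape, ax=None):
    """Minimal figure helper: energy vs total trim for motif-preserving
    candidates (the published landscape shows exactly this view)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    pres = landscape.preserving
    ax.scatter([c.total_trim for c in pres],
               [c.fold.energy for c in pres], s=12)
    ax.set_xlabel("total bases trimmed")
    ax.set_ylabel("MFE (kcal/mol)")
    ax.set_title(f"truncation landscape: {landscape.parent.id}")
    return ax
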