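"""End-to-end aptamer minimization pipeline.

Stages, mirroring the in-silico workflow that produced the Gol1 aptamer
from its U2-style parent: fold the parent, truncate it while preserving
the designated multiloop motif, redesign the minimized scaffold by
repeated constrained inverse folding, re-truncate the ranked designs,
restore the functional loop sequences of the best design, emit junction
composition variants, and screen everything for G-quadruplex motifs.

Every run writes a resolved-configuration JSON carrying the master seed
and the parameter-file checksum; re-running with the same seed
reproduces all outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .design import (DesignBatch, RestoredDesign, SequenceConstraint,
                     junction_variants, restore_loop_sequences,
                     run_design_batch)
from .fold import FoldResult, mfe_fold
from .io import write_fasta, write_vienna
from .params import EnergyParameterSet, default_parameters, load_parameter_set
from .screen import g4_scan, write_g4_bed
from .structures import DnaSequence, MotifSpec
from .truncate import TruncationCandidate, TruncationLandscape, truncation_scan


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration (serializable).

    With ``n_runs = 0`` the pipeline stops after folding (and, when the
    trim grid is non-trivial, truncating) the parent.
    """

    parent: DnaSequence
    out_dir: Union[str, Path]
    param_file: Optional[str] = None
    motif: MotifSpec = field(default_factory=MotifSpec)
    max_trim5: Optional[int] = 0
    max_trim3: Optional[int] = 0
    n_runs: int = 0
    master_seed: int = 0
    max_steps: Optional[int] = None
    top_k_retruncate: int = 3
    loop_edits: tuple[tuple[int, int, str], ...] = ()
    junction: Optional[tuple[int, int]] = None
    junction_compositions: tuple[str, ...] = ("AAAA", "TTTT", "ATAT")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["parent"] = {"id": self.parent.id, "residues": self.parent.residues}
        d.pop("out_dir")  # runtime location, not part of the science
        d["motif"] = {"kind": self.motif.kind,
                      "min_helices": self.motif.min_helices,
                      "fragment": self.motif.fragment,
                      "loop_segments": list(self.motif.loop_segments),
                      "near": self.motif.near}
        return d


@dataclass(frozen=True)
class PipelineReport:
    """In-memory results of a pipeline run (files are written too)."""

    config: PipelineConfig
    parent_fold: FoldResult
    landscape: Optional[TruncationLandscape]
    minimal: Optional[TruncationCandidate]
    batch: Optional[DesignBatch]
    retruncated: tuple[TruncationCandidate, ...]
    restored: Optional[RestoredDesign]
    variants: tuple[DnaSequence, ...]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the configured stages; deterministic given the master seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = (load_parameter_set(config.param_file) if config.param_file
              else default_parameters())

    parent_fold = mfe_fold(config.parent, params)
    write_vienna(parent_fold, out / "parent.vienna")

    landscape = minimal = None
    if (config.max_trim5 or 0) > 0 or (config.max_trim3 or 0) > 0 \
            or config.max_trim5 is None or config.max_trim3 is None:
        landscape = truncation_scan(config.parent, config.motif, params,
                                    config.max_trim5, config.max_trim3)
        landscape.to_tsv(out / "landscape.tsv")
        minimal = landscape.selected

    batch = None
    retruncated: list[TruncationCandidate] = []
    restored = None
    variants: list[DnaSequence] = []
    if config.n_runs > 0:
        scaffold = minimal.fold if minimal is not None else parent_fold
        target = scaffold.structure
        constraints = SequenceConstraint.unconstrained(target.n)
        batch = run_design_batch(target, constraints, config.n_runs,
                                 config.master_seed, params,
                                 max_steps=config.max_steps)
        batch.to_json(out / "batch.json")
        write_fasta([d.sequence for d in batch.ranking], out / "ranked.fasta")

        from .structures import StructureError
        for d in batch.ranking[:config.top_k_retruncate]:
            try:
                land = truncation_scan(d.sequence, config.motif, params,
                                       config.max_trim5, config.max_trim3)
                retruncated.append(land.selected)
            except StructureError:
                continue  # design lost the motif under re-truncation

        if batch.ranking:
            best = batch.ranking[0]
            if config.loop_edits:
                restored = restore_loop_sequences(best.sequence,
                                                 config.loop_edits,
                                                 target, params)
                final_seq = restored.sequence
            else:
                final_seq = best.sequence
            if config.junction is not None:
                variants = junction_variants(final_seq, config.junction,
                                             config.junction_compositions)
                write_fasta(variants, out / "variants.fasta")

    screened = {config.parent.id: g4_scan(config.parent)}
    if batch is not None:
        for d in batch.unique:
            screened[d.sequence.id] = list(d.g4_hits)
    for v in variants:
        screened[v.id] = g4_scan(v)
    write_g4_bed(screened, out / "screen.tsv")

    report = {
        "master_seed": config.master_seed,
        "param_sha256": params.sha256,
        "dangle_model": params.dangle_model,
        "parent": {"id": config.parent.id,
                   "length": len(config.parent),
                   "energy_kcal_mol": parent_fold.energy,
                   "dotbracket": parent_fold.dotbracket},
        "minimal": None if minimal is None else {
            "trim5": minimal.trim5, "trim3": minimal.trim3,
            "length": len(minimal.subsequence),
            "energy_kcal_mol": minimal.fold.energy},
        "design": None if batch is None else {
            "n_runs": batch.n_runs, "n_success": batch.n_success,
            "n_unique": len(batch.unique),
            "best_energy_kcal_mol": (batch.ranking[0].fold.energy
                                     if batch.ranking else None)},
        "restored": None if restored is None else {
            "sequence": restored.sequence.residues,
            "energy_kcal_mol": restored.fold.energy,
            "structure_preserved": restored.structure_preserved},
        "variants": [v.id for v in variants],
        "config": config.to_dict(),
    }
    with open(out / "pipeline.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return PipelineReport(config, parent_fold, landscape, minimal, batch,
                          tuple(retruncated), restored, variants)
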