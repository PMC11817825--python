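"""Loop-energy terms and structure-given evaluation."""

import dataclasses

import pytest

from aptamin.energy import (EnergyModelError, eval_structure_energy,
                            eval_structure_energy_int, loop_energy)
from aptamin.fold import mfe_fold
from aptamin.structures import DnaSequence, decompose, parse_dotbracket

from test_params import _section_lines


def _face(db, kind):
    (face,) = [l for l in decompose(parse_dotbracket(db)) if l.kind == kind]
    return face


def test_exterior_all_unpaired_is_zero(params):
    seq = DnaSequence("u", "ACGTA")
    pt = parse_dotbracket(".....")
    assert loop_energy(_face(".....", "exterior"), seq, params) == 0
    assert eval_structure_energy(seq, pt, params) == 0.0


def test_multiloop_zero_coefficients(params):
    zero = dataclasses.replace(params, ml_closing=0, ml_per_helix=0,
                               ml_per_unpaired=0, terminal_at=0)
    seq = DnaSequence("m", "GGAAGGAAACCAAGGAAACCAACC")
    ml = _face("((..((...))..((...))..))", "multiloop")
    assert loop_energy(ml, seq, zero) == 0


def test_multiloop_linear_formula(params):
    # a + b*(helices) + c*(unpaired) + per-helix AT penalties (none here: all GC)
    seq = DnaSequence("m", "GGAAGGAAACCAAGGAAACCAACC")
    ml = _face("((..((...))..((...))..))", "multiloop")
    expected = (params.ml_closing + 3 * params.ml_per_helix
                + 6 * params.ml_per_unpaired)
    assert loop_energy(ml, seq, params) == expected


def test_hairpin4_closed_by_gc_is_file_length_term(params):
    # with no mismatch tables in the bundled set, the 4-nt hairpin term is
    # exactly the length-4 entry of the file's hairpin table
    file_hp4 = int(" ".join(_section_lines("hairpin")).split()[3])
    seq = DnaSequence("h", "GAAAAC")
    assert loop_energy(_face("(....)", "hairpin"), seq, params) == file_hp4


def test_hairpin_below_minimum_rejected(params):
    seq = DnaSequence("h", "GAAC")
    with pytest.raises(EnergyModelError, match="minimum is 3"):
        eval_structure_energy(seq, parse_dotbracket("(..)"), params)


def test_gc_hairpin_hand_sum(params):
    # 12-nt stem-loop: three stacks + one 4-nt hairpin, summed by hand
    # from independently re-read file entries
    stack_rows = [list(map(int, r.split())) for r in _section_lines("stack")]
    hp_toks = " ".join(_section_lines("hairpin")).split()
    CG, GC = 0, 1
    expected = (stack_rows[GC][CG]      # G-C on C-G
                + stack_rows[CG][GC]    # C-G on G-C
                + stack_rows[GC][CG]    # G-C on C-G
                + int(hp_toks[3]))      # 4-nt hairpin
    seq = DnaSequence("s", "GCGCAAAAGCGC")
    got = eval_structure_energy_int(seq, parse_dotbracket("((((....))))"), params)
    assert got == expected
    # and the folding engine finds exactly this structure and energy
    fr = mfe_fold(seq, params)
    assert fr.energy_int == expected
    assert fr.dotbracket == "((((....))))"


def test_bulge1_keeps_flanking_stack(params):
    # single-nt bulge: length-1 bulge term plus the preserved stack
    seq = DnaSequence("b", "GCAGCAAAAGCGC")
    pt = parse_dotbracket("((.((....))))")
    bulge = _face("((.((....))))", "bulge")
    inner = params.stack_energy(("C", "G"), ("G", "C"))
    assert loop_energy(bulge, seq, params) == params.bulge_energy(1) + inner


def test_terminal_at_penalty_on_internal_loop(params):
    # AT-closed internal loop pays the terminal-AT penalty on that side
    seq_at = DnaSequence("i", "GAAGCAAAAGCATC")
    seq_gc = DnaSequence("i", "GGAGCAAAAGCACC")
    db = "((.((....)).))"
    e_at = loop_energy(_face(db, "internal"), seq_at, params)
    e_gc = loop_energy(_face(db, "internal"), seq_gc, params)
    assert e_at - e_gc == params.at_penalty(("A", "T"))


def test_disallowed_pair_names_positions(params):
    seq = DnaSequence("x", "GGAAAAAC")
    with pytest.raises(EnergyModelError, match="2-7"):
        eval_structure_energy(seq, parse_dotbracket("((....))"), params)


def test_eval_matches_fold_energy(params, gol1, gol1_fold):
    assert eval_structure_energy_int(gol1, gol1_fold.structure, params) \
        == gol1_fold.energy_int
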