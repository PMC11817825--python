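"""Dot-bracket parsing, loop decomposition, distances, motif matching."""

import pytest
from hypothesis import given, settings, strategies as st

from aptamin.structures import (DnaSequence, MotifSpec, PairTable,
                                StructureError, base_pair_distance, decompose,
                                matches_motif, parse_dotbracket, to_dotbracket)


@st.composite
def dotbrackets(st_draw, max_len=40):
    """Random balanced dot-bracket strings (any nesting, incl. short loops)."""
    n = st_draw(st.integers(min_value=0, max_value=max_len))
    out, depth = [], 0
    for k in range(n):
        choices = ["."]
        if n - k > depth:  # room left to close what we open
            choices.append("(")
        if depth > 0:
            choices.append(")")
        ch = st_draw(st.sampled_from(choices))
        out.append(ch)
        depth += {"(": 1, ")": -1, ".": 0}[ch]
    out.extend(")" * depth)
    return "".join(out)


class TestParseEmit:
    @pytest.mark.parametrize("text,pairs", [
        ("((((...))))", ((1, 11), (2, 10), (3, 9), (4, 8))),
        (".....", ()),
        ("((..))", ((1, 6), (2, 5))),
    ])
    def test_examples(self, text, pairs):
        assert parse_dotbracket(text).pairs == pairs

    @pytest.mark.parametrize("text,pos", [("(()", 1), (")", 1), ("..)..", 3)])
    def test_unbalanced_names_position(self, text, pos):
        with pytest.raises(StructureError, match=f"unbalanced at position {pos}"):
            parse_dotbracket(text)

    def test_illegal_character(self):
        with pytest.raises(StructureError, match="position 3"):
            parse_dotbracket("..[..")

    def test_emit_examples(self):
        assert to_dotbracket(PairTable([-1] * 5)) == "....."
        assert to_dotbracket(PairTable([5, 4, -1, -1, 1, 0])) == "((..))"

    @given(dotbrackets())
    @settings(derandomize=True, max_examples=150)
    def test_round_trip(self, text):
        pt = parse_dotbracket(text)
        assert to_dotbracket(pt) == text
        assert parse_dotbracket(to_dotbracket(pt)) == pt


class TestPairTableValidation:
    def test_rejects_crossing(self):
        with pytest.raises(StructureError, match="pseudoknot"):
            PairTable([2, 3, 0, 1])

    def test_rejects_asymmetry(self):
        with pytest.raises(StructureError, match="asymmetric"):
            PairTable([3, -1, -1, 1])

    def test_rejects_self_pair(self):
        with pytest.raises(StructureError, match="itself"):
            PairTable([0, -1])


class TestDecompose:
    def test_hairpin_stem(self):
        faces = decompose(parse_dotbracket("((((...))))"))
        kinds = sorted(l.kind for l in faces)
        assert kinds == ["exterior", "hairpin", "stack", "stack", "stack"]

    def test_three_way_junction(self):
        pt = parse_dotbracket("((..((...))..((...))..))")
        mls = decompose(pt).multiloops
        assert len(mls) == 1
        (ml,) = mls
        assert ml.n_helices == 3          # closing helix + 2 branches
        assert len(ml.unpaired) == 6
        assert ml.closing == (2, 23)

    def test_bulge_internal(self):
        faces = {l.kind for l in decompose(parse_dotbracket("((.((...))))"))}
        assert "bulge" in faces
        faces = {l.kind for l in decompose(parse_dotbracket("((.((...)).))"))}
        assert "internal" in faces

    @given(dotbrackets())
    @settings(derandomize=True, max_examples=150)
    def test_face_size_accounting(self, text):
        # unpaired positions appear once, paired positions twice
        pt = parse_dotbracket(text)
        total = sum(l.size for l in decompose(pt))
        assert total == pt.n + 2 * pt.n_pairs()

    def test_every_position_covered_once(self):
        pt = parse_dotbracket("((..((...))..((...))..))")
        unpaired_seen = [p for l in decompose(pt) for p in l.unpaired]
        expected = [i + 1 for i, x in enumerate(pt.partner) if x == -1]
        assert sorted(unpaired_seen) == expected

    def test_synthetic_fixture_has_multiloop(self, synthetic_parent):
        # the junction face is closed by the innermost pair of stem 0
        _, _, pt, coords = synthetic_parent
        mls = decompose(pt).multiloops
        assert len(mls) == 1
        (s0_open, s0_close) = coords.stem_intervals[0]
        assert mls[0].closing == (s0_open[1], s0_close[0])


class TestBasePairDistance:
    def test_examples(self):
        a = parse_dotbracket("((..))")
        assert base_pair_distance(a, a) == 0
        assert base_pair_distance(a, parse_dotbracket("......")) == 2

    def test_length_mismatch(self):
        with pytest.raises(StructureError, match="length mismatch"):
            base_pair_distance(parse_dotbracket("..."), parse_dotbracket(".."))

    def test_equals_brute_force_symmetric_difference(self):
        # independent pair extraction with a throwaway bracket matcher
        def pairs_of(db):
            stack, out = [], set()
            for i, ch in enumerate(db):
                if ch == "(":
                    stack.append(i + 1)
                elif ch == ")":
                    out.add((stack.pop(), i + 1))
            return out

        sa = "((((...)))).((...))...."
        sb = "..((...))...((...))...."
        brute = len(pairs_of(sa) ^ pairs_of(sb))
        assert brute == 2  # a's two outermost pairs are absent from b
        assert base_pair_distance(parse_dotbracket(sa),
                                  parse_dotbracket(sb)) == brute

    @given(dotbrackets(max_len=30), dotbrackets(max_len=30),
           dotbrackets(max_len=30))
    @settings(derandomize=True, max_examples=100)
    def test_metric(self, x, y, z):
        n = max(len(x), len(y), len(z))
        a = parse_dotbracket(x.ljust(n, "."))
        b = parse_dotbracket(y.ljust(n, "."))
        c = parse_dotbracket(z.ljust(n, "."))
        assert base_pair_distance(a, a) == 0
        assert base_pair_distance(a, b) == base_pair_distance(b, a)
        assert (base_pair_distance(a, c) <=
                base_pair_distance(a, b) + base_pair_distance(b, c))


class TestMotif:
    def test_hairpin_fails_multiloop_spec(self):
        ok, match = matches_motif(parse_dotbracket("((((...))))"), MotifSpec())
        assert not ok and match is None

    def test_three_helix_junction_matches(self):
        ok, match = matches_motif(
            parse_dotbracket("((..((...))..((...))..))"),
            MotifSpec(min_helices=3))
        assert ok
        assert match.closing == (2, 23)
        assert match.branches == ((5, 11), (14, 20))

    def test_min_helices_enforced(self):
        ok, _ = matches_motif(parse_dotbracket("((..((...))..((...))..))"),
                              MotifSpec(min_helices=4))
        assert not ok

    def test_synthetic_fixture_match_at_known_coordinates(self, synthetic_parent):
        _, _, pt, coords = synthetic_parent
        ok, match = matches_motif(pt, coords.motif_spec())
        assert ok
        s0_open, s0_close = coords.stem_intervals[0]
        assert match.closing == (s0_open[1], s0_close[0])
        (s1_open, s1_close) = coords.stem_intervals[1]
        (s2_open, s2_close) = coords.stem_intervals[2]
        assert match.branches == ((s1_open[0], s1_close[1]),
                                  (s2_open[0], s2_close[1]))

    def test_loop_segments_must_be_unpaired(self):
        pt = parse_dotbracket("((..((...))..((...))..))")
        ok, _ = matches_motif(pt, MotifSpec(loop_segments=((3, 4),)))
        assert ok
        ok, _ = matches_motif(pt, MotifSpec(loop_segments=((1, 2),)))
        assert not ok

    def test_fragment_must_be_balanced(self):
        with pytest.raises(StructureError):
            MotifSpec(fragment="((..)")
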