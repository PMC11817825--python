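"""Pseudoknot-free DNA secondary structures.

Dot-bracket parsing/emission, pair tables, unique loop-face decomposition
(stacks, hairpins, bulges, internal loops, multiloops, exterior loop),
base-pair distance, and multiloop motif matching.

Positions are 0-based internally; every user-facing report (``pairs``,
loop records, motif matches) is 1-based, following biology convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

DNA_ALPHABET = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Watson-Crick pairs admitted by the bundled energy model.
WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class StructureError(ValueError):
    """Invalid structure, sequence or dot-bracket input."""


@dataclass(frozen=True)
class DnaSequence:
    """An identified single-stranded DNA sequence over {A, C, G, T}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if len(res) < 1:
            raise StructureError(f"sequence {self.id!r} is empty")
        bad = set(res) - DNA_ALPHABET
        if bad:
            hint = " (use the DNA alphabet: A, C, G, T)" if "U" in bad else ""
            raise StructureError(
                f"sequence {self.id!r} contains illegal characters "
                f"{sorted(bad)}{hint}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]

    def subsequence(self, start: int, end: int, id: Optional[str] = None) -> "DnaSequence":
        """Contiguous substring [start, end) in 0-based coordinates."""
        return DnaSequence(id or f"{self.id}[{start + 1}-{end}]",
                           self.residues[start:end])


class PairTable:
    """A pseudoknot-free set of base pairs on ``n`` positions.

    ``partner[i]`` is the 0-based partner of position ``i`` or -1 if
    unpaired.  Construction validates symmetry, self-pairing and pair
    crossings; hairpin-size and pairing-rule constraints live in the
    thermodynamic layer (a structure like ``((..))`` is representable but
    has no finite energy under the bundled model).
    """

    __slots__ = ("n", "partner")

    def __init__(self, partner: Sequence[int]):
        self.n = len(partner)
        self.partner = tuple(int(p) for p in partner)
        self._validate()

    def _validate(self) -> None:
        seen_open: list[int] = []
        for i, p in enumerate(self.partner):
            if p == -1:
                continue
            if not (0 <= p < self.n):
                raise StructureError(f"partner of position {i + 1} out of range")
            if p == i:
                raise StructureError(f"position {i + 1} paired with itself")
            if self.partner[p] != i:
                raise StructureError(
                    f"asymmetric pairing at positions {i + 1}/{p + 1}")
        # crossing check via bracket discipline
        for i, p in enumerate(self.partner):
            if p > i:
                seen_open.append(p)
            elif p != -1:
                if not seen_open or seen_open[-1] != i:
                    raise StructureError(
                        f"pseudoknot: pair ({p + 1},{i + 1}) crosses another pair")
                seen_open.pop()

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """Sorted 1-based (i, j) pairs with i < j."""
        return tuple((i + 1, p + 1) for i, p in enumerate(self.partner) if p > i)

    def n_pairs(self) -> int:
        return sum(1 for i, p in enumerate(self.partner) if p > i)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairTable) and self.partner == other.partner

    def __hash__(self) -> int:
        return hash(self.partner)

    def __repr__(self) -> str:
        return f"PairTable({to_dotbracket(self)!r})"


def parse_dotbracket(text: str) -> PairTable:
    """Parse a single-bracket-type dot-bracket string into a :class:`PairTable`.

    Raises :class:`StructureError` naming the 1-based offending index on an
    illegal character or unbalanced bracket.
    """
    partner = [-1] * len(text)
    stack: list[int] = []
    for i, ch in enumerate(text):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced at position {i + 1}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {i + 1}")
    if stack:
        raise StructureError(f"unbalanced at position {stack[0] + 1}")
    return PairTable(partner)


def to_dotbracket(pt: PairTable) -> str:
    """Emit dot-bracket notation; inverse of :func:`parse_dotbracket`."""
    out = []
    for i, p in enumerate(pt.partner):
        out.append("." if p == -1 else ("(" if p > i else ")"))
    return "".join(out)


def base_pair_distance(a: PairTable, b: PairTable) -> int:
    """Symmetric-difference distance between the two pair sets.

    Zero iff the structures are identical; a metric on structures of
    equal length.
    """
    if a.n != b.n:
        raise StructureError(f"length mismatch: {a.n} vs {b.n}")
    return len(set(a.pairs) ^ set(b.pairs))


# ---------------------------------------------------------------------------
# loop decomposition

@dataclass(frozen=True)
class LoopRecord:
    """One loop face of a secondary structure (1-based coordinates).

    kind: "stack" | "hairpin" | "bulge" | "internal" | "multiloop" | "exterior"
    closing: the (i, j) pair closing the face, or None for the exterior loop.
    branches: pairs of helices emanating into the face (inner pairs).
    unpaired: 1-based unpaired positions belonging to the face.
    """

    kind: str
    closing: Optional[tuple[int, int]]
    branches: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]

    @property
    def size(self) -> int:
        """Face size: unpaired positions plus both members of every
        incident pair (closing and branches)."""
        k = (1 if self.closing else 0) + len(self.branches)
        return len(self.unpaired) + 2 * k

    @property
    def n_helices(self) -> int:
        """Helices meeting the face, closing helix included."""
        return (1 if self.closing else 0) + len(self.branches)


@dataclass(frozen=True)
class LoopDecomposition:
    """The unique loop-face decomposition of a pair table."""

    loops: tuple[LoopRecord, ...]

    @property
    def multiloops(self) -> tuple[LoopRecord, ...]:
        return tuple(l for l in self.loops if l.kind == "multiloop")

    def __iter__(self) -> Iterator[LoopRecord]:
        return iter(self.loops)


def decompose(pt: PairTable) -> LoopDecomposition:
    """Decompose a structure into its loop faces.

    Every position belongs to exactly one face as an unpaired position or
    to exactly two faces as a pair member (the face it closes and its
    parent face), so total face size is n + 2 * n_pairs.
    """
    loops: list[LoopRecord] = []

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], list[int]]:
        """Direct child pairs and unpaired positions strictly inside (i, j)."""
        kids, unp = [], []
        k = i + 1
        while k < j:
            p = pt.partner[k]
            if p == -1:
                unp.append(k)
                k += 1
            else:
                kids.append((k, p))
                k = p + 1
        return kids, unp

    # exterior face
    kids, unp = children_of(-1, pt.n)
    loops.append(LoopRecord(
        "exterior", None,
        tuple((a + 1, b + 1) for a, b in kids),
        tuple(u + 1 for u in unp)))

    stack = [(a, b) for a, b in kids]
    while stack:
        i, j = stack.pop(0)
        kids, unp = children_of(i, j)
        stack.extend(kids)
        if not kids:
            kind = "hairpin"
        elif len(kids) == 1:
            (k, l), = kids
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                kind = "stack"
            elif n1 == 0 or n2 == 0:
                kind = "bulge"
            else:
                kind = "internal"
        else:
            kind = "multiloop"
        loops.append(LoopRecord(
            kind, (i + 1, j + 1),
            tuple((a + 1, b + 1) for a, b in kids),
            tuple(u + 1 for u in unp)))
    return LoopDecomposition(tuple(loops))


# ---------------------------------------------------------------------------
# motif matching

@dataclass(frozen=True)
class MotifSpec:
    """A required structural motif, by default a multiloop (junction).

    min_helices counts the helices meeting the junction, closing helix
    included (a three-way junction has min_helices = 3).  ``fragment`` is
    an optional balanced dot-bracket string that must occur as a
    substructure at some offset.  ``loop_segments`` are 1-based inclusive
    intervals that must be entirely unpaired.  ``near`` optionally pins
    the junction: (position, window) requires the closing pair's 5' side
    within +-window of position.
    """

    kind: str = "multiloop"
    min_helices: int = 3
    fragment: Optional[str] = None
    loop_segments: tuple[tuple[int, int], ...] = ()
    near: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind != "multiloop":
            raise StructureError(f"unsupported motif kind {self.kind!r}")
        if self.fragment is not None:
            parse_dotbracket(self.fragment)  # must itself be balanced
        object.__setattr__(self, "loop_segments",
                           tuple((int(a), int(b)) for a, b in self.loop_segments))

    def shifted(self, offset: int, new_length: int) -> Optional["MotifSpec"]:
        """Translate 1-based coordinates by -offset (e.g. after a 5' trim).

        Returns None when a designated segment or the pinned position
        falls outside [1, new_length] -- the motif can then no longer be
        satisfied by any structure on the trimmed sequence.
        """
        segs = []
        for a, b in self.loop_segments:
            a2, b2 = a - offset, b - offset
            if a2 < 1 or b2 > new_length:
                return None
            segs.append((a2, b2))
        near = None
        if self.near is not None:
            pos, win = self.near
            pos2 = pos - offset
            if pos2 < 1 - win or pos2 > new_length + win:
                return None
            near = (pos2, win)
        return MotifSpec(self.kind, self.min_helices, self.fragment,
                         tuple(segs), near)


@dataclass(frozen=True)
class MotifMatch:
    """Where a motif matched: the junction's closing pair, its branch
    pairs and its unpaired positions (all 1-based)."""

    closing: tuple[int, int]
    branches: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]


def _fragment_occurs(pt: PairTable, fragment: str) -> bool:
    frag = parse_dotbracket(fragment)
    m = frag.n
    fpairs = [(i, p) for i, p in enumerate(frag.partner) if p > i]
    funp = [i for i, p in enumerate(frag.partner) if p == -1]
    for off in range(pt.n - m + 1):
        ok = all(pt.partner[off + i] == off + p for i, p in fpairs) and \
            all(pt.partner[off + i] == -1 for i in funp)
        if ok:
            return True
    return False


def matches_motif(pt: PairTable, spec: MotifSpec) -> tuple[bool, Optional[MotifMatch]]:
    """Test whether the structure contains a junction satisfying ``spec``.

    Any multiloop in the structure may satisfy the spec (position drift is
    allowed unless ``spec.near`` pins it).  Returns (True, match) with the
    first satisfying junction in 5' order, or (False, None).
    """
    for a, b in spec.loop_segments:
        if not (1 <= a <= b <= pt.n):
            return False, None
        if any(pt.partner[p - 1] != -1 for p in range(a, b + 1)):
            return False, None
    if spec.fragment is not None and not _fragment_occurs(pt, spec.fragment):
        return False, None
    candidates = sorted(decompose(pt).multiloops, key=lambda l: l.closing)
    for ml in candidates:
        if ml.n_helices < spec.min_helices:
            continue
        if spec.near is not None:
            pos, win = spec.near
            if abs(ml.closing[0] - pos) > win:
                continue
        return True, MotifMatch(ml.closing, ml.branches, ml.unpaired)
    return False, None
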