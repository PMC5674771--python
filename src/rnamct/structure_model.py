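"""Secondary-structure representations: dot-bracket parsing, canonical
rendering, and structural distance.

A target structure is a string over ``.``, ``()`` and, for pseudoknots, the
extra bracket layers ``[]``, ``{}`` and ``<>``.  Matched brackets denote base
pairs; dots denote unpaired (free) bases.  All positions in the public API are
1-based, matching the ``{AU_3,11}`` event notation used throughout the
package's logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Sequence, Tuple

__all__ = [
    "BRACKET_LAYERS",
    "StructureError",
    "TargetStructure",
    "parse_dotbracket",
    "canonical_dotbracket",
    "structure_distance",
    "dotbracket_pairs",
    "pairs_cross",
]

#: Bracket alphabets in the fixed order used for canonical rendering.  Four
#: layers cover every PseudoBase-class pseudoknot; deeper crossing patterns
#: are rejected.
BRACKET_LAYERS: Tuple[Tuple[str, str], ...] = (("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"))

_OPEN = {o: layer for layer, (o, _) in enumerate(BRACKET_LAYERS)}
_CLOSE = {c: layer for layer, (_, c) in enumerate(BRACKET_LAYERS)}


class StructureError(ValueError):
    """Raised for malformed dot-bracket input or unrenderable pair sets."""


def pairs_cross(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    """True if base pairs ``a`` and ``b`` cross (pseudoknot relation)."""
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


@dataclass(frozen=True)
class TargetStructure:
    """A parsed target secondary structure.

    Attributes
    ----------
    dotbracket : str
        Canonical dot-bracket rendering of the pair set.
    n : int
        Sequence length N.
    pairs : frozenset of (int, int)
        Base pairs (i, j) with 1 <= i < j <= N.
    single_sites : tuple of int
        Unpaired positions in ascending order.
    paired_sites : tuple of (int, int)
        Pairs sorted by opening position.
    """

    dotbracket: str
    n: int
    pairs: FrozenSet[Tuple[int, int]]
    single_sites: Tuple[int, ...]
    paired_sites: Tuple[Tuple[int, int], ...]

    @property
    def ell(self) -> int:
        """Number of design sites: base pairs plus free bases.

        This is the maximum depth of the assignment-event search tree.
        """
        return len(self.pairs) + len(self.single_sites)

    @property
    def sites(self) -> Tuple[object, ...]:
        """All design sites: single positions (int) then pairs (tuple)."""
        return tuple(self.single_sites) + tuple(self.paired_sites)

    @property
    def is_pseudoknotted(self) -> bool:
        ordered = self.paired_sites
        return any(
            pairs_cross(ordered[a], ordered[b])
            for a in range(len(ordered))
            for b in range(a + 1, len(ordered))
        )

    def partner(self, i: int) -> int | None:
        """Pairing partner of 1-based position ``i``, or None if unpaired."""
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None


def parse_dotbracket(text: str) -> TargetStructure:
    """Parse a dot-bracket string into a :class:`TargetStructure`.

    Each bracket alphabet is matched independently with its own stack, so
    crossing pairs (pseudoknots) expressed with ``[]``/``{}``/``<>`` layers
    are handled.  Positions are 1-based.

    Raises
    ------
    StructureError
        On illegal characters or unbalanced brackets (the message names the
        offending layer and position).
    """
    text = text.strip()
    if not text:
        raise StructureError("empty structure string")
    stacks: list[list[int]] = [[] for _ in BRACKET_LAYERS]
    pairs: set[Tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            if not stacks[layer]:
                o, c = BRACKET_LAYERS[layer]
                raise StructureError(
                    f"unbalanced '{c}' in layer {o}{c} at position {pos}"
                )
            pairs.add((stacks[layer].pop(), pos))
        else:
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    for layer, stack in enumerate(stacks):
        if stack:
            o, c = BRACKET_LAYERS[layer]
            raise StructureError(
                f"unbalanced '{o}' in layer {o}{c} at position {stack[-1]}"
            )
    n = len(text)
    paired_positions = {p for pair in pairs for p in pair}
    singles = tuple(i for i in range(1, n + 1) if i not in paired_positions)
    ordered_pairs = tuple(sorted(pairs))
    return TargetStructure(
        dotbracket=canonical_dotbracket(pairs, n),
        n=n,
        pairs=frozenset(pairs),
        single_sites=singles,
        paired_sites=ordered_pairs,
    )


def canonical_dotbracket(pairs: Sequence[Tuple[int, int]] | FrozenSet[Tuple[int, int]], n: int) -> str:
    """Render a pair set as a canonical dot-bracket string.

    Nested pairs use ``()``; crossing pairs are pushed to the first bracket
    layer in which they do not cross any pair already assigned there, layers
    tried in the fixed order ``()``, ``[]``, ``{}``, ``<>``.  The output is
    deterministic, independent of which layers a folding engine originally
    used, so structures from different engines compare consistently.

    Raises
    ------
    StructureError
        If pairs overlap, lie outside 1..n, or need more than four layers.
    """
    seen: set[int] = set()
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise StructureError(f"pair ({i}, {j}) outside 1..{n} or not i < j")
        if i in seen or j in seen:
            raise StructureError(f"position reused by pair ({i}, {j})")
        seen.update((i, j))
    chars = ["."] * n
    layers: list[list[Tuple[int, int]]] = [[] for _ in BRACKET_LAYERS]
    # sort by (i, -j) so an enclosing pair is placed before the pairs it
    # contains, keeping layer assignment stable
    for pair in sorted(pairs, key=lambda p: (p[0], -p[1])):
        for layer, assigned in enumerate(layers):
            if not any(pairs_cross(pair, other) for other in assigned):
                assigned.append(pair)
                o, c = BRACKET_LAYERS[layer]
                chars[pair[0] - 1] = o
                chars[pair[1] - 1] = c
                break
        else:
            raise StructureError(
                f"pair {pair} requires more than {len(BRACKET_LAYERS)} "
                "bracket layers; crossing depth not supported"
            )
    return "".join(chars)


def dotbracket_pairs(text: str) -> FrozenSet[Tuple[int, int]]:
    """Base-pair set of a dot-bracket string (1-based), without the full
    :class:`TargetStructure` bookkeeping.  Raises on malformed input."""
    stacks: list[list[int]] = [[] for _ in BRACKET_LAYERS]
    pairs: set[Tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            if not stacks[layer]:
                raise StructureError(f"unbalanced bracket at position {pos}")
            pairs.add((stacks[layer].pop(), pos))
        else:
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    if any(stacks):
        raise StructureError("unbalanced brackets")
    return frozenset(pairs)


_NESTED_CHARS = frozenset(".()")


def structure_distance(a: str, b: str) -> int:
    """Hamming distance between two structures of equal length.

    Both strings are canonicalized (parsed and re-rendered) before the
    position-wise comparison, so two engines that place the same crossing
    pairs in different bracket layers are at distance zero.  Strings using
    only ``.()`` are nested and already canonical, so they skip the
    round trip.
    """
    if len(a) != len(b):
        raise StructureError(
            f"structure length mismatch: {len(a)} vs {len(b)}"
        )
    ca = a if set(a) <= _NESTED_CHARS else parse_dotbracket(a).dotbracket
    cb = b if set(b) <= _NESTED_CHARS else parse_dotbracket(b).dotbracket
    return sum(1 for x, y in zip(ca, cb) if x != y)
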