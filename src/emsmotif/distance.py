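"""Edit distance and one-edit growth.

``edit_distance`` is the unit-cost Levenshtein distance (substitution,
insertion, deletion all cost 1), computed with edlib's banded bit-parallel
aligner. ``grow_one_edit`` enumerates the strings reachable by exactly one
edit operation; it is the primitive behind the brute-force oracle and is
never used by the production engines.
"""

from __future__ import annotations

import edlib

from .alphabet import DNA, Alphabet
from .errors import InvalidInputError


def edit_distance(x: str, y: str, alphabet: Alphabet = DNA) -> int:
    """Unit-cost Levenshtein distance between ``x`` and ``y``.

    Both strings must be over the alphabet's symbols; out-of-alphabet
    characters raise :class:`InvalidInputError`.
    """
    alphabet.validate(x)
    alphabet.validate(y)
    if not x or not y:
        return max(len(x), len(y))
    return edlib.align(x, y, mode="NW", task="distance")["editDistance"]


def min_distance_to_substring(x: str, s: str) -> int:
    """min over substrings w of ``s`` of edit_distance(x, w) (infix alignment)."""
    if not x:
        return 0
    return edlib.align(x, s, mode="HW", task="distance")["editDistance"]


def within_substring_distance(x: str, s: str, d: int) -> bool:
    """True iff some substring of ``s`` is within edit distance ``d`` of ``x``."""
    if not x:
        return True
    return edlib.align(x, s, mode="HW", task="distance", k=d)["editDistance"] != -1


def grow_one_edit(L: str, alphabet: Alphabet = DNA) -> set[str]:
    """All strings reachable from ``L`` by exactly one edit operation.

    Substitutions replace a character by a *different* symbol; insertions
    may place any symbol at any of the ``len(L)+1`` positions; deletions
    remove one character. ``L`` itself is never in the result.
    """
    alphabet.validate(L)
    out: set[str] = set()
    for i in range(len(L)):
        out.add(L[:i] + L[i + 1 :])  # deletion
        for sym in alphabet.symbols:
            if sym != L[i]:
                out.add(L[:i] + sym + L[i + 1 :])  # substitution
    for i in range(len(L) + 1):
        for sym in alphabet.symbols:
            out.add(L[:i] + sym + L[i:])  # insertion
    return out


def exact_friends(L: str, l: int, d: int, alphabet: Alphabet = DNA) -> set[str]:
    """(l,d)-friends of ``L``: l-mers at edit distance exactly d, via growth.

    Grows the edit ball one operation at a time, d times, then filters to
    length l. Oracle-only; exponential in d.
    """
    if d == 0:
        return {L} if len(L) == l else set()
    frontier = {L}
    for _ in range(d):
        nxt: set[str] = set()
        for s in frontier:
            nxt |= grow_one_edit(s, alphabet)
        frontier = nxt
    return {x for x in frontier if len(x) == l}


def neighbors_by_growth(L: str, l: int, d: int, alphabet: Alphabet = DNA) -> set[str]:
    """(l,d)-neighborhood of ``L``: union of (l,t)-friend sets for t = 0..d."""
    if d < 0:
        raise InvalidInputError("d must be non-negative")
    out: set[str] = {L} if len(L) == l else set()
    frontier = {L}
    for _ in range(d):
        nxt: set[str] = set()
        for s in frontier:
            nxt |= grow_one_edit(s, alphabet)
        frontier = nxt
        out |= {x for x in frontier if x.__len__() == l}
    return out
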