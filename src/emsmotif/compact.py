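"""Compact motif algebra.

A compact motif is a length-l string over Sigma plus the wildcard ``*``,
where ``*`` stands for every symbol of Sigma at that position. A single
compact motif therefore represents ``|Sigma|**(#wildcards)`` concrete
l-mers. Intersection is position-wise: two distinct concrete symbols at the
same position annihilate the motif, a concrete symbol absorbs a wildcard,
and two wildcards stay wild. Expansion of the intersection equals the
intersection of the expansions, which is what both set engines rely on.
"""

from __future__ import annotations

from itertools import product

from .alphabet import DNA, Alphabet
from .errors import InvalidInputError


def validate_compact(a: str, alphabet: Alphabet = DNA) -> str:
    """Check that ``a`` is over Sigma plus the wildcard (no sentinel)."""
    for c in a:
        if c != alphabet.wildcard and c not in alphabet:
            raise InvalidInputError(f"character {c!r} not valid in a compact motif")
    return a


def expand_compact(a: str, alphabet: Alphabet = DNA) -> set[str]:
    """All concrete l-mers represented by compact motif ``a``."""
    validate_compact(a, alphabet)
    choices = [
        alphabet.symbols if c == alphabet.wildcard else (c,) for c in a
    ]
    return {"".join(p) for p in product(*choices)}


def compact_intersect(a: str, b: str, alphabet: Alphabet = DNA) -> str | None:
    """Position-wise intersection of two compact motifs; None if empty."""
    if len(a) != len(b):
        raise InvalidInputError("compact motifs must have equal length")
    validate_compact(a, alphabet)
    validate_compact(b, alphabet)
    w = alphabet.wildcard
    out = []
    for ca, cb in zip(a, b):
        if ca == w:
            out.append(cb)
        elif cb == w or cb == ca:
            out.append(ca)
        else:
            return None
    return "".join(out)


def expansion_size(a: str, alphabet: Alphabet = DNA) -> int:
    """Number of concrete l-mers represented by ``a``."""
    return len(alphabet) ** a.count(alphabet.wildcard)
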