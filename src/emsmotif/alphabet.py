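"""Alphabets for motif search.

An :class:`Alphabet` fixes the ordered symbol set Sigma, which induces the
lexicographic order on l-mers, and reserves two characters that never occur
in input sequences: the wildcard ``*`` (stands for every symbol of Sigma at
a position of a compact motif) and the deletion sentinel ``-`` (marks a
deleted character during neighborhood generation so that rule predicates
over original string positions stay evaluable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError

WILDCARD = "*"
DELETION_SENTINEL = "-"


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with reserved wildcard / sentinel characters."""

    symbols: tuple[str, ...]
    wildcard: str = WILDCARD
    deletion_sentinel: str = DELETION_SENTINEL
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidInputError("alphabet symbols must be distinct")
        if any(len(s) != 1 for s in self.symbols):
            raise InvalidInputError("alphabet symbols must be single characters")
        if self.wildcard in self.symbols or self.deletion_sentinel in self.symbols:
            raise InvalidInputError("reserved characters must not be alphabet symbols")
        if self.wildcard == self.deletion_sentinel:
            raise InvalidInputError("wildcard and deletion sentinel must differ")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        """Rank of ``symbol`` in the alphabet order."""
        try:
            return self._index[symbol]
        except KeyError:
            raise InvalidInputError(f"character {symbol!r} not in alphabet") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def validate(self, s: str) -> str:
        """Return ``s`` unchanged, or raise if it has out-of-alphabet characters."""
        for c in s:
            if c not in self._index:
                raise InvalidInputError(f"character {c!r} not in alphabet")
        return s

    def full_mask(self) -> int:
        """Bitmask with one bit set per symbol (bit i = symbol of rank i)."""
        return (1 << len(self.symbols)) - 1

    def bit(self, symbol: str) -> int:
        return 1 << self.index(symbol)


DNA = Alphabet(("A", "C", "G", "T"))
PROTEIN = Alphabet(tuple("ACDEFGHIKLMNPQRSTVWY"))

_NAMED = {"dna": DNA, "protein": PROTEIN}


def get_alphabet(name: str) -> Alphabet:
    """Look up a named alphabet (``dna`` or ``protein``)."""
    try:
        return _NAMED[name.lower()]
    except KeyError:
        raise InvalidInputError(f"unknown alphabet {name!r}") from None
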