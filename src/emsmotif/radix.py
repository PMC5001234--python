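"""Array engine: wildcard-expanding radix sort and sorted-set algebra.

Motifs are packed into fixed-width integer codes, one digit of
``ceil(log2 |Sigma|)`` bits per position with position 1 most significant,
so that integer order equals lexicographic order. Wildcard positions carry
zeroed code bits plus a bit in a separate star mask.

``compact_radix_sort`` runs one stable counting-sort phase per position,
least-significant (position l) first. When the phase's position holds a
wildcard, the bucket counter of every symbol is incremented and the motif
is emitted |Sigma| times, once per symbol, with the wildcard finalized; a
motif with w wildcards therefore ends up as |Sigma|**w sorted concrete
copies. Duplicate removal and intersection are then linear scans over
sorted arrays, which is what makes the per-string candidate sets cheap to
combine across input strings and across parallel workers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import DNA, Alphabet
from .errors import ContractViolationError, InvalidInputError, InvalidParameterError


def _bits_per_symbol(alphabet: Alphabet) -> int:
    return max(1, (len(alphabet) - 1).bit_length())


@dataclass
class MotifArray:
    """Flat collection of (possibly compact) motifs in packed-integer form."""

    codes: np.ndarray  # uint64 packed digits, position 1 most significant
    star_masks: np.ndarray  # uint64, bit (l - p) set iff position p is a wildcard
    l: int
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        bits = _bits_per_symbol(self.alphabet)
        if self.l * bits > 63:
            raise InvalidParameterError(
                f"l={self.l} over a {len(self.alphabet)}-symbol alphabet "
                "does not fit a 64-bit code"
            )

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def expanded(self) -> bool:
        return bool(len(self.codes) == 0 or not self.star_masks.any())

    @property
    def is_sorted(self) -> bool:
        return bool(np.all(self.codes[1:] >= self.codes[:-1]))

    @classmethod
    def from_motifs(
        cls, motifs, l: int, alphabet: Alphabet = DNA
    ) -> "MotifArray":
        """Pack an iterable of compact motif strings."""
        bits = _bits_per_symbol(alphabet)
        wild = alphabet.wildcard
        index = {s: i for i, s in enumerate(alphabet.symbols)}
        codes, masks = [], []
        for motif in motifs:
            if len(motif) != l:
                raise InvalidInputError(f"motif {motif!r} is not of length {l}")
            code = 0
            mask = 0
            for c in motif:
                code <<= bits
                mask <<= 1
                if c == wild:
                    mask |= 1
                else:
                    code |= index[c]
            codes.append(code)
            masks.append(mask)
        return cls(
            np.asarray(codes, dtype=np.uint64),
            np.asarray(masks, dtype=np.uint64),
            l,
            alphabet,
        )

    def decode(self) -> list[str]:
        """Unpack to motif strings (wildcards restored from the star mask)."""
        bits = _bits_per_symbol(self.alphabet)
        symbols = self.alphabet.symbols
        wild = self.alphabet.wildcard
        out = []
        digit_mask = (1 << bits) - 1
        for code, mask in zip(self.codes.tolist(), self.star_masks.tolist()):
            chars = []
            for p in range(1, self.l + 1):
                if (mask >> (self.l - p)) & 1:
                    chars.append(wild)
                else:
                    chars.append(symbols[(code >> (bits * (self.l - p))) & digit_mask])
            out.append("".join(chars))
        return out


@dataclass
class BucketCounters:
    """Per-symbol bucket counts B and their exclusive prefix sums C."""

    B: np.ndarray
    C: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.C = np.concatenate(([0], np.cumsum(self.B)[:-1]))

    @classmethod
    def from_digits(cls, digits: np.ndarray, nsym: int) -> "BucketCounters":
        return cls(np.bincount(digits, minlength=nsym))

    @property
    def total(self) -> int:
        return int(self.C[-1] + self.B[-1])


def _stable_ranks(digits: np.ndarray, nsym: int) -> np.ndarray:
    """Rank of each item among equal digits, in scan order (stable)."""
    ranks = np.empty(len(digits), dtype=np.int64)
    for s in range(nsym):
        sel = digits == s
        ranks[sel] = np.arange(int(sel.sum()))
    return ranks


def compact_radix_sort(a: MotifArray) -> MotifArray:
    """Expand all wildcards and sort lexicographically, in l counting phases."""
    nsym = len(a.alphabet)
    bits = _bits_per_symbol(a.alphabet)
    l = a.l
    codes = a.codes.copy()
    masks = a.star_masks.copy()
    for p in range(l, 0, -1):  # LSD: position l first makes the pass stable-lex
        shift = np.uint64(bits * (l - p))
        star_bit = np.uint64(l - p)
        is_star = ((masks >> star_bit) & np.uint64(1)).astype(bool)
        if is_star.any():
            reps = np.where(is_star, nsym, 1)
            idx = np.repeat(np.arange(len(codes)), reps)
            block_start = np.repeat(np.cumsum(reps) - reps, reps)
            offset = (np.arange(len(idx)) - block_start).astype(np.uint64)
            codes = codes[idx]
            masks = masks[idx]
            star_rows = is_star[idx]
            # finalize the wildcard: write the symbol, clear the star bit
            codes = np.where(star_rows, codes | (offset << shift), codes)
            masks = np.where(star_rows, masks & ~(np.uint64(1) << star_bit), masks)
        digits = ((codes >> shift) & np.uint64((1 << bits) - 1)).astype(np.int64)
        counters = BucketCounters.from_digits(digits, nsym)
        dest = counters.C[digits] + _stable_ranks(digits, nsym)
        out_codes = np.empty_like(codes)
        out_masks = np.empty_like(masks)
        out_codes[dest] = codes
        out_masks[dest] = masks
        codes, masks = out_codes, out_masks
        assert counters.total == len(codes)
    return MotifArray(codes, masks, l, a.alphabet)


def _require_sorted_expanded(a: MotifArray, what: str) -> None:
    if not a.expanded:
        raise ContractViolationError(f"{what}: array still contains wildcards")
    if not a.is_sorted:
        raise ContractViolationError(f"{what}: array is not sorted")


def dedupe_sorted(a: MotifArray) -> MotifArray:
    """Strictly increasing copy of a sorted, expanded array."""
    _require_sorted_expanded(a, "dedupe_sorted")
    if len(a) == 0:
        return a
    keep = np.concatenate(([True], a.codes[1:] != a.codes[:-1]))
    return MotifArray(a.codes[keep], a.star_masks[keep], a.l, a.alphabet)


def intersect_sorted(a: MotifArray, b: MotifArray) -> MotifArray:
    """Sorted duplicate-free intersection of two sorted duplicate-free arrays."""
    for x in (a, b):
        _require_sorted_expanded(x, "intersect_sorted")
        if len(x.codes) and np.any(x.codes[1:] == x.codes[:-1]):
            raise ContractViolationError("intersect_sorted: duplicates present")
    codes = np.intersect1d(a.codes, b.codes, assume_unique=True)
    return MotifArray(codes, np.zeros(len(codes), dtype=np.uint64), a.l, a.alphabet)


def union_sorted(a: MotifArray, b: MotifArray) -> MotifArray:
    """Sorted duplicate-free union of two sorted duplicate-free arrays."""
    _require_sorted_expanded(a, "union_sorted")
    _require_sorted_expanded(b, "union_sorted")
    codes = np.union1d(a.codes, b.codes)
    return MotifArray(codes, np.zeros(len(codes), dtype=np.uint64), a.l, a.alphabet)


def empty_array(l: int, alphabet: Alphabet = DNA) -> MotifArray:
    return MotifArray(
        np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint64), l, alphabet
    )
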