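"""Motif trie: a set of l-mers with subset-labelled edges.

A non-empty trie has l+1 levels; edges out of a node carry mutually
exclusive non-empty subsets of Sigma (stored as bitmasks in alphabet
order). The trie represents every l-mer obtainable by walking root to leaf
and picking one symbol from each edge label, so a single path whose labels
have sizes s1..sl stands for s1*...*sl concrete l-mers. Compact motifs
insert naturally: a wildcard descends into every child, a concrete symbol
splits the child whose label contains it (copy-on-split), and symbols not
covered by any existing child get a fresh branch.

Intersection pairs up children by label intersection and prunes branches
that lose all leaves, so ``expansion(t1 & t2) == expansion(t1) &
expansion(t2)`` and emptiness is visible at the root.
"""

from __future__ import annotations

from typing import Iterator

from .alphabet import DNA, Alphabet
from .errors import InvalidInputError


class _Node:
    __slots__ = ("children",)

    def __init__(self) -> None:
        # list of (label bitmask, child _Node); labels pairwise disjoint
        self.children: list[tuple[int, _Node]] = []

    def copy(self) -> "_Node":
        n = _Node()
        n.children = [(mask, child.copy()) for mask, child in self.children]
        return n


class MotifTrie:
    """Set of l-mers stored as a trie with subset-labelled edges."""

    def __init__(self, l: int, alphabet: Alphabet = DNA) -> None:
        if l < 1:
            raise InvalidInputError("motif length must be positive")
        self.l = l
        self.alphabet = alphabet
        self.root = _Node()

    # -- insertion ---------------------------------------------------------

    def insert(self, motif: str) -> "MotifTrie":
        """Add the expansion of a compact motif to the set. Returns self."""
        if len(motif) != self.l:
            raise InvalidInputError(
                f"motif length {len(motif)} != trie length {self.l}"
            )
        ab = self.alphabet
        wild = ab.wildcard
        masks = []
        for c in motif:
            if c == wild:
                masks.append(ab.full_mask())
            else:
                masks.append(ab.bit(c))  # raises on out-of-alphabet chars
        self._insert(self.root, masks, 0)
        return self

    def _insert(self, node: _Node, masks: list[int], depth: int) -> None:
        if depth == self.l:
            return
        t = masks[depth]
        covered = 0
        # bound by the original child count: splits append new children
        for idx in range(len(node.children)):
            mask, child = node.children[idx]
            inter = mask & t
            if not inter:
                continue
            covered |= inter
            if inter == mask:
                # whole label affected: descend in place
                self._insert(child, masks, depth + 1)
            else:
                # copy-on-split: peel the affected symbols into a new child
                split = child.copy()
                node.children[idx] = (mask & ~inter, child)
                node.children.append((inter, split))
                self._insert(split, masks, depth + 1)
        residual = t & ~covered
        if residual:
            fresh = _Node()
            node.children.append((residual, fresh))
            cur = fresh
            for level in range(depth + 1, self.l):
                nxt = _Node()
                cur.children.append((masks[level], nxt))
                cur = nxt

    # -- intersection ------------------------------------------------------

    def intersect(self, other: "MotifTrie") -> "MotifTrie":
        """New trie whose expansion is the intersection of the two expansions."""
        if self.l != other.l or self.alphabet is not other.alphabet and (
            self.alphabet.symbols != other.alphabet.symbols
        ):
            raise InvalidInputError("tries must share length and alphabet")
        out = MotifTrie(self.l, self.alphabet)
        out.root = self._intersect(self.root, other.root, 0)
        return out

    def _intersect(self, n1: _Node, n2: _Node, depth: int) -> _Node:
        out = _Node()
        last = depth + 1 == self.l
        for m1, c1 in n1.children:
            for m2, c2 in n2.children:
                m = m1 & m2
                if not m:
                    continue
                if last:
                    out.children.append((m, _Node()))
                else:
                    w = self._intersect(c1, c2, depth + 1)
                    if w.children:  # prune branches with no surviving leaf
                        out.children.append((m, w))
        return out

    def __and__(self, other: "MotifTrie") -> "MotifTrie":
        return self.intersect(other)

    # -- queries -----------------------------------------------------------

    def is_empty(self) -> bool:
        return not self.root.children

    def expansion_size(self) -> int:
        """Number of distinct l-mers in the set, without enumerating them."""

        def count(node: _Node, depth: int) -> int:
            if depth == self.l:
                return 1
            return sum(
                mask.bit_count() * count(child, depth + 1)
                for mask, child in node.children
            )

        return count(self.root, 0)

    def enumerate(self) -> list[str]:
        """All l-mers in the set, sorted in alphabet order, duplicate-free."""
        return list(self)

    def __iter__(self) -> Iterator[str]:
        symbols = self.alphabet.symbols
        buf: list[str] = []

        def walk(node: _Node, depth: int) -> Iterator[str]:
            if depth == self.l:
                yield "".join(buf)
                return
            for i, sym in enumerate(symbols):  # alphabet order => sorted output
                bit = 1 << i
                for mask, child in node.children:
                    if mask & bit:
                        buf.append(sym)
                        yield from walk(child, depth + 1)
                        buf.pop()
                        break  # labels are disjoint: at most one child matches

        return walk(self.root, 0)

    def __contains__(self, lmer: str) -> bool:
        node = self.root
        for c in lmer:
            bit = self.alphabet.bit(c)
            for mask, child in node.children:
                if mask & bit:
                    node = child
                    break
            else:
                return False
        return True

    def check_invariants(self) -> None:
        """Structural audit: disjoint labels, uniform depth. Raises on violation."""

        def walk(node: _Node, depth: int) -> None:
            seen = 0
            for mask, child in node.children:
                if mask == 0:
                    raise InvalidInputError("empty edge label")
                if mask & seen:
                    raise InvalidInputError("overlapping edge labels")
                seen |= mask
                if depth + 1 > self.l:
                    raise InvalidInputError("path longer than l")
                walk(child, depth + 1)
            if not node.children and depth not in (0, self.l):
                raise InvalidInputError(f"leaf at interior depth {depth}")

        walk(self.root, 0)


def trie_from_string(
    S: str, l: int, d: int, alphabet: Alphabet = DNA, rules_enabled: bool = True
) -> MotifTrie:
    """Motif trie of all (l,d)-motifs of S, built from the compact friendhoods."""
    from .neighborhood import gen_all

    trie = MotifTrie(l, alphabet)
    for nb in gen_all(S, l, d, rules_enabled=rules_enabled, alphabet=alphabet):
        trie.insert(nb.motif)
    return trie
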