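"""Exact-distance compact neighborhood generation.

The engines never enumerate the full (l,<=d) edit neighborhood of every
substring. It suffices to generate, for every k-mer (k in [l-d, l+d]) of an
input string, the l-mers at edit distance *exactly* d: a neighbor at a
smaller distance is always an exact-d friend of some other (shorter or
longer) substring, so the union over all k-mers is unchanged.

Generation runs in three phases on a k-mer: delta deletions first, then
beta substitutions, then alpha insertions, with

    delta + beta + alpha = d   and   k - delta + alpha = l.

Writing q = k - l, the admissible triples are max(0, q) <= delta <=
(d + q) // 2 with alpha = delta - q and beta = d - 2*delta + q.

Substitutions and insertions write the wildcard ``*`` (one compact motif
stands for all |Sigma| choices); deletions overwrite with the sentinel
``-`` which is kept in the working string until emission so that skip-rule
predicates can still be evaluated over original string positions, and is
stripped from the emitted motif.

Every candidate carries a trace: the multiset of edit operations (p, o)
with p a 1-based position in the *parent string* S and o one of D < R < I
(deletion, substitution, insertion). A position can host one D or one R but
one or more I; an insertion "just before position p" records p, and an
insertion at the right end of the k-mer records p = j + k. Nine skip rules,
each a predicate over (j, k, m, trace), prune candidates whose compact
motif is guaranteed to be generated from another (k-mer, trace) pair; on a
string whose characters are all distinct the surviving multiset is exactly
duplication-free, and in every case the union of expansions is preserved.
All positions in this module are 1-based to match the trace convention;
``gen_friends`` converts to Python slices internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

from .alphabet import DNA, Alphabet
from .errors import InvalidParameterError

#: generation-order rank of operation kinds: D < R < I
OP_ORDER = {"D": 0, "R": 1, "I": 2}


class EditOp(NamedTuple):
    """One edit operation: 1-based position in S and kind (D, R or I)."""

    p: int
    o: str

    def sort_key(self) -> tuple[int, int]:
        return (self.p, OP_ORDER[self.o])


class OpTrace(NamedTuple):
    """Completed operation trace, sorted by (position, D < R < I)."""

    ops: tuple[EditOp, ...]

    @property
    def deletions(self) -> int:
        return sum(1 for op in self.ops if op.o == "D")

    @property
    def substitutions(self) -> int:
        return sum(1 for op in self.ops if op.o == "R")

    @property
    def insertions(self) -> int:
        return sum(1 for op in self.ops if op.o == "I")


class TaggedNeighbor(NamedTuple):
    """A compact motif together with its provenance (j, k, trace)."""

    j: int
    k: int
    trace: OpTrace
    motif: str


@dataclass(frozen=True)
class PhasePlan:
    """Admissible (delta, beta, alpha) phase triples for one k-mer length."""

    k: int
    l: int
    d: int
    triples: tuple[tuple[int, int, int], ...]

    @property
    def q(self) -> int:
        return self.k - self.l

    def __iter__(self):
        return iter(self.triples)


def phase_plan(k: int, l: int, d: int) -> PhasePlan:
    """All (deletions, substitutions, insertions) triples for a k-mer.

    Raises :class:`InvalidParameterError` if k is outside [l-d, l+d].
    """
    if not l - d <= k <= l + d:
        raise InvalidParameterError(f"k={k} outside [l-d, l+d] = [{l-d}, {l+d}]")
    q = k - l
    triples = []
    for delta in range(max(0, q), (d + q) // 2 + 1):
        alpha = delta - q
        beta = d - 2 * delta + q
        assert alpha >= 0 and beta >= 0 and delta + alpha + beta == d
        assert k - delta + alpha == l
        triples.append((delta, beta, alpha))
    return PhasePlan(k, l, d, tuple(triples))


def skip_rule(j: int, k: int, m: int, trace) -> int | None:
    """Lowest-numbered skip rule matching the (partial) trace, or None.

    ``trace`` is any container of (p, o) pairs supporting membership tests.
    Every rule condition is monotone in the trace (a conjunction of
    membership requirements plus static predicates on j, k, m), so a rule
    that matches a partial trace matches all of its completions; the
    generator may therefore prune as soon as a rule fires.
    """
    right_open = j + k <= m  # the k-mer is not the rightmost one
    # 1: leftmost base deleted, k-mer not rightmost
    if right_open and (j, "D") in trace:
        return 1
    # 2: substitution immediately after a deletion
    for p, o in trace:
        if o == "D" and (p + 1, "R") in trace:
            return 2
    # run of substitutions covering j, j+1, ..., j+r-1 (used by rules 3, 8)
    r = 0
    while (j + r, "R") in trace:
        r += 1
    # 3: deletion right after a substitution run anchored at j, not rightmost
    if right_open and r and (j + r, "D") in trace:
        return 3
    # 4: insertion at a deleted position
    for p, o in trace:
        if o == "I" and (p, "D") in trace:
            return 4
    # 5: insertion immediately after a deletion
    for p, o in trace:
        if o == "I" and (p - 1, "D") in trace:
            return 5
    # 6: insertion at a substituted position
    for p, o in trace:
        if o == "I" and (p, "R") in trace:
            return 6
    # 7: insertion at the leftmost position of a non-leftmost k-mer
    if j > 1 and (j, "I") in trace:
        return 7
    # 8: insertion right after a substitution run anchored at j, non-leftmost k-mer
    if j > 1:
        for s in range(1, r + 1):
            if (j + s, "I") in trace:
                return 8
    # 9: insertion at the right end of a non-rightmost k-mer
    if right_open and (j + k, "I") in trace:
        return 9
    return None


def gen_friends(
    S: str,
    j: int,
    k: int,
    l: int,
    d: int,
    rules_enabled: bool = True,
    alphabet: Alphabet = DNA,
) -> Iterator[TaggedNeighbor]:
    """Tagged exact-d compact friends of the k-mer of S starting at j (1-based).

    With ``rules_enabled`` the skip rules prune duplicated candidates; with
    rules disabled the full three-phase enumeration is produced. Either way
    every emitted trace has exactly d operations and every motif has length
    exactly l.
    """
    m = len(S)
    phase_plan(k, l, d)  # validates k against [l-d, l+d]
    if not 1 <= j <= m - k + 1:
        raise InvalidParameterError(f"k-mer (j={j}, k={k}) not within |S|={m}")

    sent = alphabet.deletion_sentinel
    wild = alphabet.wildcard
    W = list(S[j - 1 : j - 1 + k])  # W[p - j] is the character at position p
    ins = [0] * (k + 1)  # ins[p - j]: insertions just before position p
    trace: list[tuple[int, str]] = []
    end = j + k

    def pruned() -> bool:
        return rules_enabled and skip_rule(j, k, m, trace) is not None

    def emit() -> TaggedNeighbor:
        parts = []
        for p in range(j, end):
            i = p - j
            if ins[i]:
                parts.append(wild * ins[i])
            c = W[i]
            if c != sent:
                parts.append(c)
        if ins[k]:
            parts.append(wild * ins[k])
        motif = "".join(parts)
        assert len(motif) == l
        ops = tuple(EditOp(p, o) for p, o in sorted(trace, key=lambda t: (t[0], OP_ORDER[t[1]])))
        return TaggedNeighbor(j, k, OpTrace(ops), motif)

    def do_insert(next_p: int, alpha: int) -> Iterator[TaggedNeighbor]:
        if alpha == 0:
            yield emit()
            return
        for p in range(next_p, end + 1):  # insertion points, non-decreasing
            ins[p - j] += 1
            trace.append((p, "I"))
            if not pruned():
                yield from do_insert(p, alpha - 1)
            trace.pop()
            ins[p - j] -= 1

    def do_subst(next_p: int, beta: int, alpha: int) -> Iterator[TaggedNeighbor]:
        if beta == 0:
            yield from do_insert(j, alpha)
            return
        for p in range(next_p, end):
            i = p - j
            if W[i] == sent:
                continue
            orig = W[i]
            W[i] = wild
            trace.append((p, "R"))
            if not pruned():
                yield from do_subst(p + 1, beta - 1, alpha)
            trace.pop()
            W[i] = orig

    def do_delete(next_p: int, delta: int, beta: int, alpha: int) -> Iterator[TaggedNeighbor]:
        if delta == 0:
            yield from do_subst(j, beta, alpha)
            return
        for p in range(next_p, end - delta + 1):  # room for remaining deletions
            i = p - j
            orig = W[i]
            W[i] = sent
            trace.append((p, "D"))
            if not pruned():
                yield from do_delete(p + 1, delta - 1, beta, alpha)
            trace.pop()
            W[i] = orig

    for delta, beta, alpha in phase_plan(k, l, d):
        yield from do_delete(j, delta, beta, alpha)


def gen_all(
    S: str,
    l: int,
    d: int,
    rules_enabled: bool = True,
    alphabet: Alphabet = DNA,
) -> Iterator[TaggedNeighbor]:
    """Stream tagged exact-d compact friends over all k-mers of S.

    k ranges over [l-d, min(l+d, |S|)] and j over [1, |S|-k+1]. The union
    of the expansions of the emitted motifs is the full (l,d)-motif set of
    S; with rules enabled the multiset is additionally (nearly) free of
    repeated compact motifs.
    """
    if d < 0:
        raise InvalidParameterError("d must be non-negative")
    if l <= d:
        raise InvalidParameterError("l must exceed d")
    m = len(S)
    if m < l - d:
        raise InvalidParameterError("string shorter than l - d admits no motifs")
    alphabet.validate(S)
    for k in range(max(1, l - d), min(l + d, m) + 1):
        for j in range(1, m - k + 2):
            yield from gen_friends(S, j, k, l, d, rules_enabled, alphabet)
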