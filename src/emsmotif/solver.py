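"""End-to-end exact (l,d) motif solving.

Both engines compute, per input string, the set of l-mers within edit
distance d of some substring (via exact-distance compact friendhood
generation) and intersect these sets across strings in input order,
starting the accumulator from the first string and exiting early once it
empties. The trie engine stores candidates as a motif trie and intersects
tries; the array engine radix-sorts packed candidates and merge-scans
sorted arrays. Their outputs are identical sorted motif lists.

The array engine also implements the parallel contract: the per-string
(2d+1)(m-l+1) k-mer generation workloads are shuffled with a seed derived
from the instance seed, split evenly across workers, processed in
isolation (generate, sort, dedupe, filter against the accumulated common
set), and merged pairwise in a binary tree. Output is independent of the
worker count; worker tasks may run serially or in separate OS processes.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .alphabet import DNA, Alphabet
from .errors import CandidateLimitError, InvalidInputError, InvalidParameterError
from .neighborhood import gen_friends
from .radix import (
    MotifArray,
    compact_radix_sort,
    dedupe_sorted,
    empty_array,
    intersect_sorted,
    union_sorted,
)
from .trie import trie_from_string

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Configuration of one end-to-end solve."""

    l: int
    d: int
    engine: str = "trie"  # "trie" or "radix"
    workers: int = 1
    alphabet: Alphabet = field(default=DNA)
    seed: int = 0
    max_candidates: int | None = None  # per-string compact candidate cap
    rules_enabled: bool = True
    use_processes: bool = False

    def validate(self) -> None:
        if self.d < 0 or self.l <= self.d:
            raise InvalidParameterError("require l > d >= 0")
        if self.workers < 1:
            raise InvalidParameterError("workers must be >= 1")
        if self.engine not in ("trie", "radix"):
            raise InvalidParameterError(f"unknown engine {self.engine!r}")


def _validate_sequences(sequences: list[str], config: SolverConfig) -> None:
    if not sequences:
        raise InvalidInputError("no input sequences")
    for i, s in enumerate(sequences):
        if len(s) < config.l - config.d:
            raise InvalidInputError(
                f"sequence {i + 1} is shorter than l - d = {config.l - config.d}"
            )
        config.alphabet.validate(s)


def solve(sequences: list[str], config: SolverConfig) -> list[str]:
    """Exact common (l,d)-motif set of the input strings, sorted."""
    config.validate()
    _validate_sequences(sequences, config)
    if config.engine == "trie":
        return _solve_trie(sequences, config)
    return parallel_solve(sequences, config)


def _solve_trie(sequences: list[str], config: SolverConfig) -> list[str]:
    acc = None
    for i, s in enumerate(sequences):
        trie = trie_from_string(
            s, config.l, config.d, config.alphabet, config.rules_enabled
        )
        logger.info(
            "string %d: %d unique candidate l-mers", i + 1, trie.expansion_size()
        )
        acc = trie if acc is None else acc.intersect(trie)
        if acc.is_empty():
            return []
    assert acc is not None
    return acc.enumerate()


def _workloads(m: int, l: int, d: int) -> list[tuple[int, int]]:
    """All (j, k) k-mer generation workloads of one string, 1-based."""
    return [
        (j, k)
        for k in range(max(1, l - d), min(l + d, m) + 1)
        for j in range(1, m - k + 2)
    ]


def _worker_task(args) -> tuple[MotifArray, int]:
    """Generate, sort and dedupe the candidates of one workload chunk.

    Returns the sorted unique expanded candidates plus the compact
    candidate count (for the memory guard and diagnostics).
    """
    (s, chunk, l, d, rules_enabled, alphabet) = args
    motifs = [
        nb.motif
        for j, k in chunk
        for nb in gen_friends(s, j, k, l, d, rules_enabled, alphabet)
    ]
    arr = MotifArray.from_motifs(motifs, l, alphabet)
    return dedupe_sorted(compact_radix_sort(arr)), len(motifs)


def _tree_merge(arrays: list[MotifArray], l: int, alphabet: Alphabet) -> MotifArray:
    """Union sorted worker outputs pairwise, in log2(len) rounds."""
    if not arrays:
        return empty_array(l, alphabet)
    while len(arrays) > 1:
        if len(arrays) % 2:
            arrays.append(empty_array(l, alphabet))  # pad to an even round
        arrays = [
            union_sorted(arrays[i], arrays[i + 1]) for i in range(0, len(arrays), 2)
        ]
    return arrays[0]


def parallel_solve(sequences: list[str], config: SolverConfig) -> list[str]:
    """Array-engine solve with the seeded workload-partition contract."""
    config.validate()
    _validate_sequences(sequences, config)
    l, d, ab = config.l, config.d, config.alphabet
    executor = (
        ProcessPoolExecutor(max_workers=config.workers)
        if config.use_processes and config.workers > 1
        else None
    )
    try:
        acc: MotifArray | None = None
        for i, s in enumerate(sequences):
            work = _workloads(len(s), l, d)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, i])
            )
            order = rng.permutation(len(work))
            chunks = [
                [work[t] for t in part]
                for part in np.array_split(order, config.workers)
            ]
            tasks = [
                (s, chunk, l, d, config.rules_enabled, ab) for chunk in chunks
            ]
            if executor is not None:
                results = list(executor.map(_worker_task, tasks))
            else:
                results = [_worker_task(t) for t in tasks]
            parts = [arr for arr, _ in results]
            compact_total = sum(n for _, n in results)
            if (
                config.max_candidates is not None
                and compact_total > config.max_candidates
            ):
                raise CandidateLimitError(
                    f"string {i + 1}: {compact_total} compact candidates "
                    f"exceed the cap {config.max_candidates}"
                )
            unique_expanded = sum(len(p) for p in parts)
            logger.info(
                "string %d: %d compact candidates, <=%d unique expanded",
                i + 1,
                compact_total,
                unique_expanded,
            )
            if acc is not None:
                parts = [intersect_sorted(p, acc) for p in parts]
            acc = _tree_merge(parts, l, ab)
            if len(acc) == 0:
                return []
        assert acc is not None
        return acc.decode()
    finally:
        if executor is not None:
            executor.shutdown()
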