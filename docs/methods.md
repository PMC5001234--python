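# Methods

## Problem and scope

Given strings S⁽¹⁾…S⁽ⁿ⁾ over an ordered alphabet Σ and integers l > d ≥ 0,
the solver reports every l-mer within unit-cost edit distance d of at
least one substring of every string, exactly and in lexicographic order.
Only substring lengths k ∈ [l−d, l+d] can contribute, since |k−l| lower-
bounds the edit distance. We require l > d: for l ≤ d every l-mer is
trivially within distance d of short substrings and the answer degenerates
to Σˡ. Approximate or heuristic search and weighted edit costs are out of
scope.

## Exact-distance generation and the skip rules

Per k-mer the generator emits only candidates at distance *exactly* d
(three phases: δ deletions at strictly increasing positions, then β
substitutions at strictly increasing positions, then α insertions over
insertion points in non-decreasing order with multiplicity; δ+β+α = d,
k−δ+α = l). Substitutions and insertions write the wildcard `*`, which
expands to **all** of Σ — including the replaced character, which is legal
because a distance-(d−1) neighbor is in the motif set anyway. Deleted
characters are overwritten with a sentinel `-` that is kept until emission
(so rule predicates over original 1-based string positions stay
evaluable) and stripped from the emitted length-l motif.

Each candidate carries its trace {⟨p, o⟩}, o ∈ {D < R < I}. The nine skip
rules are monotone predicates over (j, k, m, trace) — conjunctions of
trace-membership conditions plus static position guards — so they are
applied as generation-time guards: as soon as a partial trace matches a
rule the whole subtree is pruned, which is equivalent to filtering
completed traces. `skip_rule` returns the lowest matching rule id for
diagnostics. Rules-off mode (the full three-phase enumeration) is a
first-class code path because the duplication statistics compare the two.

Two properties pin the implementation:

* **Completeness.** The union of expansions over all k-mers equals the
  brute-force motif set, with rules on and off. Verified on hundreds of
  randomized strings (m from l−d to 30, l ≤ 6, d ≤ 2) against two
  independent oracles.
* **Duplication-freeness on distinct characters.** With rules on, a string
  with no repeated character yields no repeated compact motif (tested on an
  enlarged alphabet, l ≤ 5, d ≤ 3).

Boundary note: the stronger statement that rules on and off produce the
same *set of compact strings* holds whenever m ≥ l+d, but can fail when a
k-mer spans the entire string (j = 1 and j+k = m+1, only possible for
m < l+d): the canonical surviving representative of a skipped trace may
need a character left of position 1. Expansion-level completeness — the
property the solver relies on — holds in every case we tested, including
m down to l−d; the compact-set equality test is therefore restricted to
m ≥ l+d.

## Set engines

**Motif trie.** Children of a node carry mutually exclusive label sets
(bitmasks in alphabet order). Insertion of a compact motif descends into
every child whose label meets the current character's symbol set (all of Σ
for `*`), peeling affected symbols into a deep-copied child when the label
is not fully covered, and creating a fresh chain for residual symbols.
Intersection pairs children by label intersection, recursing level-wise
and pruning branches that lose all leaves, so emptiness is visible at the
root; it builds a new trie (pure function) rather than mutating the
accumulator. Sorted, duplicate-free output falls out of a DFS that visits
symbols in alphabet order. The sibling-pointer memory layout used by some
implementations is intentionally not provided.

**Radix array engine.** Motifs are packed MSB-first, ⌈log₂|Σ|⌉ bits per
position, so integer order is lexicographic order; wildcards have zeroed
code bits plus a star-mask bit (l·bits must fit 63 bits — l ≤ 31 for DNA,
l ≤ 12 for protein; the trie engine has no such cap). The modified radix
sort runs one stable counting phase per position. Direction is LSD —
position l first — which the sorted-output contract forces: each phase
finalizes any wildcard at its position by emitting |Σ| copies (every
symbol's bucket counter is incremented), and phase-local stability makes
the final pass lexicographic. Dedup and intersection are linear scans over
the sorted arrays.

**Parallel contract.** Per string there are (2d+1)(m−l+1) k-mer
generation workloads. They are shuffled with a generator seeded from
(instance seed, string index), split evenly across `workers`, and each
worker generates, sorts and dedupes in isolation; worker outputs are
filtered against the accumulated common set and unioned pairwise in a
binary merge tree (padded with empty arrays for non-power-of-two counts).
Output is provably independent of the worker count. Worker tasks run
in-process by default; `use_processes=True` maps them onto a
`ProcessPoolExecutor` with identical results. Filtering against the
accumulator is applied by the coordinator after collecting worker arrays —
the same merge-scan primitive, identical output.

The solver processes strings in input order (no rarest-first reordering),
starts the accumulator from the first string, and exits early when the
accumulator empties. A configurable per-string compact-candidate cap
(`max_candidates`) aborts with a clear error instead of exhausting memory
on oversized (l,d) combinations.

## Oracles

Correctness is defined by brute force, two independent ways: (i) scan all
|Σ|ˡ candidate l-mers, testing each against the whole string with a banded
semiglobal (infix) alignment (edlib); (ii) grow the exact edit ball of
every k-mer one operation at a time and keep the length-l strings. Both
must agree with each other and with both engines; the randomized
acceptance sweep (100 instances, n ∈ [2,5], m ∈ [10,30], l ∈ [3,6],
d ∈ [0,2], workers ∈ {1,2,4}) enforces this. Pairwise `edit_distance` is
edlib's Needleman–Wunsch distance, cross-checked in tests against a
recursive definition and metric axioms on exhaustive small-string sets.

## Instance model and statistics

The simulator draws n i.i.d. uniform strings of length m (defaults n=20,
m=600 — the standard benchmark setting), draws one uniform l-mer M, and
plants in each string an independent neighbor at Hamming distance
*exactly* d (positions without replacement, each changed to a different
symbol; a flag allows ≤ d instead), overwriting a uniformly chosen
length-l window. Overwriting (rather than inserting) preserves m and
matches the established planted-instance tradition. One instance seed
spawns per-string substreams, so regeneration is bit-identical. A planted
occurrence has edit distance ≤ d from M, hence planted recovery is
guaranteed for an exact solver and asserted in tests. What the simulator
deliberately does not model: base composition bias, repeats,
phylogenetic correlation between sequences, or multiple/missing plant
occurrences — passing tests speak to algorithmic exactness on the i.i.d.
benchmark model, not to biological sensitivity.

`repetition_stats` counts, per string, how often each distinct compact
motif is emitted (total, distinct, multiplicity histogram); the instance
statistic averages per-string means, over a configurable subset of strings
since between-string spread is small (the acceptance script uses 2 of the
20 strings for the (11,3) measurement, and 8 replicate instances for the
(8,1) spurious mean).

`estimate_spurious` is a Monte-Carlo estimate of the expected number of
chance motifs on *unplanted* instances — spurious motifs are by definition
chance motifs, so unplanted instances are the right null — obtained by
actually running the solver per replicate and averaging counts (mean ±
standard error). No closed-form expectation is implemented.

### Measured values and two honest discrepancies

On random (11,3) 600-mers the generator emits each distinct compact motif
on average ≈1.5 times with the rules — the published ≈1.55 — but only
≈2.6–2.8 times with rules disabled, well short of the published ≈3.63.
Since the rules-on totals match, the historical rules-off baseline must
have produced ~40 % more duplicate generation events than the unordered
three-phase enumeration implemented here (an enumeration-order detail of
the original implementation that its description does not determine). We
report what this package computes.

The published expected spurious-motif count of 225.8 for (8,1) at n=20,
m=600 could not be reproduced and appears inconsistent with the model: a
random 600-mer's (8,1) neighborhood contains ≈21,060 of the 65,536
possible 8-mers (confirmed independently by both oracles and both
engines), giving a per-string coverage of ≈0.321 and an expected common
count of 65536·0.321²⁰ ≈ 10⁻⁵. The Monte-Carlo estimate is accordingly
0.0; the published figure derives from a closed form whose derivation is
not available. The d=0 column and the saturated 4ˡ entries of the same
published table *are* consistent with our measurements.

## Numerical and design choices

* Positions are 0-based half-open internally; traces and rule predicates
  use the 1-based closed convention of the trace definition, converted in
  one place (`gen_friends`).
* Lexicographic order is fixed by the alphabet's symbol order (A<C<G<T for
  DNA; listed order for protein).
* Characters outside the alphabet (e.g. `N`) are rejected with an error;
  FASTA reading is permissive (validation happens in the solver).
* Seeds: every stochastic component (instances, workload shuffling,
  replicate streams) derives from explicit integer seeds via seed
  sequences; derived seeds stay below 2³¹.
* Degenerate inputs: empty tries/arrays intersect to empty in O(1);
  sequences shorter than l−d are rejected; k ranges are clamped to the
  string length.

## Known limitations

Runtime grows exponentially with d (the (13,4)/(16,3) regimes need the
compiled-language treatment; this package targets correctness and
moderate instances), the radix engine's packed codes cap l as noted above,
and the duplication statistics at (11,3) take tens of seconds per string
in pure Python — the test suite and acceptance script therefore measure
subsets of strings and moderate replicate counts, as stated above.
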