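"""Brute-force reference solvers.

These define correctness for every production engine. An (l,d)-motif of a
string S is an l-mer within edit distance d of some substring of S; only
substring lengths k in [l-d, l+d] can contribute, since |k - l| is a lower
bound on the edit distance. A common motif of a string collection is an
l-mer that is a motif of every string.

Two independent routes are provided and must agree:

* ``scan``: enumerate all |Sigma|**l candidate l-mers and test each against
  the whole string with a banded infix alignment;
* ``grow``: grow the exact edit ball of every k-mer one operation at a time
  and keep the length-l strings.

Both are exponential and intended only for small problems.
"""

from __future__ import annotations

from itertools import product

from .alphabet import DNA, Alphabet
from .distance import neighbors_by_growth, within_substring_distance
from .errors import InvalidParameterError


def _check_params(l: int, d: int) -> None:
    if d < 0:
        raise InvalidParameterError("d must be non-negative")
    if l <= d:
        raise InvalidParameterError("l must exceed d (l > d required)")


def oracle_motifs_one_string(
    S: str,
    l: int,
    d: int,
    alphabet: Alphabet = DNA,
    method: str = "scan",
) -> set[str]:
    """Set of (l,d)-motifs of a single string, by exhaustive search."""
    _check_params(l, d)
    alphabet.validate(S)
    if method == "scan":
        return {
            x
            for tup in product(alphabet.symbols, repeat=l)
            if within_substring_distance(x := "".join(tup), S, d)
        }
    if method == "grow":
        out: set[str] = set()
        seen: dict[str, set[str]] = {}
        m = len(S)
        for k in range(max(1, l - d), min(l + d, m) + 1):
            for j in range(m - k + 1):
                kmer = S[j : j + k]
                if kmer not in seen:
                    seen[kmer] = neighbors_by_growth(kmer, l, d, alphabet)
                out |= seen[kmer]
        return out
    raise InvalidParameterError(f"unknown oracle method {method!r}")


def oracle_common_motifs(
    sequences: list[str],
    l: int,
    d: int,
    alphabet: Alphabet = DNA,
    method: str = "scan",
) -> list[str]:
    """Sorted common (l,d)-motifs of a collection of strings."""
    if not sequences:
        raise InvalidParameterError("at least one sequence required")
    common: set[str] | None = None
    for S in sequences:
        motifs = oracle_motifs_one_string(S, l, d, alphabet, method=method)
        common = motifs if common is None else common & motifs
        if not common:
            break
    assert common is not None
    return sorted(common, key=lambda x: tuple(alphabet.index(c) for c in x))
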