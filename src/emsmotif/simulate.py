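"""Planted-instance simulation.

The standard benchmark model for motif search: n i.i.d. uniform strings of
length m over Sigma (defaults n=20, m=600), with an optional planted motif.
When planting, a random l-mer M is drawn once; each string independently
receives a uniformly chosen neighbor of M at Hamming distance exactly d,
written over a uniformly chosen length-l window. A planted occurrence at
Hamming distance d has edit distance at most d from M, so M is guaranteed
to be reported by an exact (l,d) solver on a planted instance. Instances
with ``plant=False`` are the null model used to estimate how many motifs a
random input produces by chance (spurious motifs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import DNA, Alphabet
from .errors import InvalidParameterError


@dataclass(frozen=True)
class InstanceSpec:
    """Parameters of the planted-instance model."""

    l: int
    d: int
    n: int = 20
    m: int = 600
    plant: bool = True
    seed: int = 0


@dataclass
class Instance:
    """A concrete simulated (or loaded) problem instance."""

    sequences: list[str]
    l: int
    d: int
    planted: tuple[str, list[int]] | None = None  # (motif, 0-based plant starts)
    seed: int | None = None
    alphabet: Alphabet = field(default=DNA)

    @property
    def n(self) -> int:
        return len(self.sequences)


def _random_lmer(rng: np.random.Generator, l: int, alphabet: Alphabet) -> str:
    return "".join(alphabet.symbols[i] for i in rng.integers(0, len(alphabet), l))


def hamming_neighbor(
    M: str,
    d: int,
    rng: np.random.Generator,
    alphabet: Alphabet = DNA,
    exact: bool = True,
) -> str:
    """Uniform neighbor of M at Hamming distance exactly d (or <= d).

    d positions are chosen uniformly without replacement and each is changed
    to a uniformly chosen *different* symbol. With ``exact=False`` the
    number of changed positions is drawn uniformly from 0..d instead.
    """
    if d > len(M):
        raise InvalidParameterError("d cannot exceed the motif length")
    k = int(rng.integers(0, d + 1)) if not exact else d
    positions = rng.choice(len(M), size=k, replace=False)
    chars = list(M)
    for p in positions:
        others = [s for s in alphabet.symbols if s != chars[p]]
        chars[p] = others[int(rng.integers(0, len(others)))]
    return "".join(chars)


def generate_instance(spec: InstanceSpec, alphabet: Alphabet = DNA) -> Instance:
    """Draw an instance from the i.i.d. background model, optionally planted.

    A single instance seed deterministically derives independent sub-streams
    for the motif draw and for each string (content, plant variant, plant
    window), so regeneration with the same spec is bit-identical.
    """
    if spec.m < spec.l:
        raise InvalidParameterError("m must be at least l to plant a motif")
    if spec.d < 0 or spec.l <= spec.d:
        raise InvalidParameterError("require l > d >= 0")
    ss = np.random.SeedSequence(spec.seed)
    motif_ss, *string_ss = ss.spawn(spec.n + 1)
    motif = _random_lmer(np.random.default_rng(motif_ss), spec.l, alphabet)

    sequences: list[str] = []
    positions: list[int] = []
    for i in range(spec.n):
        rng = np.random.default_rng(string_ss[i])
        s = list(_random_lmer(rng, spec.m, alphabet))
        if spec.plant:
            variant = hamming_neighbor(motif, spec.d, rng, alphabet)
            pos = int(rng.integers(0, spec.m - spec.l + 1))
            s[pos : pos + spec.l] = variant
            positions.append(pos)
        sequences.append("".join(s))

    planted = (motif, positions) if spec.plant else None
    return Instance(sequences, spec.l, spec.d, planted, spec.seed, alphabet)
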