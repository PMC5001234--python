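"""Duplication and spurious-motif statistics.

``repetition_stats`` measures how often the compact neighborhood generator
emits the same compact motif string more than once on a given string —
the quantity the skip rules exist to reduce (mean multiplicity is exactly
1.0 on strings whose characters are all distinct).

``estimate_spurious`` estimates, by Monte Carlo over unplanted random
instances, the expected number of motifs an exact (l,d) solver reports on
pure background noise. This expectation determines which (l,d) instances
are "challenging": the largest l per d for which it is at least 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import DNA, Alphabet
from .errors import InvalidParameterError
from .neighborhood import gen_all
from .simulate import InstanceSpec, generate_instance
from .solver import SolverConfig, solve


@dataclass(frozen=True)
class RepetitionStats:
    """Multiplicity profile of compact motif generation on one string."""

    total_generated: int
    distinct: int
    histogram: dict[int, int]  # multiplicity -> number of distinct motifs

    @property
    def mean_multiplicity(self) -> float:
        return self.total_generated / self.distinct if self.distinct else float("nan")


def repetition_stats(
    S: str,
    l: int,
    d: int,
    rules_enabled: bool = True,
    alphabet: Alphabet = DNA,
) -> RepetitionStats:
    """Count how often each distinct compact motif is generated for S."""
    counts = Counter(
        nb.motif for nb in gen_all(S, l, d, rules_enabled=rules_enabled, alphabet=alphabet)
    )
    histogram = Counter(counts.values())
    return RepetitionStats(
        total_generated=sum(counts.values()),
        distinct=len(counts),
        histogram=dict(sorted(histogram.items())),
    )


@dataclass(frozen=True)
class SpuriousEstimate:
    """Monte-Carlo estimate of the expected chance-motif count."""

    mean: float
    stderr: float
    counts: tuple[int, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": range(1, len(self.counts) + 1), "motifs": self.counts}
        )


def estimate_spurious(
    l: int,
    d: int,
    n: int = 20,
    m: int = 600,
    replicates: int = 5,
    seed: int = 0,
    engine: str = "radix",
    alphabet: Alphabet = DNA,
) -> SpuriousEstimate:
    """Mean +- stderr of the motif count over unplanted random instances."""
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) >> 1
    counts = []
    for r in range(replicates):
        inst = generate_instance(
            InstanceSpec(l=l, d=d, n=n, m=m, plant=False, seed=int(child_seeds[r])),
            alphabet,
        )
        motifs = solve(
            inst.sequences,
            SolverConfig(l=l, d=d, engine=engine, seed=int(child_seeds[r]), alphabet=alphabet),
        )
        counts.append(len(motifs))
    arr = np.asarray(counts, dtype=float)
    stderr = float(arr.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else float("nan")
    return SpuriousEstimate(float(arr.mean()), stderr, tuple(counts))
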