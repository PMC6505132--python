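"""Allelic series: partitions of the 8 founder haplotypes into functional alleles.

An allelic series groups the founders A..H into m <= 8 functionally distinct
alleles; it is encoded as an 8 x m zero/one merge matrix M with exactly one 1
per row and no empty column.  Series are kept in canonical form: allele
labels are assigned in order of first appearance scanning founders A -> H,
so e.g. "11122222" is the canonical 3v5 bi-allelic series.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genome import N_FOUNDERS


@dataclass(frozen=True)
class AllelicSeries:
    """Canonical assignment of the 8 founders to alleles 1..m."""

    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        a = self.assignment
        if len(a) != N_FOUNDERS:
            raise ValueError("assignment must cover exactly 8 founders")
        seen_max = 0
        for label in a:
            if not 1 <= label <= seen_max + 1:
                raise ValueError(
                    f"assignment {a} is not canonical (labels by first appearance)"
                )
            seen_max = max(seen_max, label)

    @property
    def n_alleles(self) -> int:
        return max(self.assignment)

    @property
    def merge_matrix(self) -> np.ndarray:
        """8 x m zero/one matrix M mapping founders to alleles."""
        M = np.zeros((N_FOUNDERS, self.n_alleles))
        for f, label in enumerate(self.assignment):
            M[f, label - 1] = 1.0
        return M

    def block_sizes(self) -> tuple[int, ...]:
        counts = np.bincount(np.asarray(self.assignment), minlength=self.n_alleles + 1)[1:]
        return tuple(sorted((int(c) for c in counts), reverse=True))

    def to_string(self) -> str:
        return "".join(str(label) for label in self.assignment)

    @classmethod
    def from_string(cls, s: str) -> "AllelicSeries":
        return cls(tuple(int(ch) for ch in s))

    @classmethod
    def from_labels(cls, labels) -> "AllelicSeries":
        """Canonicalize an arbitrary labelling of the 8 founders."""
        remap: dict = {}
        out = []
        for lab in labels:
            if lab not in remap:
                remap[lab] = len(remap) + 1
            out.append(remap[lab])
        return cls(tuple(out))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


@lru_cache(maxsize=None)
def _enumerate_cached(n_founders: int, m: int) -> tuple[AllelicSeries, ...]:
    # Restricted growth strings: a_0 = 1, a_i <= max(a_0..a_{i-1}) + 1.
    results: list[AllelicSeries] = []

    def grow(prefix: list[int], current_max: int) -> None:
        if len(prefix) == n_founders:
            if current_max == m:
                results.append(AllelicSeries(tuple(prefix)))
            return
        # prune: cannot reach m alleles with the founders left
        remaining = n_founders - len(prefix)
        if current_max + remaining < m:
            return
        for label in range(1, min(current_max + 1, m) + 1):
            grow(prefix + [label], max(current_max, label))

    grow([1], 1)
    return tuple(results)


def enumerate_series(n_founders: int = N_FOUNDERS, m: int = 2) -> list[AllelicSeries]:
    """All set partitions of the founders into exactly m nonempty alleles,
    canonically labelled; the count is the Stirling number S(n_founders, m)."""
    if n_founders != N_FOUNDERS:
        raise ValueError("series are defined for the 8-founder panel")
    if not 1 <= m <= n_founders:
        raise ValueError(f"m must lie in [1, {n_founders}]")
    return list(_enumerate_cached(n_founders, m))


def sample_series(m: int, seed: int | np.random.Generator) -> AllelicSeries:
    """Draw an allelic series uniformly from all partitions with m alleles.

    m = 1 is rejected: a single functional allele carries no QTL variance.
    """
    if not 2 <= m <= N_FOUNDERS:
        raise ValueError("m must lie in [2, 8] for a variance-carrying QTL")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    options = _enumerate_cached(N_FOUNDERS, m)
    return options[int(rng.integers(len(options)))]


def balance_class(series: AllelicSeries) -> str:
    """Sorted block-size signature, e.g. '4v4', '7v1', '1v1v1v1v1v1v1v1'."""
    return "v".join(str(b) for b in series.block_sizes())
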