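"""Synthetic founder-mosaic genomes for an eight-founder RI panel.

Emulates the salient features of Collaborative Cross-like genomes — mosaic
founder haplotype blocks along 19 autosomes plus X, near-complete
homozygosity, and confident but not certain diplotype probabilities — with a
first-order Markov chain over founder labels.  It makes no attempt to model
breeding funnels, selection, or realized founder imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import (
    FOUNDERS,
    N_FOUNDERS,
    N_STATES,
    FounderProbTable,
    MarkerMap,
    haplotype_dosages,
)
import itertools

import pandas as pd

_HET_INDEX = {
    frozenset(p): N_FOUNDERS + k
    for k, p in enumerate(itertools.combinations(range(N_FOUNDERS), 2))
}


@dataclass
class SyntheticGenomeConfig:
    """Parameters of the synthetic RI panel.

    Defaults give a desk-scale genome: 20 chromosomes (19 autosomes + "X",
    treated identically) of 90 Mb each at 1 Mb marker spacing, ~1,800 loci.
    block_length_mb is the expected founder-haplotype block length; the
    per-interval switch probability is spacing / block_length.  softening
    is the maximum probability mass smeared off the true diplotype state
    (0 = hard one-hot calls; 0.1 leaves >= 0.9 on the truth).
    """

    n_strains: int = 50
    n_founders: int = N_FOUNDERS
    chrom_lengths_mb: tuple[float, ...] = field(default_factory=lambda: (90.0,) * 20)
    marker_spacing_mb: float = 1.0
    block_length_mb: float = 18.0
    het_rate: float = 0.0
    het_run_loci: float = 3.0
    softening: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders != N_FOUNDERS:
            raise ValueError("the panel model is fixed at 8 founders")
        if not self.chrom_lengths_mb or min(self.chrom_lengths_mb) <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.marker_spacing_mb <= 0 or self.block_length_mb <= 0:
            raise ValueError("spacing and block length must be positive")
        if not 0.0 <= self.het_rate <= 1.0:
            raise ValueError("het_rate must lie in [0, 1]")
        if not 0.0 <= self.softening < 1.0:
            raise ValueError("softening must lie in [0, 1)")

    @property
    def chromosome_labels(self) -> list[str]:
        n = len(self.chrom_lengths_mb)
        if n >= 2:
            return [str(i + 1) for i in range(n - 1)] + ["X"]
        return [str(i + 1) for i in range(n)]


def _chromosome_mosaic(rng: np.random.Generator, n_loci: int, p_switch: float) -> np.ndarray:
    """First-order Markov founder path: uniform start, switch to a uniformly
    chosen *different* founder with probability p_switch per interval."""
    path = np.empty(n_loci, dtype=int)
    path[0] = rng.integers(N_FOUNDERS)
    switches = rng.random(n_loci - 1) < p_switch if n_loci > 1 else np.empty(0, bool)
    for i in range(1, n_loci):
        if switches[i - 1]:
            shift = rng.integers(1, N_FOUNDERS)
            path[i] = (path[i - 1] + shift) % N_FOUNDERS
        else:
            path[i] = path[i - 1]
    return path


def simulate_ri_panel(config: SyntheticGenomeConfig) -> FounderProbTable:
    """Generate a panel of mosaic genomes as a validated FounderProbTable."""
    rng = np.random.default_rng(config.seed)
    spacing = config.marker_spacing_mb
    p_switch = min(1.0, spacing / config.block_length_mb)

    chrom_rows = []
    chrom_n_loci = []
    for label, length in zip(config.chromosome_labels, config.chrom_lengths_mb):
        positions = np.arange(spacing / 2.0, length, spacing)
        if positions.size == 0:
            raise ValueError(f"chromosome {label} shorter than one marker spacing")
        chrom_n_loci.append(positions.size)
        for pos in positions:
            chrom_rows.append({"chromosome": label, "position_mb": float(pos)})
    markers = pd.DataFrame(chrom_rows)
    markers.insert(0, "locus_id", [f"L{i:05d}" for i in range(len(markers))])
    n_loci = len(markers)

    states = np.empty((config.n_strains, n_loci), dtype=int)
    for s in range(config.n_strains):
        offset = 0
        for n_c in chrom_n_loci:
            path = _chromosome_mosaic(rng, n_c, p_switch)
            chrom_states = path.copy()  # homozygote state index == founder index
            if config.het_rate > 0:
                l = 0
                while l < n_c:
                    if rng.random() < config.het_rate:
                        run = int(rng.geometric(1.0 / config.het_run_loci))
                        partner = (path[l] + rng.integers(1, N_FOUNDERS)) % N_FOUNDERS
                        for j in range(l, min(l + run, n_c)):
                            chrom_states[j] = _HET_INDEX[frozenset((int(path[j]), int(partner)))] \
                                if path[j] != partner else path[j]
                        l += run
                    else:
                        l += 1
            states[s, offset : offset + n_c] = chrom_states
            offset += n_c

    probs = np.zeros((config.n_strains, n_loci, N_STATES))
    flat_strain = np.repeat(np.arange(config.n_strains), n_loci)
    flat_locus = np.tile(np.arange(n_loci), config.n_strains)
    probs[flat_strain, flat_locus, states.ravel()] = 1.0

    if config.softening > 0:
        removed = config.softening * rng.random((config.n_strains, n_loci))
        probs *= (1.0 - removed)[:, :, None]
        spread = removed / (N_STATES - 1)
        probs += spread[:, :, None]
        probs[flat_strain, flat_locus, states.ravel()] -= spread.ravel()

    return FounderProbTable(
        strain_ids=[f"SYN{s + 1:03d}" for s in range(config.n_strains)],
        markers=MarkerMap(markers),
        probs=probs,
    )


def founder_contribution_table(table: FounderProbTable) -> np.ndarray:
    """Genome-wide founder shares: mean haplotype-probability share over all
    strains and loci.  Sums to 1; ~1/8 each for a balanced generator."""
    shares = haplotype_dosages(table) / 2.0
    return shares.mean(axis=(0, 1))
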