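"""Phenotype simulation on strain means for a single additive QTL.

The generative model for strain means is

    y_bar = mu + X beta + u + eps_bar,        X = D A M,

with D the hard-called diplotype incidence at the QTL, A the additive
36 -> 8 dosage map, M the allelic-series merge matrix, beta the allele
effects, u polygenic strain effects, and eps_bar the residual error on
means with variance sigma^2 / r for r replicates.  All random components
are rescaled per draw to *population* variances (denominator N), so a
draw's realized variance decomposition matches the configured fractions
exactly rather than only in expectation.

Allele effect scaling supports three effect-size definitions:
  B    - h2_qtl = Var(2 beta): variance in a theoretical population
         balanced in the functional alleles
  MB   - h2_qtl = Var(2 M beta): balanced in the founders
  DAMB - h2_qtl = Var(X beta): variance realized in the mapping sample
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import ADDITIVE_MATRIX, FounderProbTable, diplotype_incidence
from .series import AllelicSeries, sample_series

DEFINITIONS = ("B", "MB", "DAMB")


class DegenerateLocusError(RuntimeError):
    """The QTL is monomorphic in the sampled strains under Definition DAMB,
    so no finite scaling can realize the requested variance."""


def popvar(x: np.ndarray) -> float:
    """Population variance (denominator N)."""
    return float(np.var(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class VarianceConfig:
    """QTL / strain / residual variance fractions (must sum to exactly 1)
    and the number of replicates per strain."""

    h2_qtl: float
    h2_strain: float
    sigma2: float
    replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("h2_qtl", "h2_strain", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        total = self.h2_qtl + self.h2_strain + self.sigma2
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {total}, must be exactly 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def effective_qtl_size(variance: VarianceConfig) -> float:
    """Replicate-equivalent QTL effect size on the strain-mean scale:
    h2_qtl / (h2_qtl + h2_strain + sigma2 / r).

    A mapping experiment on means of r replicates is equivalent to a
    single-observation experiment with no strain effect at this size.
    """
    denom = variance.h2_qtl + variance.h2_strain + variance.sigma2 / variance.replicates
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return variance.h2_qtl / denom


@dataclass
class QTLSimSpec:
    """Everything needed to simulate one phenotype draw."""

    locus: int | str
    series: AllelicSeries
    variance: VarianceConfig
    definition: str = "B"
    strain_subset: Sequence[int] | Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.definition not in DEFINITIONS:
            raise ValueError(f"definition must be one of {DEFINITIONS}")


@dataclass
class PhenotypeSet:
    """Simulated strain means plus the generative truth for audit."""

    strain_means: np.ndarray
    strain_ids: list[str]
    truth: dict


def build_design(
    table: FounderProbTable, locus: int | str, series: AllelicSeries
) -> np.ndarray:
    """Allele dosage design X = D A M (strains x m) from hard-called
    diplotypes; every row sums to 2."""
    D = diplotype_incidence(table, locus)
    return D @ ADDITIVE_MATRIX @ series.merge_matrix


def scale_allele_effects(
    raw: np.ndarray,
    definition: str,
    X: np.ndarray,
    M: np.ndarray,
    h2_qtl: float,
) -> np.ndarray:
    """Rescale raw allele effects so the requested definition's population
    variance equals h2_qtl exactly.

    The variance taken is Var(2 beta) for B, Var(2 M beta) for MB, and
    Var(X beta) over the sampled strains for DAMB.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"definition must be one of {DEFINITIONS}")
    raw = np.asarray(raw, dtype=float)
    if h2_qtl == 0.0:
        return np.zeros_like(raw)
    if raw.size < 2:
        raise ValueError("need at least 2 allele effects")
    if definition == "B":
        base = 2.0 * raw
    elif definition == "MB":
        base = 2.0 * (M @ raw)
    else:
        base = X @ raw
    v = popvar(base)
    if v <= 1e-14:
        if definition == "DAMB":
            raise DegenerateLocusError(
                "QTL monomorphic in the sampled strains: Var(X beta) = 0"
            )
        raise ValueError("raw allele effects carry no variance")
    return raw * np.sqrt(h2_qtl / v)


def _rescaled_normal(rng: np.random.Generator, n: int, target_var: float) -> np.ndarray:
    """Standard normal draws rescaled to population variance target_var."""
    if target_var == 0.0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    v = popvar(z)
    if v <= 0:
        raise RuntimeError("degenerate normal draw")
    return z * np.sqrt(target_var / v)


def simulate_phenotypes(
    spec: QTLSimSpec,
    table: FounderProbTable,
    kinship: np.ndarray | None = None,
) -> PhenotypeSet:
    """Simulate strain means y_bar = X beta + u + eps_bar (mu = 0).

    u has population variance h2_strain; independent draws by default, or
    correlated as N(0, K h2_strain) when a kinship matrix (subset to the
    sampled strains) is supplied, then rescaled to the exact fraction.
    eps_bar has population variance sigma2 / r.
    """
    sub = table.subset_strains(spec.strain_subset) if spec.strain_subset is not None else table
    n = sub.n_strains
    rng = np.random.default_rng(spec.seed)
    var = spec.variance

    X = build_design(sub, spec.locus, spec.series)
    raw = rng.standard_normal(spec.series.n_alleles)
    beta = scale_allele_effects(raw, spec.definition, X, spec.series.merge_matrix, var.h2_qtl)
    qtl_term = X @ beta

    if kinship is not None and var.h2_strain > 0:
        K = np.asarray(kinship, dtype=float)
        if K.shape != (n, n):
            raise ValueError("kinship shape does not match the sampled strains")
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
        u = L @ rng.standard_normal(n)
        v = popvar(u)
        if v <= 0:
            raise ValueError("kinship produced a degenerate strain-effect draw")
        u *= np.sqrt(var.h2_strain / v)
    else:
        u = _rescaled_normal(rng, n, var.h2_strain)

    eps = _rescaled_normal(rng, n, var.sigma2 / var.replicates)
    y = qtl_term + u + eps
    return PhenotypeSet(
        strain_means=y,
        strain_ids=list(sub.strain_ids),
        truth={
            "locus": spec.locus,
            "series": spec.series.to_string(),
            "definition": spec.definition,
            "beta": beta,
            "u": u,
            "eps_bar": eps,
            "h2_qtl": var.h2_qtl,
            "h2_strain": var.h2_strain,
            "sigma2": var.sigma2,
            "replicates": var.replicates,
            "structured": kinship is not None,
        },
    )


def sample_experiment(
    table: FounderProbTable,
    n_strains: int,
    m_alleles: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, int, AllelicSeries]:
    """Uniformly sample the strain subset, the causal locus, and the allelic
    series for one simulation trial."""
    if n_strains > table.n_strains:
        raise ValueError(
            f"requested {n_strains} strains but the panel has {table.n_strains}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strains = np.sort(rng.choice(table.n_strains, size=n_strains, replace=False))
    locus = int(rng.integers(table.n_loci))
    series = sample_series(m_alleles, rng)
    return strains, locus, series
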