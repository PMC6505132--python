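import numpy as np
import pandas as pd
import pytest

import ccpower as cp
from ccpower.genome import FounderProbTable, MarkerMap, N_STATES


def random_prob_table(
    n_strains: int, n_loci: int, seed: int, n_chroms: int = 2, concentration: float = 0.3
) -> FounderProbTable:
    """Dirichlet-random diplotype probabilities over a simple marker map."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(N_STATES, concentration), size=(n_strains, n_loci))
    per = n_loci // n_chroms
    chroms, pos = [], []
    for l in range(n_loci):
        c = min(l // per, n_chroms - 1)
        chroms.append(str(c + 1))
        pos.append(float((l - c * per) + 1.0) if c < n_chroms - 1 else float((l - (n_chroms - 1) * per) + 1.0))
    markers = MarkerMap(
        pd.DataFrame(
            {"locus_id": [f"T{l:03d}" for l in range(n_loci)], "chromosome": chroms,
             "position_mb": pos}
        )
    )
    return FounderProbTable(
        strain_ids=[f"S{i}" for i in range(n_strains)], markers=markers, probs=probs
    )


@pytest.fixture(scope="session")
def tiny_panel() -> FounderProbTable:
    """12 strains x 200 loci over 5 chromosomes; hard one-hot mosaics."""
    return cp.simulate_ri_panel(
        cp.SyntheticGenomeConfig(n_strains=12, chrom_lengths_mb=(40.0,) * 5, seed=1)
    )


@pytest.fixture(scope="session")
def soft_panel() -> FounderProbTable:
    """20 strains x 50 loci with softened (uncertain) probabilities."""
    return cp.simulate_ri_panel(
        cp.SyntheticGenomeConfig(
            n_strains=20, chrom_lengths_mb=(25.0,) * 2, marker_spacing_mb=1.0,
            softening=0.1, seed=7,
        )
    )


@pytest.fixture(scope="session")
def panel50() -> FounderProbTable:
    """Desk-scale study panel: 50 strains, 20 chromosomes, ~1,800 loci."""
    return cp.simulate_ri_panel(cp.SyntheticGenomeConfig(n_strains=50, seed=11))


def oracle_logp(y: np.ndarray, table: FounderProbTable, strains=None) -> np.ndarray:
    """Independent per-locus regression oracle: statsmodels OLS of the strain
    means on intercept + 8 haplotype dosages, F-test against intercept-only
    via compare_f_test."""
    import statsmodels.api as sm

    sub = table.subset_strains(strains) if strains is not None else table
    dosages = cp.haplotype_dosages(sub)
    y = np.asarray(y, dtype=float)
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    out = np.empty(sub.n_loci)
    for l in range(sub.n_loci):
        X = np.column_stack([np.ones(len(y)), dosages[:, l, :]])
        full = sm.OLS(y, X).fit()
        if full.df_resid <= 0 or full.df_model <= 0:
            out[l] = 0.0
            continue
        _, p, _ = full.compare_f_test(null)
        out[l] = min(-np.log10(max(float(p), 1e-300)), 300.0)
    return out
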