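"""Genome scans by haplotype-dosage regression with permutation thresholds.

At each locus the strain means are regressed on an intercept plus the eight
expected founder-haplotype dosages (the soft-probability design P A); the
fit is compared with the intercept-only model by an F-test and reported as
logP = -log10(p).  Because dosage rows sum to 2 the eight columns are always
collinear with the intercept, so degrees of freedom are taken from the
numerical rank of the centered dosage block (typically 7; fewer when some
founders are absent among the sampled strains).

Genome-wide significance is calibrated by permuting the strain-mean vector,
recording each permutation's maximum logP, fitting a generalized extreme
value distribution to the maxima by maximum likelihood, and taking its
upper-alpha quantile.  Permutation scans reuse one orthogonal decomposition
per locus, so scanning many permutations costs a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FounderProbTable, MarkerMap, haplotype_dosages

#: p-values below 10**-LOGP_CAP are capped to avoid infinities.
LOGP_CAP = 300.0

#: Minimum strains for a scan: rank headroom over 8 dosage columns + intercept.
MIN_STRAINS = 10


@dataclass
class ScanResult:
    """Per-locus logP scores over a marker map."""

    markers: MarkerMap
    logp: np.ndarray

    def __post_init__(self) -> None:
        self.logp = np.asarray(self.logp, dtype=float)
        if self.logp.shape != (self.markers.n_loci,):
            raise ValueError("logp length mismatch with marker map")

    @property
    def max_logp(self) -> float:
        return float(self.logp.max())

    def peak_per_chromosome(self) -> pd.DataFrame:
        df = self.markers.df.copy()
        df["logp"] = self.logp
        idx = df.groupby("chromosome", sort=False)["logp"].idxmax()
        return df.loc[idx].reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.df.copy()
        df["logp"] = self.logp
        return df


@dataclass
class Threshold:
    """Permutation-calibrated genome-wide logP critical value."""

    alpha: float
    value: float
    gev_shape: float | None
    gev_loc: float | None
    gev_scale: float | None
    n_permutations: int
    method: str = "gev"  # or "empirical" on fit failure

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.value < 0:
            raise ValueError("threshold must be nonnegative")


class GenomeScanner:
    """Precomputed per-locus orthogonal bases for fast repeated scans.

    Centering the dosage block absorbs the intercept; an SVD per locus gives
    a rank-revealing orthonormal basis U_l, so the model sum of squares for
    any (centered) response is ||U_l' y||^2.  The same bases serve the
    observed scan and every permutation, which guarantees batch permutation
    scans agree with naive per-permutation scans to machine precision.
    """

    def __init__(self, table: FounderProbTable, strain_subset=None):
        sub = table.subset_strains(strain_subset) if strain_subset is not None else table
        if sub.n_strains < MIN_STRAINS:
            raise ValueError(
                f"need at least {MIN_STRAINS} strains for a stable scan; got {sub.n_strains}"
            )
        self.table = sub
        self.markers = sub.markers
        self.n = sub.n_strains

        dos = haplotype_dosages(sub)  # (n, L, 8)
        W = dos - dos.mean(axis=0, keepdims=True)
        Wl = np.ascontiguousarray(W.transpose(1, 0, 2))  # (L, n, 8)
        U, s, _ = np.linalg.svd(Wl, full_matrices=False)
        tol = s[:, :1] * max(self.n, 8) * np.finfo(float).eps
        rank = (s > tol).sum(axis=1)
        # zero out directions beyond the numerical rank
        keep = np.arange(s.shape[1])[None, :] < rank[:, None]
        self._U = U * keep[:, None, :]  # (L, n, 8)
        self.rank = rank.astype(int)  # numerator df per locus
        self._df2 = self.n - 1 - self.rank

    def _logp_from_explained(self, explained: np.ndarray, tss: np.ndarray) -> np.ndarray:
        """F-test logP from model SS and total SS (broadcast over loci)."""
        df1 = self.rank.reshape(-1, *([1] * (explained.ndim - 1)))
        df2 = self._df2.reshape(df1.shape)
        tss = np.broadcast_to(np.asarray(tss, dtype=float), explained.shape)
        rss = np.clip(tss - explained, 0.0, None)
        valid = (df1 > 0) & (df2 > 0) & (tss > 0)
        perfect = valid & (rss <= tss * 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (explained / df1) / (rss / df2)
            p = stats.f.sf(F, df1, df2)
        logp = np.where(valid & ~perfect, -np.log10(np.clip(p, 10.0 ** -LOGP_CAP, None)), 0.0)
        logp = np.where(perfect, LOGP_CAP, logp)
        return np.minimum(logp, LOGP_CAP)

    def scan(self, y: np.ndarray) -> ScanResult:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("phenotype length mismatch with strains")
        yc = y - y.mean()
        tss = float(yc @ yc)
        coefs = np.tensordot(self._U, yc, axes=(1, 0))  # (L, 8)
        explained = (coefs**2).sum(axis=1)
        return ScanResult(markers=self.markers, logp=self._logp_from_explained(explained, tss))

    def r_squared(self, y: np.ndarray) -> np.ndarray:
        """Per-locus model R^2 of the eight-allele fit (for effect-size
        estimation at detected peaks)."""
        y = np.asarray(y, dtype=float)
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss <= 0:
            return np.zeros(self.markers.n_loci)
        coefs = np.tensordot(self._U, yc, axes=(1, 0))
        return np.clip((coefs**2).sum(axis=1) / tss, 0.0, 1.0)

    def permutation_max_logp(self, y: np.ndarray, permutations: np.ndarray) -> np.ndarray:
        """Genome-wide max logP for each permutation (rows of index vectors).

        Identical (to machine precision) to scanning each permuted vector
        independently.
        """
        y = np.asarray(y, dtype=float)
        permutations = np.asarray(permutations)
        if permutations.ndim != 2 or permutations.shape[1] != self.n:
            raise ValueError("permutations must be (n_perm, n_strains) index rows")
        ident = np.arange(self.n)
        for row in permutations:
            if not np.array_equal(np.sort(row), ident):
                raise ValueError("permutation is not a bijection of strain indices")
        yc = y - y.mean()
        tss = float(yc @ yc)
        Y = yc[permutations.T]  # (n, n_perm); mean is permutation-invariant
        coefs = np.tensordot(self._U, Y, axes=(1, 0))  # (L, 8, n_perm)
        explained = (coefs**2).sum(axis=1)  # (L, n_perm)
        logp = self._logp_from_explained(explained, tss)
        return logp.max(axis=0)


def scan_genome(
    y: np.ndarray, table: FounderProbTable, strain_subset=None
) -> ScanResult:
    """Single genome scan of strain means by haplotype-dosage regression."""
    return GenomeScanner(table, strain_subset).scan(y)


def batch_permutation_scans(
    y: np.ndarray, table: FounderProbTable, strain_subset=None, permutations=None
) -> np.ndarray:
    """Max logP per supplied permutation; equals the naive per-permutation
    scan loop to machine precision."""
    if permutations is None:
        raise ValueError("permutations (index rows) are required")
    return GenomeScanner(table, strain_subset).permutation_max_logp(
        y, np.asarray(permutations)
    )


def fit_gev_threshold(maxima: np.ndarray, alpha: float = 0.05) -> Threshold:
    """Fit a GEV to permutation maxima by ML; threshold = upper-alpha quantile.

    Falls back to the empirical (1 - alpha) quantile when the fit fails or
    yields a non-finite quantile (e.g. near-constant maxima).
    """
    maxima = np.asarray(maxima, dtype=float)
    n_perm = maxima.size
    try:
        if np.ptp(maxima) <= 1e-12:
            raise RuntimeError("degenerate maxima")
        c, loc, scale = stats.genextreme.fit(maxima)
        value = float(stats.genextreme.isf(alpha, c, loc=loc, scale=scale))
        if not np.isfinite(value) or value < 0:
            raise RuntimeError("non-finite GEV quantile")
        return Threshold(
            alpha=alpha, value=value, gev_shape=float(c), gev_loc=float(loc),
            gev_scale=float(scale), n_permutations=n_perm, method="gev",
        )
    except Exception:
        value = float(np.quantile(maxima, 1.0 - alpha))
        return Threshold(
            alpha=alpha, value=max(value, 0.0), gev_shape=None, gev_loc=None,
            gev_scale=None, n_permutations=n_perm, method="empirical",
        )


def permutation_thresholds(
    y: np.ndarray,
    table: FounderProbTable,
    strain_subset=None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    scanner: GenomeScanner | None = None,
) -> Threshold:
    """Permutation-calibrated genome-wide threshold for one phenotype draw."""
    if n_perm < 20:
        raise ValueError("need at least 20 permutations for a stable GEV fit")
    if scanner is None:
        scanner = GenomeScanner(table, strain_subset)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(scanner.n) for _ in range(n_perm)])
    maxima = scanner.permutation_max_logp(np.asarray(y, dtype=float), perms)
    return fit_gev_threshold(maxima, alpha)
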