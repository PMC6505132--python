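"""Founder-diplotype probability genomes for eight-founder recombinant inbred panels.

A strain's genome is represented locus-by-locus as a probability distribution
over the 36 unordered diplotype states of 8 founder haplotypes (labelled
A..H): the 8 homozygous states AA..HH followed by the 28 heterozygous pairs
AB, AC, ..., GH in lexicographic founder order.  This module loads and saves
such tables, collapses nearly-identical adjacent intervals, converts
probabilities to additive haplotype dosages and hard diplotype calls, and
computes realized-kinship diagnostics of population structure.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FOUNDERS: tuple[str, ...] = tuple("ABCDEFGH")
N_FOUNDERS = 8
N_STATES = 36

#: Unordered diplotype state labels: homozygotes first, then heterozygote
#: pairs in lexicographic founder order.  This order is fixed package-wide
#: and enforced at load time.
STATE_LABELS: tuple[str, ...] = tuple(f + f for f in FOUNDERS) + tuple(
    a + b for a, b in itertools.combinations(FOUNDERS, 2)
)

#: Maximum possible L2 distance between two diplotype probability vectors,
#: by the convention used for the adjacent-interval reduction threshold.
MAX_L2_NORM = 2.0

PROB_TOL = 1e-6


def additive_model_matrix() -> np.ndarray:
    """The fixed 36 x 8 map from diplotype state to founder haplotype dosage.

    Row for homozygote FF has a single 2 in column F; the row for
    heterozygote FG has 1s in columns F and G.  Every row sums to 2.
    """
    A = np.zeros((N_STATES, N_FOUNDERS))
    for k in range(N_FOUNDERS):
        A[k, k] = 2.0
    for k, (i, j) in enumerate(itertools.combinations(range(N_FOUNDERS), 2)):
        A[N_FOUNDERS + k, i] = 1.0
        A[N_FOUNDERS + k, j] = 1.0
    return A


ADDITIVE_MATRIX = additive_model_matrix()
ADDITIVE_MATRIX.setflags(write=False)


class GenomeValidationError(ValueError):
    """A genome table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Marker map and probability table containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered marker/interval map: locus_id, chromosome label, position in Mb.

    Positions must be strictly increasing within each chromosome and locus
    ids unique.  The X chromosome is carried as the label "X" but treated
    identically to an autosome throughout.
    """

    df: pd.DataFrame  # columns: locus_id, chromosome, position_mb

    def __post_init__(self) -> None:
        required = {"locus_id", "chromosome", "position_mb"}
        missing = required - set(self.df.columns)
        if missing:
            raise GenomeValidationError(f"marker map missing columns {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        self.df["chromosome"] = self.df["chromosome"].astype(str)
        if self.df["locus_id"].duplicated().any():
            dup = self.df.loc[self.df["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise GenomeValidationError(f"duplicated locus_id {dup!r}")
        for chrom, grp in self.df.groupby("chromosome", sort=False):
            pos = grp["position_mb"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise GenomeValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.df)

    @property
    def locus_ids(self) -> np.ndarray:
        return self.df["locus_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.df["chromosome"].to_numpy()

    @property
    def positions_mb(self) -> np.ndarray:
        return self.df["position_mb"].to_numpy(float)

    def chromosome_labels(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.df["chromosome"]))

    def index_of(self, locus: int | str) -> int:
        """Resolve a locus id or integer index to an integer index."""
        if isinstance(locus, (int, np.integer)):
            idx = int(locus)
            if not 0 <= idx < self.n_loci:
                raise KeyError(f"locus index {idx} out of range")
            return idx
        hits = np.flatnonzero(self.df["locus_id"].to_numpy() == locus)
        if hits.size == 0:
            raise KeyError(f"unknown locus {locus!r}")
        return int(hits[0])


@dataclass
class FounderProbTable:
    """Diplotype probabilities for a panel: strains x loci x 36 states."""

    strain_ids: list[str]
    markers: MarkerMap
    probs: np.ndarray  # (n_strains, n_loci, 36)

    def __post_init__(self) -> None:
        self.strain_ids = [str(s) for s in self.strain_ids]
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != N_STATES:
            raise GenomeValidationError(
                f"probs must be (strains, loci, {N_STATES}); got {self.probs.shape}"
            )
        if len(self.strain_ids) != self.probs.shape[0]:
            raise GenomeValidationError("strain_ids length mismatch with probs")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise GenomeValidationError("duplicated strain ids")
        if self.markers.n_loci != self.probs.shape[1]:
            raise GenomeValidationError("marker map length mismatch with probs")
        if self.n_strains < 2:
            raise GenomeValidationError("need at least 2 strains")
        if np.any(self.probs < -PROB_TOL):
            raise GenomeValidationError("negative diplotype probability")
        sums = self.probs.sum(axis=2)
        bad = np.abs(sums - 1.0) > PROB_TOL
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise GenomeValidationError(
                f"probability row for strain {self.strain_ids[i]!r}, locus "
                f"{self.markers.locus_ids[l]!r} sums to {sums[i, l]:.6f}, not 1"
            )

    @property
    def n_strains(self) -> int:
        return self.probs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.probs.shape[1]

    def strain_indices(self, strains: Sequence[int] | Sequence[str] | None) -> np.ndarray:
        """Resolve strain ids/indices (or None for all) to an index array."""
        if strains is None:
            return np.arange(self.n_strains)
        strains = list(strains)
        if all(isinstance(s, (int, np.integer)) for s in strains):
            idx = np.asarray(strains, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_strains):
                raise KeyError("strain index out of range")
            return idx
        lookup = {s: i for i, s in enumerate(self.strain_ids)}
        try:
            return np.asarray([lookup[str(s)] for s in strains], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown strain {e.args[0]!r}") from None

    def subset_strains(self, strains: Sequence[int] | Sequence[str]) -> "FounderProbTable":
        idx = self.strain_indices(strains)
        return FounderProbTable(
            strain_ids=[self.strain_ids[i] for i in idx],
            markers=self.markers,
            probs=self.probs[idx],
        )


# ---------------------------------------------------------------------------
# Cache IO
# ---------------------------------------------------------------------------
#
# On-disk layout (one directory):
#   cache.json            - state order, strain list, chromosome labels
#   markers.csv           - locus_id, chromosome, position_mb
#   chr<label>.csv        - strain-major rows (strain, locus_id, 36 state cols)
#
# This mirrors the per-chromosome directory convention of HAPPY-style caches
# while staying plain-text.


def save_genome_cache(table: FounderProbTable, directory: str | Path) -> Path:
    """Write a genome cache directory; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "state_order": list(STATE_LABELS),
        "strain_ids": table.strain_ids,
        "chromosomes": table.markers.chromosome_labels(),
        "n_loci": table.n_loci,
    }
    (directory / "cache.json").write_text(json.dumps(meta, indent=1))
    table.markers.df.to_csv(directory / "markers.csv", index=False)
    chroms = table.markers.chromosomes
    locus_ids = table.markers.locus_ids
    for chrom in table.markers.chromosome_labels():
        mask = np.flatnonzero(chroms == chrom)
        rows = []
        for i, strain in enumerate(table.strain_ids):
            block = pd.DataFrame(table.probs[i, mask, :], columns=list(STATE_LABELS))
            block.insert(0, "locus_id", locus_ids[mask])
            block.insert(0, "strain", strain)
            rows.append(block)
        pd.concat(rows, ignore_index=True).to_csv(directory / f"chr{chrom}.csv", index=False)
    return directory


def load_genome_cache(directory: str | Path) -> FounderProbTable:
    """Load and validate a genome cache directory written by save_genome_cache."""
    directory = Path(directory)
    meta_path = directory / "cache.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no cache.json in {directory}")
    meta = json.loads(meta_path.read_text())
    if list(meta["state_order"]) != list(STATE_LABELS):
        raise GenomeValidationError("cache state order differs from the package convention")
    strain_ids = [str(s) for s in meta["strain_ids"]]
    markers = MarkerMap(pd.read_csv(directory / "markers.csv", dtype={"chromosome": str}))
    n_loci = markers.n_loci
    probs = np.empty((len(strain_ids), n_loci, N_STATES))
    probs.fill(np.nan)
    locus_pos = {lid: i for i, lid in enumerate(markers.locus_ids)}
    strain_pos = {s: i for i, s in enumerate(strain_ids)}
    for chrom in meta["chromosomes"]:
        path = directory / f"chr{chrom}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing chromosome file {path.name}")
        df = pd.read_csv(path)
        vals = df[list(STATE_LABELS)].to_numpy(float)
        si = df["strain"].astype(str).map(strain_pos).to_numpy()
        li = df["locus_id"].map(locus_pos).to_numpy()
        if np.any(pd.isna(si)) or np.any(pd.isna(li)):
            raise GenomeValidationError(f"unknown strain or locus in {path.name}")
        probs[si.astype(int), li.astype(int), :] = vals
    if np.isnan(probs).any():
        raise GenomeValidationError("cache does not cover every strain x locus cell")
    return FounderProbTable(strain_ids=strain_ids, markers=markers, probs=probs)


# ---------------------------------------------------------------------------
# Adjacent-interval reduction
# ---------------------------------------------------------------------------


def reduce_adjacent_loci(
    table: FounderProbTable,
    threshold: float = 0.10,
    policy: str = "run-average",
    return_provenance: bool = False,
):
    """Merge adjacent intervals whose diplotype probabilities nearly coincide.

    Scanning left to right within each chromosome, an interval joins the
    current run when, for *every* strain, the L2 distance between its
    36-vector and the run's comparison vector is below
    ``threshold * MAX_L2_NORM`` (default absolute threshold 0.2).  Merged
    intervals get the mean probability vector (renormalized) and the mean
    position.  Runs never span chromosome boundaries.

    policy:
      "run-average"  - compare against the running mean of the current run
      "adjacent-pair"- compare against the previous interval only

    Returns the reduced table, plus a provenance DataFrame (merged locus id,
    source locus ids) when return_provenance is True.
    """
    if table.n_loci == 0:
        raise GenomeValidationError("cannot reduce an empty table")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be a fraction in (0, 1)")
    if policy not in ("run-average", "adjacent-pair"):
        raise ValueError(f"unknown reduction policy {policy!r}")
    abs_thr = threshold * MAX_L2_NORM

    chroms = table.markers.chromosomes
    positions = table.markers.positions_mb
    locus_ids = table.markers.locus_ids

    runs: list[list[int]] = []
    for chrom in table.markers.chromosome_labels():
        idx = np.flatnonzero(chroms == chrom)
        run: list[int] = [int(idx[0])]
        run_sum = table.probs[:, idx[0], :].copy()
        for l in idx[1:]:
            if policy == "run-average":
                ref = run_sum / len(run)
            else:
                ref = table.probs[:, run[-1], :]
            d = np.linalg.norm(table.probs[:, l, :] - ref, axis=1)
            if np.all(d < abs_thr):
                run.append(int(l))
                run_sum += table.probs[:, l, :]
            else:
                runs.append(run)
                run = [int(l)]
                run_sum = table.probs[:, l, :].copy()
        runs.append(run)

    new_probs = np.empty((table.n_strains, len(runs), N_STATES))
    rows = []
    for j, run in enumerate(runs):
        block = table.probs[:, run, :].mean(axis=1)
        block = np.clip(block, 0.0, None)
        block /= block.sum(axis=1, keepdims=True)
        new_probs[:, j, :] = block
        rows.append(
            {
                "locus_id": locus_ids[run[0]] if len(run) == 1 else f"{locus_ids[run[0]]}+{len(run) - 1}",
                "chromosome": chroms[run[0]],
                "position_mb": float(np.mean(positions[run])),
            }
        )
    reduced = FounderProbTable(
        strain_ids=list(table.strain_ids),
        markers=MarkerMap(pd.DataFrame(rows)),
        probs=new_probs,
    )
    if not return_provenance:
        return reduced
    prov = pd.DataFrame(
        {
            "merged_locus_id": [rows[j]["locus_id"] for j in range(len(runs))],
            "source_locus_ids": [";".join(locus_ids[r] for r in run) for run in runs],
            "n_source": [len(run) for run in runs],
        }
    )
    return reduced, prov


# ---------------------------------------------------------------------------
# Dosages, hard calls, kinship
# ---------------------------------------------------------------------------


def haplotype_dosage(table: FounderProbTable, locus: int | str) -> np.ndarray:
    """Expected founder-haplotype dosages (strains x 8) at one locus: P @ A."""
    l = table.markers.index_of(locus)
    return table.probs[:, l, :] @ ADDITIVE_MATRIX


def haplotype_dosages(table: FounderProbTable) -> np.ndarray:
    """Expected dosages at every locus: (strains, loci, 8)."""
    return table.probs @ ADDITIVE_MATRIX


def hard_call_diplotypes(table: FounderProbTable) -> np.ndarray:
    """Most probable diplotype state per strain/locus as integer state codes.

    Ties resolve to the lowest state index (argmax convention).  Use
    diplotype_incidence for the one-hot incidence matrix at a single locus.
    """
    return np.argmax(table.probs, axis=2)


def diplotype_incidence(table: FounderProbTable, locus: int | str) -> np.ndarray:
    """One-hot hard-call incidence matrix D (strains x 36) at one locus."""
    l = table.markers.index_of(locus)
    calls = np.argmax(table.probs[:, l, :], axis=1)
    D = np.zeros((table.n_strains, N_STATES))
    D[np.arange(table.n_strains), calls] = 1.0
    return D


@dataclass
class KinshipMatrix:
    """Strain x strain realized genetic relationship matrix."""

    matrix: np.ndarray
    strain_ids: list[str]
    normalization: str = "mean haplotype-share inner product across loci"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.strain_ids)
        if self.matrix.shape != (n, n):
            raise GenomeValidationError("kinship shape mismatch with strain list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise GenomeValidationError("kinship not symmetric")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)


def compute_kinship(table: FounderProbTable) -> KinshipMatrix:
    """Realized kinship from founder mosaic probabilities.

    K_ij = (1/L) sum_l <f_il, f_jl>, where f_il is the 8-vector of haplotype
    probability shares (expected dosage / 2) of strain i at locus l.  For a
    fully inbred strain with certain assignments, K_ii = 1.
    """
    shares = haplotype_dosages(table) / 2.0  # (n, L, 8)
    n, L, _ = shares.shape
    flat = shares.reshape(n, L * N_FOUNDERS)
    K = (flat @ flat.T) / L
    K = (K + K.T) / 2.0
    return KinshipMatrix(matrix=K, strain_ids=list(table.strain_ids))


def balanced_kinship(K: KinshipMatrix) -> KinshipMatrix:
    """Idealized equal-relatedness kinship: every off-diagonal replaced by
    the mean realized off-diagonal; diagonal preserved."""
    M = K.matrix.copy()
    n = M.shape[0]
    off = ~np.eye(n, dtype=bool)
    M[off] = M[off].mean()
    return KinshipMatrix(
        matrix=M, strain_ids=list(K.strain_ids), normalization=K.normalization + " (balanced)"
    )


def pcs_for_variance(K: KinshipMatrix, fraction: float = 0.95) -> int:
    """Smallest number of principal components of K explaining >= fraction
    of the total (nonnegative) eigenvalue mass."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    w = np.linalg.eigvalsh(K.matrix)
    w = np.clip(w, 0.0, None)[::-1]
    total = w.sum()
    if total <= 0:
        return 0
    cum = np.cumsum(w) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)
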