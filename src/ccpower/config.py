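"""Experiment configuration, orchestration, and results serialization.

A single YAML file specifies the genome source (a cache directory or a
synthetic-panel recipe), the simulation grid, and the Monte Carlo budget.
run_from_config executes the requested experiment and writes a results
directory containing the summary table, per-simulation outcome log, an
echo of the configuration, and a machine-readable provenance record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (
    GridSetting,
    outcomes_to_frame,
    run_power_grid,
    structured_null_experiment,
    beavis_experiment,
    summaries_to_frame,
)
from .genome import FounderProbTable, compute_kinship, load_genome_cache, reduce_adjacent_loci
from .synth import SyntheticGenomeConfig, simulate_ri_panel

log = logging.getLogger("ccpower")


class ConfigError(ValueError):
    """An experiment configuration field is invalid; message names the field."""


#: Default grids of the full-scale study design: strains 10-70 by 5 plus 72,
#: QTL effect sizes 1% and 5-95% by 5%, and 2/3/8 functional alleles, with
#: 1,000 simulations x 100 permutations at alpha 0.05.
FULL_STUDY_PRESET: dict = {
    "n_strains": list(range(10, 71, 5)) + [72],
    "h2_qtl": [0.01] + [round(x, 2) for x in np.arange(0.05, 0.951, 0.05)],
    "m_alleles": [2, 3, 8],
    "definition": "B",
    "h2_strain": 0.0,
    "replicates": 1,
    "n_sims": 1000,
    "n_perm": 100,
    "alpha": 0.05,
}


@dataclass
class ExperimentConfig:
    """Grid axes, Monte Carlo budget, genome source, and seeding."""

    experiment: str = "power"  # power | null | beavis
    genome_cache: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticGenomeConfig kwargs
    reduce_threshold: float | None = None

    n_strains: list = field(default_factory=lambda: [50])
    h2_qtl: list = field(default_factory=lambda: [0.5])
    m_alleles: list = field(default_factory=lambda: [8])
    definition: str = "B"
    h2_strain: float = 0.0
    h2_strain_grid: list = field(default_factory=lambda: [0.0, 0.5, 1.0])
    replicates: int = 1

    n_sims: int = 100
    n_perm: int = 100
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.experiment not in ("power", "null", "beavis"):
            raise ConfigError(f"experiment: unknown experiment {self.experiment!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha: must lie in (0, 1)")
        if self.n_sims < 1:
            raise ConfigError("n_sims: must be >= 1")
        if self.n_perm < 20:
            raise ConfigError("n_perm: must be >= 20")
        if self.replicates < 1:
            raise ConfigError("replicates: must be >= 1")
        if not 0.0 <= self.h2_strain <= 1.0:
            raise ConfigError("h2_strain: must lie in [0, 1]")
        for h2 in self.h2_qtl:
            if not 0.0 <= h2 <= 1.0:
                raise ConfigError(f"h2_qtl: value {h2} outside [0, 1]")
            if h2 + self.h2_strain > 1.0 + 1e-9:
                raise ConfigError(
                    f"h2_qtl: value {h2} plus h2_strain {self.h2_strain} exceeds 1"
                )
        for h2s in self.h2_strain_grid:
            if not 0.0 <= h2s <= 1.0:
                raise ConfigError(f"h2_strain_grid: value {h2s} outside [0, 1]")
        for m in self.m_alleles:
            if not 2 <= m <= 8:
                raise ConfigError(f"m_alleles: value {m} outside [2, 8]")
        for n in self.n_strains:
            if n < 2:
                raise ConfigError(f"n_strains: value {n} must be >= 2")
        if self.genome_cache is None and not self.synthetic:
            raise ConfigError("genome_cache/synthetic: one genome source is required")

    # -- YAML round-trip ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    # -- genome construction -------------------------------------------------

    def build_genome(self) -> FounderProbTable:
        if self.genome_cache is not None:
            table = load_genome_cache(self.genome_cache)
        else:
            table = simulate_ri_panel(SyntheticGenomeConfig(**self.synthetic))
        if self.reduce_threshold is not None:
            table = reduce_adjacent_loci(table, self.reduce_threshold)
        return table

    def grid(self) -> list[GridSetting]:
        return [
            GridSetting(
                n_strains=n, h2_qtl=h2, m_alleles=m, definition=self.definition,
                h2_strain=self.h2_strain, replicates=self.replicates,
            )
            for n in self.n_strains
            for h2 in self.h2_qtl
            for m in self.m_alleles
        ]


def _genome_checksum(table: FounderProbTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(table.probs).tobytes())
    h.update(",".join(table.strain_ids).encode())
    return h.hexdigest()


def run_from_config(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Execute the configured experiment and write the results directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = config.build_genome()
    log.info(
        "experiment=%s genome: %d strains x %d loci",
        config.experiment, table.n_strains, table.n_loci,
    )

    if config.experiment == "power":
        settings = config.grid()
        summaries, outcomes = run_power_grid(
            table, settings, n_sims=config.n_sims, n_perm=config.n_perm,
            alpha=config.alpha, seed=config.seed, return_outcomes=True,
        )
        summaries_to_frame(summaries).to_csv(outdir / "summary.csv", index=False)
        outcomes_to_frame(outcomes, settings).to_csv(outdir / "outcomes.csv", index=False)
    elif config.experiment == "null":
        K = compute_kinship(table)
        df = structured_null_experiment(
            table, K, config.h2_strain_grid, n_sims=config.n_sims,
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed,
        )
        df.to_csv(outdir / "summary.csv", index=False)
    else:  # beavis
        df = beavis_experiment(
            table, config.n_strains, config.h2_qtl, n_sims=config.n_sims,
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed,
        )
        df.to_csv(outdir / "summary.csv", index=False)

    config.to_yaml(outdir / "config_echo.yaml")
    provenance = {
        "package_version": __version__,
        "experiment": config.experiment,
        "seed": config.seed,
        "n_strains_panel": table.n_strains,
        "n_loci": table.n_loci,
        "genome_sha256": _genome_checksum(table),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    log.info("results written to %s", outdir)
    return outdir


def summarize_outcomes_file(outcomes_csv: str | Path) -> pd.DataFrame:
    """Re-aggregate a per-simulation outcome log into per-setting summaries;
    reproduces the original summary table exactly (pure aggregation)."""
    from .evaluate import DetectionOutcome, summarize_power

    df = pd.read_csv(outcomes_csv)
    setting_cols = ["n_strains", "h2_qtl", "m_alleles", "definition", "h2_strain", "replicates"]
    rows = []
    for key, grp in df.groupby(setting_cols, sort=False):
        outcomes = [
            DetectionOutcome(
                label=r.label, is_tp=bool(r.is_tp), is_fp=bool(r.is_fp),
                distance_mb=None if pd.isna(r.distance_mb) else float(r.distance_mb),
            )
            for r in grp.itertuples()
        ]
        setting = dict(zip(setting_cols, key))
        rows.append(summarize_power(outcomes, setting).to_row())
    return pd.DataFrame(rows)
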