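# ccpower

Simulation-based power analysis for QTL mapping in eight-founder
recombinant inbred (RI) panels such as the Collaborative Cross (CC).

Designing a CC mapping experiment means trading off the number of strains,
the number of replicates per strain, and assumptions about the QTL — its
effect size and how the eight founder haplotypes collapse into functional
alleles (the *allelic series*). `ccpower` answers those design questions by
simulating phenotypes directly on founder-haplotype mosaic genomes, mapping
each simulated trait exactly as an analyst would, and reporting detection
power, false positive rate, and localization accuracy.

## Model

Strain-mean phenotypes are generated from a single additive QTL plus
polygenic background and noise:

    y_bar = mu + X beta + u + eps_bar,        X = D A M

where `D` (n×36) is the hard-called diplotype incidence at the QTL, `A`
(36×8) maps diplotypes to founder dosages, and `M` (8×m) is the merge
matrix encoding the allelic series. Variance fractions `(h2_qtl, h2_strain,
sigma2)` sum to 1; residual variance on means is `sigma2 / r` for `r`
replicates. Allele effects are scaled under **Definition B** (`h2_qtl =
Var(2 beta)`, a balanced theoretical population), **MB** (`Var(2 M beta)`),
or **DAMB** (`Var(X beta)`, the realized mapping sample).

Mapping is Haley–Knott regression of strain means on the eight expected
haplotype dosages `P A` (an eight-allele model on the soft probabilities),
scored as `logP = -log10 p` from a rank-aware F-test against the
intercept-only model. Genome-wide thresholds come from 100 permutations of
the strain means with a generalized extreme value (GEV) fit to the
permutation maxima; the upper 5% quantile is the significance threshold. A
true positive is a significant locus within ±5 Mb of the simulated QTL; a
false positive is any significant locus on another chromosome.

The package also ships a synthetic CC-like genome generator (Markov founder
mosaics over 19 autosomes + X), realized-kinship population-structure
diagnostics, a structured-null experiment quantifying FPR inflation when
exchangeability fails, and a Beavis-effect (winner's curse) experiment. See
`docs/methods.md` for the full account.

## Worked example

Power to detect a bi-allelic QTL explaining 40% of phenotypic variance
(Definition B, one observation per strain) as the panel grows, on a
synthetic 50-strain, 1,800-locus genome with 200 simulations per setting
and 100 permutations each:

```python
import ccpower as cp

table = cp.simulate_ri_panel(cp.SyntheticGenomeConfig(n_strains=50, seed=11))
settings = [cp.GridSetting(n_strains=n, h2_qtl=0.4, m_alleles=2, definition="B")
            for n in (30, 40, 50)]
summaries = cp.run_power_grid(table, settings, n_sims=200, n_perm=100, seed=42)
print(cp.summaries_to_frame(summaries)[
    ["n_strains", "power", "power_lo", "power_hi", "fpr", "mean_loc_err_mb"]
])
```

```
 n_strains  power  power_lo  power_hi  fpr  mean_loc_err_mb
        30  0.030  0.012617  0.060783 0.07         2.375000
        40  0.155  0.109946  0.209950 0.07         1.303030
        50  0.295  0.235078  0.360806 0.05         1.147541
```

Reading the output: with 30 strains a 40% bi-allelic QTL (averaged over
uniformly sampled allelic series, including badly imbalanced ones) is
detected in only 3% of experiments; 50 strains raise that to ~30%
(Jeffreys 95% interval 0.24–0.36). The false positive rate stays near the
nominal 5% because the simulated strain effects are exchangeable. The
regularized mean distance between the detected peak and the simulated QTL
shrinks from ~2.4 Mb (prior-dominated: almost no detections at 30 strains)
to ~1.1 Mb at 50 strains.

The same pipeline is scriptable from the shell:

```sh
ccpower simulate-genomes --seed 3 --out cache/
ccpower run-power --config experiment.yaml --seed 3 --out results/
ccpower summarize --outcomes results/outcomes.csv --out resummary.csv
```

`ExperimentConfig` accepts either a genome cache directory (HAPPY-style
per-chromosome probability tables) or a synthetic-genome recipe;
`FULL_STUDY_PRESET` carries the full-scale grid (strains 10–70 by 5 plus
72, effect sizes 1–95%, 2/3/8 alleles, 1,000 simulations × 100
permutations per setting).

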