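# Methods

## Scope and model

`ccpower` estimates the power of QTL mapping experiments in eight-founder
recombinant inbred (RI) panels of the Collaborative Cross (CC) type, by
simulation. A panel is represented by founder-diplotype probabilities: at
each genomic interval every strain carries a 36-state distribution over the
unordered founder diplotypes (8 homozygous AA..HH, then the 28 heterozygous
pairs AB..GH in lexicographic order). The X chromosome is carried as an
ordinary chromosome throughout, the convention appropriate to an all-female
study design.

Strain-mean phenotypes for a single additive QTL are generated as

    y_bar = mu + X beta + u + eps_bar,        X = D A M,

where D is the hard-called (argmax, ties to the lowest state index)
diplotype incidence at the QTL, A the fixed 36x8 additive map from
diplotype to founder dosage, and M the 8xm merge matrix of the allelic
series (the partition of the 8 founders into m functional alleles). u is
the polygenic strain effect and eps_bar the residual on means, with
variance sigma^2 / r for r replicates — simulating at the strain-mean level
is exactly equivalent to simulating r individuals and averaging, and much
cheaper. mu is fixed at 0; any intercept is absorbed by the mapping model.

The three variance fractions (h2_qtl, h2_strain, sigma2) must sum to
exactly 1. beta, u and eps_bar are independent normal draws rescaled to
*population* variances (denominator N), so each draw's realized variance
decomposition matches the configured fractions to machine precision, not
just in expectation. The replicate-equivalence identity

    h2_eff = h2_qtl / (h2_qtl + h2_strain + sigma2 / r)

converts replicate designs to the equivalent single-observation design.

### Effect-size definitions

The scaling target of the allele effects beta is definition-dependent:

* **B** — h2_qtl = Var(2 beta): variance the QTL would explain in a
  theoretical population balanced in the functional alleles. Allele values
  are population-invariant; realized power then depends on allelic-series
  balance and founder representation.
* **MB** — h2_qtl = Var(2 M beta): balanced in the founders rather than in
  the alleles. Exposed for completeness, not used in default grids.
* **DAMB** — h2_qtl = Var(X beta) over the sampled strains: exactly the
  variance explained in the mapping sample (an R^2), so power is invariant
  to the allelic series by construction.

Under DAMB a locus monomorphic in the sampled strains admits no finite
scaling; this raises a degenerate-locus error and the experiment loop
resamples strains/locus/series, keeping a counter. Whether the hard-called
or probabilistic design should define the DAMB variance is a judgment call;
we pin the hard-called D (the same matrix that generates the phenotype) and
note the soft-probability alternative would differ only at uncertain loci.

## Mapping and thresholds

Mapping is Haley–Knott regression on strain means: at every locus the means
are regressed on an intercept plus the eight *expected* dosages P A from
the soft probabilities (an eight-allele model, since the true series is
unknown in practice), and compared with the intercept-only model by an
F-test, reported as logP = -log10 p, capped at 300. Simulation truth uses
hard calls D while mapping uses soft probabilities P, mirroring the
generative/analytic distinction above.

Dosage rows sum to 2, so the eight columns are always collinear with the
intercept; additionally a founder may be absent among the sampled strains.
Degrees of freedom therefore come from the numerical rank of the centered
dosage block at each locus (typically 7), computed by a rank-revealing SVD;
dependent directions are dropped. A constant phenotype or zero-rank locus
yields p = 1 (logP 0); an exact fit (residual sum of squares below 1e-12 of
the total) yields the cap.

Genome-wide significance is calibrated per simulated phenotype by
permutation of the strain-mean vector (valid under the exchangeability the
balanced RI design aims for): 100 permutation scans, each genome-wide
maximum logP recorded, a generalized extreme value (GEV) distribution
fitted to the maxima by maximum likelihood, and the upper-alpha (0.05)
quantile taken as the threshold. If the ML fit fails or returns a
non-finite quantile (e.g. near-constant maxima), the empirical (1-alpha)
quantile is used and flagged. The per-locus SVD bases are reused across
permutations, so a 100-permutation threshold costs one matrix product; the
batch path is contractually identical (to 1e-10) to scanning each permuted
vector independently, and tests enforce this.

## Detection and summaries

A simulation is a **true positive** when a significant locus lies within
±5 Mb of the simulated QTL (the window approximates a CC support interval);
a **false positive** when any locus on a different chromosome is
significant. Both can hold at once and are counted independently, each over
all simulations. A simulation whose only significant on-chromosome signal
falls outside the window is **disregarded** (neither TP nor FP) — this
slightly deflates FPR but avoids arbitrary edge rules.

Power and FPR are proportions with Jeffreys Beta(k+1/2, n-k+1/2) 95%
intervals (boundary convention: lower 0 at k=0, upper 1 at k=n). Location
error (distance from peak to simulated QTL, necessarily ≤ 5 Mb) is
regularized with pseudo-observations at the values a uniformly placed peak
would give: the mean with priors of 2.5 Mb, the 95% quantile with priors of
4.75 Mb. The pseudo-count is 1% of the simulation count (minimum 1), i.e.
10 for the reference 1,000-simulation setting; the quantile is computed on
the augmented sample.

## Structure diagnostics and experiments

The realized kinship is K_ij = (1/L) sum_l <f_il, f_jl> over haplotype
probability shares f = dosage/2, giving self-similarity 1 for a fully
inbred strain with certain assignments. The exact normalization of the
published CC relationship matrix is not fully specified, so this pinned
form may differ from it by an affine factor; the principal-component
diagnostic (smallest number of components explaining 95% of clipped
eigenvalue mass, compared between realized K and its "balanced" version
with all off-diagonals set to their mean) is unaffected by global scaling.

The **structured-null experiment** sets h2_qtl = 0 and draws u ~ N(0, K
h2_strain) (eigendecomposition square root, then exact population-variance
rescaling, which preserves correlation structure) while leaving the
exchangeability-assuming mapping protocol unchanged; any genome-wide
detection is a false positive. The **Beavis experiment** maps bi-allelic
DAMB QTL with r = 1 and no strain effect and, for detections within the
±5 Mb window, records the peak locus's eight-allele model R^2; the reported
inflation is the mean of R^2 / h2_qtl over detections only.

## Synthetic genomes

The generator emulates what matters for these analyses: founder mosaics
from a first-order Markov chain over founder labels (switch probability =
marker spacing / expected block length), near-complete homozygosity
(optional short residual heterozygous runs, default rate 0), and
optionally softened probabilities (a uniform smear of at most `softening`
mass off the true state — default off; 0.1 leaves ≥ 0.9 on the truth,
mimicking confident HMM output). Defaults are a desk-scale genome of 20
chromosomes (19 + "X") × 90 Mb at 1 Mb spacing (~1,800 intervals, roughly
a tenth of the ~17,900 reduced intervals of a realized CC cache) and an
expected block length of 18 Mb, chosen so a genome carries on the order of
120–140 recombination breakpoints, typical of realized CC strains. Strains
are generated i.i.d., hence exchangeable by construction.

The generator deliberately does **not** reproduce realized CC founder
imbalance, subspecies-related transmission distortion, breeding-funnel
relatedness, or locus-specific inference uncertainty. Consequently,
passing tests demonstrate correctness and calibration of the machinery
under the stated model — e.g. type-I error control under true
exchangeability — not quantitative power values for the realized CC, which
require the realized founder-probability cache as input.

## Adjacent-interval reduction

Mapping loci with near-identical descent is redundant, so adjacent
intervals are merged (per chromosome, greedy left-to-right run
accumulation) when, for every strain, the L2 distance between the interval
and the run's running mean stays below 10% of a maximum norm convention of
2 — i.e. absolute threshold 0.2. (For unit-sum probability vectors the
geometric maximum distance is sqrt(2) ≈ 1.414, not 2; the threshold is
kept at the conventional 0.2 regardless, and is configurable.) Merged
intervals take the mean probability vector (renormalized) and mean
position; a provenance table maps each merged interval to its sources. A
"adjacent-pair" comparison policy is exposed as an option since run
semantics admit either reading. Single-pass greedy merging is not exactly
idempotent on arbitrary diffuse probability tables (two run *means* can end
up closer than the threshold that separated their members); on mosaic-like
genomes — the intended input, where distances are either near 0 or near
sqrt(2) — a second pass is a no-op, and tests pin this.

## Numerical choices and reproducibility

* Probability rows must sum to 1 within 1e-6; rank tolerance for the locus
  SVD is max(n, 8)·eps relative to the leading singular value.
* p-values are floored at 1e-300 (logP cap 300).
* Every stochastic routine takes a seed or Generator; simulation s of grid
  setting g uses seed `base + 1_000_000·g + s`, so any single simulation
  is reproducible in isolation. Runs from a config file are byte-identical
  under a fixed (config, seed) pair.
* Scanner decompositions are cached per strain subset, so designs that use
  the whole panel pay the SVD cost once per genome.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on synthetic panels:
the calibration and structure experiments use a 50-strain, ~1,800-locus
genome with 500 simulations × 100 permutations, and the series-balance
contrast uses a 40-strain, 500-locus genome with 300 simulations per
series class — sizes chosen to give stable Monte-Carlo estimates on a
single CPU in minutes. The full-scale study grids (strains 10–70 by 5 plus
72; effect sizes 1% and 5–95%; 2/3/8 alleles; 1,000 simulations per
setting) ship as `FULL_STUDY_PRESET` and run unchanged, just longer.

## Known limitations

* Single additive QTL only: no epistasis, dominance deviations, covariates,
  batch effects, or variance heterogeneity.
* Fixed-effect mapping only; linear mixed models are out of scope (the
  permutation shortcut is incompatible with them), so the structured-null
  experiment quantifies the cost of ignoring structure rather than fixing it.
* No HMM inference of mosaics from genotypes: probabilities are consumed,
  not estimated, and no liftover between genome builds is attempted.
* Power numbers on synthetic panels characterize the method, not the
  realized CC; feed a realized cache through the same interfaces for
  strain-specific design work.
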