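# Methods

This note documents the models behind `polygs`, the defaults and why
they were chosen, the numerical choices, and what the synthetic data can
and cannot say about real breeding data.

## The breeding scheme being modelled

A recurrent-selection cycle in an outbreeding forage crop: several
hundred plants drawn from a handful of selected half-sib families are
intermated in a polycross; ~100 mother-plants provide open-pollinated
seed; each mother's half-sib family is sown as replicated sward plots
and phenotyped; the best families supply the next cycle's polycross
parents. Genotypes exist only for the mother-plants, phenotypes only for
their progeny families — so "accuracy" here is the rank correlation
between a mother's genomic prediction and her family's sward value, not
individual-level accuracy.

## Simulator

**Genome.** Seven chromosomes of 8/7 Morgans each (configurable),
markers placed uniformly at random (irregular spacing, like a real
consensus map), plus `n_qtl` QTL per trait at uniform positions. All
loci are carried in a single binary haplotype pair per individual;
genotype code = h1 + h2 − 1 ∈ {−1, 0, 1}.

**Meiosis.** Haldane model: per-chromosome crossover counts
Poisson(length in Morgans), positions uniform, no interference, free
assortment between chromosomes. Implemented as a vectorized batch over
gametes (crossover-count parity per locus), which keeps a full program
run in tens of seconds.

**Founders and LD.** Founder haplotypes start in linkage equilibrium
with per-locus allele frequencies uniform on [0.1, 0.9] and are
random-mated without selfing at census size `effective_size` for
`burn_in` generations. Drift then builds LD toward Sved's expectation
E[r²] ≈ 1/(4·Ne·c + 1). The approach rate at separation c is roughly
2c + 1/(2Ne) per generation, so the default `burn_in = 250` fully
equilibrates LD at adjacent-marker spacing (~0.5 cM for 1670 markers)
while very long-range LD remains slightly below equilibrium — immaterial
for every statistic computed here.

**Defaults.** `effective_size = 400` (between the program's 10 founders
and its 400–600 polycross parents, and inside the range implied by LD
observed in such programs), `polycross_size = 400`, `n_families = 5`,
`n_mothers = 100`, `progeny_per_family = 50`, `n_plots = 4`,
`n_qtl = 200` per trait (many small additive effects, N(0, 1/n_qtl)).
Eleven default traits carry target heritabilities between 0.14 and 0.35,
quality traits above yield traits. Under these defaults the emitted
generations show mean adjacent-marker r² ≈ 0.16 (band 0.12–0.22 across
seeds).

**Two lineages and the generation schedule.** The Intermediate
(F11–F14) and Late (F5) lineages are founded independently and drift
independently; that alone separates them on PC1 of the marker matrix.
Each *labeled* generation is an explicit selection cycle
(polycross → mothers → family phenotypes → select `n_families` best by
the index trait); the burn-in stands in for the unobserved earlier
cycles. Running all historical cycles explicitly would stack a
4–6-family maternal bottleneck (per-cycle Ne ≈ 4·n_families ≈ 20)
fourteen times and drive adjacent-marker LD toward ~0.7, far above what
real programs of this design show, so the burn-in representation is
both cheaper and more faithful. `paper_shape_config()` sets the
per-generation mother counts 119/86/54/100 (F11–F14) and 105 (F5) so
the composed training sets reach 54/259/364.

**Phenotypes and heritability calibration.** A family's genetic value is
the mean breeding value of `progeny_per_family` simulated half-sib
progeny (paternal gametes from the polycross pollen pool, no selfing).
Each plot adds independent Gaussian noise; the plot variance is solved
analytically as σ²_p = s²_G·(1 − h²)/h² from the realized variance
s²_G of family genetic means, so the plot-level one-way-ANOVA
heritability equals the target in expectation — no iteration, no
feedback from the estimator. A target of h² = 0 emits pure noise (the
calibration diverges there); a fixed `env_variance = 0` reproduces the
family genetic mean exactly. The family-mean table (one record per
mother × trait) is the pipeline's currency; the plot-level table feeds
heritability estimation, which needs within-family replicates.

## Statistics

**Heritability.** One-way ANOVA over families; σ²_E = within-family mean
square, σ²_G = (MS_between − MS_within)/n0 with the unbalanced-design
coefficient n0 = (N − Σn_i²/N)/(k − 1); negative σ²_G clamped to 0, so
H² ∈ [0, 1] (with H² = 1 when the within mean square is exactly 0 and
the between is not). The jackknife SD deletes one *observation* (plot)
at a time. Degenerate inputs (one family, all-singleton families, a
degenerate leave-one-out subset) raise rather than guess.

**LD.** r² is the squared Pearson correlation of unphased −1/0/1 codes
(composite LD) — phase is unavailable for real mother-plants, and under
random mating this tracks gametic r². Monomorphic markers are excluded
with a count. Distances are cM everywhere at the interface; the Sved and
Me formulas take Morgans, so callers divide by 100 at that boundary.
The decay curve bins pairs (empty bins absent, never zero) and fits a
cubic smoothing spline with its penalty chosen by generalized
cross-validation, after averaging duplicate distances (count-weighted);
fewer than four distinct distances skips the spline.

A caution the package's own tests encode: the *mean* r² over adjacent
pairs is convex-biased upward when spacing is irregular (close pairs
dominate), so inverting Sved's relation on that mean underestimates Ne
badly. Evaluating the fitted decay curve at the mean adjacent spacing
and inverting that value recovers the configured Ne within ±30%.

**Design formulas.** Ne = (1/r² − 1)/(4c); Me = 2·Ne·L/ln(4·Ne·L);
expected accuracy r = √(N·h²/(N·h² + Me)) and its exact inverse
N = Me·r²/(h²·(1 − r²)). The worked chain at r² = 0.1, c = 0.003 M,
L = 8 M, h² = 0.4, target r² = 0.5 gives N ≈ 2974.5. Two caveats are
deliberately surfaced rather than patched: (i) an often-quoted companion
value Ne = 281 is not reproducible from those same inputs (they give
750); (ii) reading "accuracy ≈ 0.5" as r rather than r² (with Ne = 281)
would give N ≈ 412. The functions implement the formulas; both readings
can be computed, neither is hard-coded as truth.

## Prediction models

**RRBLUP.** y = 1μ + Zu + e with u ~ N(0, Iσ²_u), fitted on raw codes
(no centering — μ absorbs it). The REML log-likelihood is profiled over
λ = σ²_e/σ²_u using one eigendecomposition of ZZ′ and maximized by
golden-section search on log₁₀λ ∈ [−10, 10] (tol 1e−6); then
μ̂ is the GLS intercept and û = Z′(ZZ′ + λI)⁻¹(y − 1μ̂). The dual and
primal ridge forms agree to 1e−8 on random instances for n < M, n = M
and n > M; σ²_u = 0 is handled as the λ → ∞ limit (û = 0, predictions =
training mean). The marker-effect parameterization is used throughout
(numerically equivalent to kinship-matrix GBLUP).

**KNN.** Euclidean distance on imputed codes, prediction = mean
phenotype of the k nearest; ties at the k-th rank break by ascending
training index (stable sort), making predictions deterministic. k is
chosen by seeded 5-fold CV minimizing squared error over a
per-composition grid (1–10 for F13, 3–20 for INT, 4–26 for ALL);
CV-score ties break toward smaller k.

**RF / GBM.** scikit-learn adapters pinned at the evaluated settings:
RF — 500 trees, ⅓ of features per split, ≥5 observations per leaf,
unpruned; GBM — 1500 trees, shrinkage 0.01, subsample 0.5, depth 5.
These are adapters on purpose: the object of study is their behavior at
stated settings, not tree internals. Genotypes enter all models as raw
−1/0/1 codes (no standardization).

## Evaluation pipeline

Phenotypes are standardized within each (generation, trait) group
(mean 0, variance 1 with ddof = 1); pooled groups therefore need not
have unit variance. Because standardization is per generation, test-
generation statistics never touch the training data. The test
generation (F14) may not appear in any training spec (guarded). A failed
cell is logged and reported missing. Everything is deterministic under
(inputs, seed); the CLI writes a JSON manifest (config hash, seed,
versions) next to its tables.

## Problem sizes used in the tests

The shipped test-suite experiments run scaled-down configurations chosen
to keep the whole suite in a couple of minutes while leaving each effect
detectable: Ne recovery uses 2 × 1 M chromosomes, 300 markers, Ne = 100,
burn-in 250, 50 replicates; heritability recovery uses 100 families × 4
plots × 200 replicates at h² ∈ {0.1, 0.4, 0.6}; the accuracy-vs-formula
check uses 400 markers on 2 M, Ne = 100, N = 150, h² = 0.5, 50
replicates (marker density per Morgan comparable to the full program);
the lineage/heritability-ordering checks use 30 replicate two-lineage
programs with 250 markers.

## Limitations

* Traits are purely additive; dominance, epistasis and G×E are out of
  scope, so the ML methods are benchmarked on terrain that favors BLUP.
* Seed yield, winter survival and disease — the auxiliary selection
  criteria of real programs — are not modelled; cycle selection uses a
  single index trait (or random selection when disabled).
* The simulator reproduces drift, structure and half-sib covariance,
  not real-data artifacts: marker ascertainment, genotype-call error,
  NIRS measurement structure, or normalization against control
  varieties. Passing tests therefore validate the machinery and the
  qualitative findings, not any particular published accuracy table.
* Founder allele frequencies are uniform; site-frequency-spectrum
  realism is not attempted.
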