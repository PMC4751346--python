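# polygs

Genomic selection evaluation for polycross recurrent-selection breeding
programs, modelled on perennial ryegrass (*Lolium perenne* L.).

Outbreeding forage crops are improved by recurrent selection: a
polycross of 400–600 plants from a few half-sib families, ~100
mother-plants whose open-pollinated progeny are evaluated as replicated
sward plots, and family selection into the next cycle. Genomic selection
promises to shorten this cycle by predicting each mother's merit from
genome-wide SNP markers. `polygs` provides the full toolchain for
studying that design:

* **I/O** for −1/0/1 SNP genotype tables (native and PLINK additive
  dialects), genetic maps (7 chromosomes, cM) and long-format phenotypes,
  with marker-mean imputation and PCA structure diagnostics;
* a **breeding-program simulator**: drift-equilibrated founders, Haldane
  meiosis, two independently founded lineages, polycross cycles and
  half-sib family sward phenotypes with calibrated heritability;
* **quantitative/population genetics**: broad-sense heritability
  H² = σ²_G/(σ²_G + σ²_E) from one-way ANOVA of family plots with
  jackknife SDs; pairwise LD (r²) against the map with binned decay
  curves and a GCV cubic smoothing spline; the design chain
  r² = 1/(4·Ne·c + 1)  →  Me = 2·Ne·L / ln(4·Ne·L)  →
  r² = N·h²/(N·h² + Me);
* **prediction engines**: RRBLUP (y = 1μ + Zu + e, u ~ N(0, Iσ²_u))
  with REML variance components via the spectral decomposition of ZZ′,
  KNN regression with cross-validated k, and random-forest /
  gradient-boosting adapters at fixed, published-style hyperparameters;
* an **evaluation pipeline** that standardizes phenotypes per
  subpopulation, composes training sets across generations (F13,
  INT = F11+F12+F13, ALL = INT+F5), predicts a held-out generation
  (F14) and reports Spearman rank-correlation accuracies per
  (training set × trait × method).

## Worked example

`examples/01_design_formulas.py` sizes a training population from
observed LD:

```
effective population size Ne     = 750.0
effective genome segments Me     = 1189.8
required training individuals N  = 2974.5
sanity: accuracy at that N       = 0.7071
```

Mean adjacent-marker LD of r² = 0.1 at 0.003 Morgans implies Ne = 750;
an 8-Morgan genome then behaves like ~1190 independent segments, and
reaching squared accuracy 0.5 for a h² = 0.4 trait with unrelated
individuals needs ~3000 training plants — far more than any single
generation of the program supplies, which is why relatedness between
training and test material carries the observed accuracies.

`examples/05_prediction_accuracy.py` runs the full matrix on a simulated
program at the genotyped mother counts (54/259/364 training plants):

```
== training set F13 (n = 54) ==
method       BLUP    KNN     RF    GBM best_method
trait
dmd         0.477  0.432  0.421  0.437        BLUP
vegyld_yr1  0.103  0.085  0.078 -0.001        BLUP
wsc         0.406  0.159  0.282  0.368        BLUP
```

Cells are Spearman correlations between predicted and observed F14
values: quality traits (dmd, wsc; higher h²) predict much better than
yield (vegyld), and BLUP usually leads — the qualitative pattern this
package is built to study. The other examples cover simulation
(`02`), heritability estimation (`03`) and LD decay / Ne recovery
(`04`).

A thin CLI mirrors the workflow: `polygs simulate`, `polygs h2`,
`polygs ld`, `polygs design`, `polygs evaluate` (see `polygs --help`);
all commands are byte-reproducible under a fixed `--seed`.

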