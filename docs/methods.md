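# Methods

This document describes the statistical models implemented in `hybridgs`,
the defaults chosen, the scope of the simulator, the numerical choices, and
the known limitations. Module references: `simcross` (simulator), `genio`
(marker I/O and QC), `kinship` (relationship matrices), `mm` (mixed
models), `gsmodels` (prediction models), `evalx` (cross-validation and
tests), `cdopt` (training-set optimisation), `cli` (command line).

## 1. Phenotypic model of the factorial trial series

A hybrid between a flint line *i* and a dent line *j*, observed in trial
*t*, is modelled as

```
y_ijt = mu + trial_t + GCAf_i + GCAd_j + SCA_ij
        + GCAfxE_it + GCAdxE_jt + SCAxE_ijt + e_ijt
```

with all genetic terms random and independent, and a **separate residual
variance per trial** (`e_ijt ~ N(0, sigma2_t)`), because partially
replicated unreplicated-checks layouts differ markedly in error variance
across environments. When the data contain several hybrid generations
(e.g. a first-cycle factorial G0R, selected-line hybrids G0S, new-cycle
hybrids G1), each generation receives its **own** GCAf/GCAd/SCA and
interaction components, since variances are not comparable across
generations that differ in selection history and allele frequencies.
Repeated control hybrids contribute to trial and residual estimation but
carry no random genetic effect (they are fixed entries), so they calibrate
the error model without inflating genetic variance.

Assumptions: hybrids are crosses of fully homozygous (DH) lines, so hybrid
dosage at a marker is the sum of one gamete from each parent; trials are
exchangeable environments (interactions are compound-symmetric); no
row/column spatial trend beyond optional block effects handled by
`mm.correct_spatial`.

Derived summaries (`mm.decompose_variance` returns both the component
table and a per-generation summary):

* `pct_sca = 100 * SCA / (GCAf + GCAd + SCA)` — the share of hybrid
  genetic variance not captured by parental averages (`mm.percent_sca`).
* Broad-sense heritability of a hybrid mean,
  `H2 = s_H / (s_H + s_HxE/n_site + s_E/(n_rep*n_site))`, with `s_H` the
  summed genetic variance, `s_HxE` the summed interaction variance, `s_E`
  the average residual variance, `n_site` the trial count and `n_rep` the
  average number of plots per hybrid and trial.

Hybrid least-squares means (`mm.ls_means`) are population-marginal means
from an OLS fit of hybrid + trial fixed effects; they are the single-value
inputs to all prediction models. Disconnected hybrid/trial designs raise
`NotEstimableError` rather than silently returning non-estimable means.

## 2. Prediction models

All models are two-stage: ls-means of the training hybrids as the
response, kernels as covariance structures, fitted by REML, hybrids
predicted as `mu + sum of kernel BLUPs`. Model codes:

| Code | Kernels |
|---|---|
| `PBLUP` | pedigree hybrid relationship (tabular method; DH diagonal = 2) |
| `GCA` | VanRaden additive kinship of flint parents + of dent parents |
| `GCA_SCA` | `GCA` + product SCA kernel `Kf ∘ Kd` on parent pairs |
| `GCA:A`, `GCA:AD` | gamete-origin additive kernels per parent group (identical structure to `GCA`/`GCA_SCA`; retained as separate codes to make the equivalence testable) |
| `GCA:A(AAdf)`, `GCA:AD(AAdf)`, `GCA:AD(AAf)(AAd)(AAdf)` | add epistatic additive×additive kernels within and between groups (`AAdf = Af ∘ Ad`) |
| `G:A`, `G:AD`, `G:A(AA)`, `G:AD(AA)` | genotypic models on the hybrid dosage matrix: additive `G_A` (VanRaden), dominance `G_D` with covariates `{−2q², 2pq, −2p²}` scaled by `Σ(2pq)²`, epistasis `G_AA = (G_A ∘ G_A)/mean diag` |

Structural identities hold exactly and are enforced by tests: `GCA` ≡
`GCA:A`, `GCA_SCA` ≡ `GCA:AD`, and the between-group dominance kernel of
the gamete-origin parameterisation equals `Af ∘ Ad`. `G:A` with a
pedigree kernel substituted for the genomic one reproduces `PBLUP`.

A tester-based model (`gsmodels`) supports topcross designs: candidate
lines crossed to one or two testers of the opposite group, predicting
candidate GCAs as `offset + gca` from the tester means.

Predicted genetic gain of a selection step is the mean true (or predicted)
value of the selected fraction minus the base population mean
(`evalx.genetic_gain`).

## 3. Cross-validation scenarios

* **Scenario 1** — random 4/5 train : 1/5 predict splits *within* one
  factorial; the default 100 repetitions give a Monte-Carlo SE of the mean
  ability well below typical model differences.
* **Scenario 2** — train on one factorial, predict a second factorial with
  partially overlapping parents (labels `T2/T1/T0` for hybrids with
  two/one/zero parents represented in training).
* **Scenario 3a** — predict the *next cycle*: train on the previous-cycle
  factorial plus `m` hybrids of the new cycle, for a grid of `m`; measures
  the value of early new-cycle phenotypes.

Predictive ability is `cor(predicted, ls-mean)` on the predicted set.
Model comparisons use paired t-tests over CV replicates with Bonferroni
correction; correlations sharing the observed vector are compared with
Williams' test, whose implementation is validated against a Monte-Carlo
null. Overlap between predicted-best and observed-best sets is summarised
as coincidence of selection (ties broken by id for determinism).

## 4. Training-set optimisation (CDmean)

For a candidate training set T and contrast matrix C (each row a hybrid
versus the population mean, built by `cdopt.build_contrasts`), the
coefficient of determination of a contrast `c` is

```
CD(c) = cᵀ (K − λ (ZᵀMZ + λK⁻¹)⁻¹) c / (cᵀ K c),   λ = (1−h²)/h²
```

the squared accuracy of the BLUP of that contrast given phenotypes on T
(`Z` the incidence of phenotypes on candidates, `M` the projector
absorbing the fixed intercept).
`optimize_trs` maximises the mean CD over contrasts by a greedy exchange
search with **random restarts**: from a random subset, single swaps are
accepted only on strict improvement; after `stop_after` consecutive
rejections the search restarts from a fresh random subset until the
proposal `budget` is spent, and the best subset over all restarts is
returned. Restarts are required because the single-swap neighbourhood has
genuine local optima even on small pools; with the default budget the
search recovers the exhaustively verified optimum in ≥95% of small random
instances (enforced by a test). The whole search is deterministic given
`CDmeanConfig.seed`. `evaluate_optimized_trs` compares strategies
(`cdmean1`, `cdmean2`, `random`) by realised predictive ability at fixed
training sizes.

## 5. Simulator scope

`simcross` generates a **two-cycle reciprocal DH breeding scheme** in two
heterotic groups:

1. Founders per group drawn with allele frequencies `Beta(2,2)` plus a
   divergence shift between groups (controls FST).
2. Biparental crosses; DH lines are produced by doubling one gamete of the
   (implicit) F1 — meiosis uses Poisson crossovers on a Haldane map (no
   interference), so dosages are 0/2 and DH pedigree diagonals equal 2.
3. A sparse incomplete factorial mates the groups; trait values come from
   additive + dominance QTL effects at marker positions, **calibrated
   exactly** so that the variances of line GCAs and pairwise SCAs over the
   full factorial grid hit the requested targets (the calibration is a
   closed-form scalar rescaling, not a stochastic fit).
4. Plot phenotypes follow the model of §1: augmented p-rep layout, every
   hybrid once per trial, controls twice per trial, a fraction of
   experimental hybrids replicated within trial, per-trial residual
   variances.
5. Truncation selection of the best lines per group (on true or on
   GCA-model-predicted GCA), intragroup crosses among the selected lines,
   a new DH generation, and a joint new-cycle factorial (G1 hybrids plus
   hybrids among the selected previous-cycle lines, G0S).

Default parameters and rationale:

| Parameter | Default | Why |
|---|---|---|
| genome | 10 chromosomes × 1.5 M, 482 markers | medium-density array scale |
| `lines_per_group_g0` | 822 | realistic first-cycle panel size |
| `hybrids_per_line_g0` | 1.2 | sparse factorial typical of hybrid programmes |
| variance `targets` | (0.44, 0.25, 0.19) | GCAf/GCAd/SCA of a moderately SCA-rich trait |
| trial interactions | 0.10/0.10/0.05, residual 0.5 | G×E smaller than main effects |
| `n_trials` | 8 | multi-environment series |
| `n_selected` | 30 per group, `n_intragroup_crosses` 40 | strong truncation as in recurrent selection |
| `lines_per_group_g1` | 351, `n_g0s_hybrids` 47 | second-cycle scale |
| `prep_fraction` | 0.15 | common p-rep replication rate |
| `select_on` | `"predicted_gca"` | selection as a breeder would do it; `"true_gca"` available for oracle studies |
| QC thresholds (`genio.qc_markers`) | missing > 20%, heterozygosity > 5%, MAF < 5% | standard array QC for inbred panels |
| CDmean `h2` | 0.7 (λ = 3/7) | average trait heritability |

Tests and documented examples use scaled-down scheme sizes (tens of lines,
4–6 trials); this is a package choice to keep the suite fast — the
defaults above remain the full-scale configuration.

## 6. Numerical choices

* REML uses average-information updates with step-halving on log-likelihood
  decrease and an EM fallback; components driven negative are pinned at
  zero and released only if their score turns positive ("pin at boundary,
  test the score"). Convergence on both log-likelihood (1e-8) and relative
  parameter change (1e-6), `max_iter = 1000`.
* Kinship matrices get a `1e-8` diagonal jitter before inversion/solves;
  symmetry is validated at `1e-10`.
* Missing dosages are mean-imputed per marker before VanRaden centring.
* CD is computed from the mixed-model-equation inverse block restricted to
  the candidate effects; a direct dense formulation is used since hybrid
  panels are small (≤ a few thousand).
* All stochastic code takes explicit seeds; internal child seeds are drawn
  as integers `< 2^31` so results are stable across platforms.

## 7. Known limitations

* **Next-cycle vs same-cycle ability ordering.** In the simulator, QTL are
  a subset of the genotyped markers, so marker–QTL linkage never decays
  across cycles; meanwhile truncation selection range-restricts the GCA
  variance among the selected lines. The net effect is that hybrids of the
  *new* cycle (G1) are typically predicted *better* than new hybrids among
  the *selected previous-cycle* lines (G0S) — the opposite of what is
  observed in real programmes, where imperfect marker–QTL LD erodes
  across-cycle accuracy. Reproducing the empirical ordering would require
  ungenotyped QTL in LD with markers; this is out of scope of the current
  generator and the corresponding acceptance test is expected to fail.
* **Topcross SCA leakage.** With only one or two testers, SCA deviations
  of candidate×tester pairs are not separable from candidate GCA; tester
  predictions are biased for traits with substantial SCA. This is a
  property of the design, not of the estimator.
* **No spatial field model.** Only block effects are supported; row-column
  or autoregressive spatial adjustment must be done upstream.
* **Compound-symmetric G×E.** Trial interactions share one variance per
  term; heterogeneous genetic covariances across environments (factor
  analytic structures) are not implemented.
* **Two-allele biallelic markers, two discrete cycles.** Multi-allelic
  markers, more than two recurrent cycles, and overlapping generations are
  outside the generator's scope.
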