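# Methods

## The statistical model

All three whole-genome regression models share one record-level linear
predictor: a phenotype record of accession *i* in trial *j*, maturity
group *k*, is

    y_ijk = mu + e_j + m_k(j) + g_i + eps_ijk,   eps IID N(0, sigma2_e).

Trial effects and maturity-group-within-trial effects are treated as fixed
(flat priors inside the Bayesian samplers, OLS in the adjustment step);
MG is nested within trial because maturity adaptation changes with trial
latitude.  An accession evaluated in several trials contributes several
records to a single genetic value `g_i` through an incidence mapping.
Lodging and shattering scores (1–5) can additionally enter as fixed
covariates when the goal is to strip their influence from machine-harvest
yield.

`g_i = sum_l x_il b_l` with allele dosages `x` in {0, 1, 2}.  Dosage
coding (not 0/1 presence) is required for the `2*theta_l` centering of the
relationship matrix to zero-mean the marker scores; for a fully inbred
collection dosages are effectively {0, 2}.

### G-BLUP

`g ~ N(0, G sigma2_g)` with the per-marker-standardized genomic
relationship matrix

    G_ii' = (1/p) sum_l (x_il - 2 theta_l)(x_i'l - 2 theta_l) / (2 theta_l (1 - theta_l)).

This per-marker standardization (not the pooled `sum 2 theta (1-theta)`
denominator) is deliberate.  Two consequences worth knowing:

* with in-sample allele frequencies, every row of G sums to zero — G is
  always singular, so the BLUP is computed inversion-free as
  `g_hat = sigma2_g K' V^{-1}(y - F beta)`, which reduces to
  `G (G + lambda I)^{-1} y_tilde` in the single-record case;
* for fully inbred lines the expected diagonal is `1 + F = 2`, so the
  per-accession genetic variance is `sigma2_g * mean(diag G)`.  The
  reported genomic heritability `h2_` therefore uses
  `sigma2_g * mean(diag G) / (sigma2_g * mean(diag G) + sigma2_e)`, which
  equals the familiar ratio for a unit-diagonal GRM and recovers the
  simulated heritability on inbred panels.

REML maximizes the restricted profile likelihood in the single ratio
`delta = sigma2_e / sigma2_g`.  The kernel `S(K+I)S` (S the
residual-forming matrix of the fixed design) is eigendecomposed once; the
`+I` offset cleanly separates the residual space from the fixed-effect
span, which matters at variance-component boundaries.  The profile is
scanned on a 61-point log grid over `delta` in `[1e-6, 1e6]` and refined
by bounded Brent search to `1e-8`.  Hitting the upper bound is the
infinite-shrinkage limit (`sigma2_g -> 0`) and is legal, not an error.

### Bayes B and Bayesian LASSO

Both are Gibbs samplers over (fixed effects, marker effects, variances),
sharing the variance-partition hyperparameter rule with prior trait
heritability `r2_prior = 0.5`:

* residual scale `S_e = var(y) (1 - R2) (df_e + 2)`, `df_e = 5`;
* Bayes B slab scale `S_b = var(y) R2 (df_b + 2) / ((1 - pi0) MSx)`,
  `df_b = 5`, with `MSx = sum_l 2 theta_l (1 - theta_l)`;
* LASSO regularization initialized at `lambda2 = 2 (1 - R2) MSx / R2`,
  with a Gamma hyperprior (shape 1.1) whose mode sits at that value.

Bayes B's inclusion indicators are sampled with the marker effect
integrated out (partially collapsed step), then the effect is drawn for
included markers; slab variances are scaled-inverse-chi-squared per
marker; the null proportion `pi` gets a beta prior parametrized by mean
`pi0 = 0.5` and concentration `p0 = 10` — the mean/concentration reading
of a `(p0, pi0)` beta specification, chosen because the conventional
shape/shape reading would put mass outside [0, 1] semantics.  The LASSO
uses the standard exponential-mixing representation; `1/tau2` draws are
inverse-Gaussian (numpy's Wald sampler).

Sampler defaults are 12,000 iterations, 2,000 burn-in, thinning 5.  The
sequential marker sweeps are numba-compiled; every random number is drawn
from one seeded numpy Generator outside the compiled kernels, so chains
are bit-reproducible.  Posterior means of linear quantities (g, b) are
accumulated as running sums; divergence (non-finite residual variance)
raises with the iteration index.

### Adjusted phenotypes and heritability

The "adjusted phenotype" `y_tilde = y - (fitted fixed part - mu)` keeps
the grand mean and removes trial/MG (and optional covariate) structure;
accession-level values are means of record-level `y_tilde`.  Sum-to-zero
constraints make the OLS parametrization full rank; only cell means are
identified, and downstream consumers use exactly those.  Entry-mean
broad-sense heritability for a replicated trial fits rep (fixed) +
accession (random) by the same REML machinery and reports
`H2 = s2_A / (s2_A + s2_e / r)` with `r` the harmonic-mean rep count.

## Cross-validation design

Groups are trials, states, or genetic clusters (argmax membership
assignment, ties to the lowest cluster index).  Schemes: One/Group
(leave-one-accession-out within group), One/All (same folds, training from
all groups), Group/All (leave-one-group-out), Group/Group (every ordered
train→validate pair).  Leave-one-accession-out is executed as
accession-level k-fold (default 10) because literal LOO at collection
scale means thousands of refits per scheme; `loo=True` restores the exact
design.  Fold assignment is seeded per group so One/All on a single group
reproduces One/Group exactly.

The leakage rule is absolute: all records of a validation accession are
removed from training in every fold, and each fold asserts the
training/validation accession sets are disjoint.  The CV evaluator uses
the two-stage path — fixed effects fitted on all records of the trait,
G-BLUP on accession-level adjusted means — with predictions never feeding
the adjustment; record-level joint fitting remains available on the
estimators via `accession_idx`/`fixed`.  Validation observations are
adjusted phenotypes aggregated per accession within the scored group.
Groups with fewer than 3 validation accessions report an undefined (NaN)
predictive ability rather than crashing.

Predictive ability is plain Pearson correlation (no heritability
correction, hence conservative).  Confidence intervals are percentile
bootstrap (10,000 paired resamples by default; degenerate resamples are
redrawn and counted).  Percentile rather than BCa: simpler, deterministic
given a seed, and adequate for correlation-scale quantities.

Selection enrichment selects the top `ceil(0.10 n)` accessions by
prediction (stable tie order) and reports the share observed above the
group mean and the share at or below the empirical 10th percentile
(type-7 quantile, ties included).  Enrichment is computed on raw (not
covariate-corrected) yield by default, since a breeder selecting for
machine-harvestable yield would not correct away shattering.

## The synthetic collection

The generator emulates the structure the analysis assumes, not any real
data set:

* **Genotypes** — ancestral frequencies Uniform(0.05, 0.95); cluster
  frequencies Balding–Nichols Beta with differentiation `fst = 0.15`
  across 9 clusters; Dirichlet admixture with a dominant home cluster
  (emitted as the membership table); fully inbred dosages {0, 2} with
  P(2) equal to the admixture-weighted frequency.  An outbred HWE mode
  exists solely for relationship-diagonal diagnostics.
* **Structure → maturity → trials** — maturity groups (10 levels)
  correlate with cluster through staggered latitude niches; 25 trials
  (default) split over 3 states whose MG bands overlap slightly, so no
  trial mixes the earliest and latest groups; 85% of accessions appear in
  one trial, 15% in two.
* **Phenotypes** — oil (mean 19%, SD 2, h2 0.7), protein (42%, SD 3,
  h2 0.7), yield potential (2.2 Mg/ha, SD 0.5, h2 0.35); trial effects
  SD 0.6, MG effects SD 0.4, G×E SD 0.35 (all in phenotypic-SD units),
  residual making the within-trial variance close.  h2 here is
  `var(g) / var(record - fixed part)`, so G×E counts as noise.  Marker
  effects are Gaussian over all markers (infinitesimal) or over `n_qtl`
  markers (sparse), scaled so `var(g)` hits the target; the stored truth
  satisfies `g = X b` exactly.
* **Lodging/shattering** — latent Gaussian scores with heritabilities
  0.75 and 0.85 (shattering is near-Mendelian in unimproved soybean
  landraces; this high heritability is what makes yield models partly
  "predict shattering", the mechanism the covariate correction exists
  for), discretized at equiprobable normal thresholds into 1–5.
  Machine-harvest yield subtracts `gamma_L (lodging - 1) +
  gamma_S (shattering - 1)` plus harvest noise.  The penalties are solved
  in closed form from the target pooled within-trial correlations
  (-0.21 lodging, -0.27 shattering): with 5 equiprobable classes
  Var(score) = 2, so `D = s0 / sqrt(1 - a^2 - b^2)` and
  `gamma = |target| D / sqrt(2)` where `s0` is the non-penalty
  within-trial SD.  No empirical tuning is involved.

What the generator does **not** emulate: linkage disequilibrium (markers
are exchangeable given cluster frequencies), pedigree structure within
clusters, multi-year trial repetition, spatial field trends, genetic
correlation between yield and the scores beyond the mechanical penalty,
and selection history.  Passing tests therefore demonstrate correctness
of the machinery and the qualitative training-set-design phenomena, not
real-data effect sizes; in particular, predictive abilities on synthetic
data need not match any published magnitude.

## Numerical choices and degenerate inputs

* QC boundaries are literal: remove when missingness is strictly greater
  than 0.80 or MAF strictly below 0.01; markers exactly at the thresholds
  stay.  All-missing markers are always removed.  Mean imputation
  (`2 theta_l`) preserves allele frequencies exactly; theta is frozen
  after imputation so one frequency definition feeds the GRM.
* Fixed markers (`theta` in {0, 1}) make the GRM denominator zero and
  raise, naming the marker — they should have been MAF-filtered.
* Problem sizes in the test and acceptance runs (hundreds to ~1,600
  accessions, 500–1,000 markers, 6–12 trials) are deliberate desk-scale
  stand-ins for the collection-scale analysis; every quantity reported is
  computed at those sizes.
* Per-trial covariate-correction percentages are intrinsically noisy
  (they are ratios of correlated correlation estimates); only the mean
  across a dozen trials is directionally stable, which is how it is
  evaluated.

## Known limitations

* The CV evaluator adjusts validation phenotypes with fixed effects
  estimated from *all* records (the natural reading of adjusting
  observations as preprocessing); a training-only adjustment variant
  would require per-fold designs and is not implemented.
* Bayes A / Bayes C and multi-kernel or G×E interaction models are out of
  scope, as are LD pruning, Hardy–Weinberg filtering and haplotype-aware
  imputation.
* The samplers are single-chain; convergence diagnostics are limited to
  variance-component traces.
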