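# Methods

## Scope

`mrpsup` implements a complete inference pipeline for estimating population
attitudes from non-representative survey samples: multilevel regression and
poststratification (MRP) for ordinal and categorical outcomes, a
within-subject probability-of-superiority (PSup) estimand with three
estimators, ROPE-based decision rules with graded effect-size thresholds,
pair-swap permutation tests with a cumulative c-value budget for small
fixed samples, and simulation-based calibration of both decision layers.
A synthetic-data module supplies a ground-truth population, selection-biased
samples, and exact closed-form oracles, so the whole pipeline runs and is
validated without any external data.

## Models

**Cumulative ordinal probit.** A K-point Likert response arises from a
latent normal variable crossed against K−1 ordered cutpoints:
P(y ≤ k) = Φ(c_k − η), with linear predictor

η = β_sex·sex + β_region·region + β_h·z(state hesitancy)
  + u_age + u_edu + u_inc + u_race + u_party + u_state
  + u_sex×race + u_edu×age,

where each varying-intercept term u_g has levels drawn N(0, σ_g²). The
latent residual scale is fixed at 1 (probit identification); there is no
global intercept, its role being absorbed by the cutpoints. Categorical
fixed effects are reference-coded (first declared level).

**Categorical logit.** For 2–3 unordered categories, per-category linear
predictors with the same structure plus an explicit intercept; the first
category is the fixed reference (all coefficients zero) and probabilities
are the softmax.

**Priors** (configurable via `PriorSpec`): fixed effects normal(0, 2);
cutpoints and categorical intercepts normal(0, 4); group standard
deviations half-normal(1). These are conventional weakly informative
choices for probit/logit scales; the wide normal(0, 4) on
cutpoints/intercepts accommodates items with extremely skewed response
distributions (nearly empty outer categories) without constraining
between-item comparisons.

## Sampling

Both families are fitted by exact MCMC written for this package
(`mrpsup._gibbs`, `mrpsup._pg`):

* **Ordinal probit** — Albert–Chib data augmentation: truncated-normal
  latents given cutpoints and coefficients; one joint conjugate Gaussian
  update for all coefficients (fixed effects and every group level at
  once, prior precisions per block); slice sampling of each log group sd;
  and Metropolis updates of the cutpoints on the
  (first cutpoint, log-spacings) transform with the latents integrated
  out, step size adapted toward ~30% acceptance during warmup.
* **Categorical logit** — Pólya–Gamma augmentation per non-reference
  category: ω_i ~ PG(1, ψ_k − log Σ_{j≠k} e^{ψ_j}) makes the conditional
  for that category's coefficient vector Gaussian. PG(1, z) variates are
  drawn with Devroye's exact alternating-series rejection sampler,
  compiled with numba and seeded explicitly.

Two extra moves repair the slow directions of blocked Gibbs on these
models:

* **Recentring.** Adding δ_b to every effect of block b while shifting the
  cutpoints — and, crucially, the latent responses — by Σδ_b (ordinal), or
  shifting the intercept by −Σδ_b (categorical), leaves the augmented-model
  likelihood exactly invariant; the conditional for δ under the priors is
  a small multivariate Gaussian sampled exactly each iteration. Without
  this move the cutpoints and block means wander on the prior scale with
  extreme autocorrelation.
* **Interweaving (ASIS).** After the centered update of each σ_g, the
  non-centered conditional — holding u_g/σ_g fixed — is a positive
  truncated normal under the conditionally Gaussian likelihood (latent z,
  or the PG working response), and is redrawn exactly. This breaks the
  funnel between group sds and their effects when σ_g is near zero.

Defaults: 4 chains × 1000 post-warmup draws after 1000 warmup iterations;
convergence gate split-R̂ ≤ 1.01 over all monitored parameters (arviz),
raising a `ConvergenceError` unless `check_convergence=False`. Validation
fits in the test suite use 2 chains × 400–800 draws, which this sampler's
mixing makes sufficient for the quantities tested; the gate is relaxed
there because split-R̂ at such short chains is noisy. Divergence counts are
reported as zero — Gibbs kernels have no divergent transitions; the
cutpoint acceptance rate is recorded instead.

Kernel correctness is tested against independent oracles: posterior means
under near-flat priors versus maximum-likelihood ordered probit
(statsmodels `OrderedModel`) and multinomial logit (`MNLogit`), PG sampler
moments versus tanh(z/2)/(2z), and poststratified HDI coverage of
closed-form truths.

## Poststratification

Per posterior draw, every cell of the population cross-tabulation receives
predicted category probabilities; the population estimand is the
cell-count-weighted average. Estimands: category probabilities, mean
response, and the 3-category support collapse (1–3 oppose / 4 neutral /
5–7 support on 7-point items; the three anchor labels on each side of the
scale midpoint force this mapping). Levels declared (or present in the
table) but never observed in the sample receive effects drawn from
N(0, σ_g) per draw — standard partial-pooling prediction — deterministic
per (fit seed, level). The party extension splits each cell of a
party-less table across parties by posterior-mean party probabilities from
an auxiliary categorical fit; counts are conserved exactly because
probabilities sum to one. Posterior-mean (rather than per-draw) party
probabilities are used, so party-model uncertainty is not propagated into
the table — a deliberate simplification, as the table is treated as a
fixed weighting basis.

## PSup

PSup(A,B) = [#(a>b) + ½#(a=b)]/n in a sample. Ties always contribute ½, so
PSup(A,B) + PSup(B,A) = 1 exactly and .5 means equivalence. The population
version fits the derived greater/equal/less category (an MRP categorical
fit) and computes PSup = P(greater) + ½P(equal) per poststratified draw —
per draw, not on draw-averaged probabilities, so the HDI carries full
posterior uncertainty. The population-versus-fixed-sample version computes
Σ_{i>j} p_i q_j + ½Σ_i p_i q_i per draw of the population category
probabilities p against fixed empirical frequencies q; the fixed side is
never resampled, so the comparison is conditional on that specific sample.

## Decision rules

ROPE: .47–.53 by default; "reliable difference" iff the 95% HDI lies
entirely outside; graded flags at .53/.60/.67/.75 when the HDI lies
entirely beyond the threshold in the effect's direction (above t going up,
below 1−t going down).

Randomization test: each permutation independently swaps each respondent's
paired ratings with probability ½ (the full 2ⁿ sign-flip space);
extremeness is two-sided, |PSup − .5| ≥ |PSup_obs − .5|; the c-value is
the fraction of permutations at least as extreme. Two-sided extremeness is
used because comparisons are run in both directions with no directional
hypotheses. Budget selection sorts c-values ascending (ties broken by
label) and admits comparisons while the running sum of admitted c-values
stays ≤ 0.05; the selected set is always a prefix of the ascending order.
"Cumulative chance level" is interpreted as this running sum — the reading
under which the simulated expected false-positive percentage per set stays
below 5% (verified by `simulate_permutation_fdr`).

## Synthetic data

The generator emulates: (a) a census-style cross-tabulation over
sex × age band (5) × education (4) × income (6) × race (5) × state
(default 8 states in 4 regions, with a continuous per-state hesitancy rate
z-scored across states, sample sd); cell counts are one multinomial draw
over the full cross with mildly non-uniform independent marginals;
(b) party identification from a multinomial logit on demographics,
splitting each cell; (c) selection-biased sampling with inclusion
probability ∝ count × exp(additive per-level log-odds) — the simplest
mechanism that biases raw means while leaving MRP consistent, since
selection depends only on modeled cells; (d) ordinal responses from the
same latent-probit family the models assume, and paired items optionally
sharing a respondent intercept (latent correlation).
`true_population_value` computes category probabilities, mean response,
and paired PSup exactly by cell enumeration (Gauss–Hermite quadrature over
the shared intercept when present), serving as the recovery oracle.

What the generator does **not** emulate: real ACS margins or dependence
between demographic factors (marginals are independent), real
party–demographic correlations, item nonresponse mechanisms other than
MCAR, response styles (straight-lining, acquiescence), or model
misspecification — responses are generated from the fitted family. Passing
recovery tests therefore demonstrates correctness of the machinery, not
robustness of MRP to violated assumptions on real data.

## Calibration

Both supplementary-style assessments run under a null with exchangeable
items (shared respondent intercept sd 1, identical cutpoints at scaled
normal quantiles):

* **ROPE false-positive rate** — fraction of null comparisons whose 95%
  PSup HDI escapes the ROPE. Default fast path: conjugate Dirichlet(1,1,1)
  posterior over the greater/equal/less counts with 4000 draws — under the
  null the covariate structure is uninformative, and the full-MRP path
  (available behind `method="mrp"`) agrees within Monte-Carlo error on a
  reduced grid. At the public scale (500 replicates, n=1500, K=7) the rate
  is well below 1%. At tiny n (~10) the rate is small but not zero:
  extreme splits (e.g. 7 greater vs 1 less) can place the whole, wide HDI
  below .47.
* **Budget-rule false positives** — expected percentage of comparisons
  selected per null set (default 200 sets of 21 pairs from 7 items, n=20,
  K=5, 1000 permutations, budget .05); stays below 5%.

Replicate counts (500 / 200) are the package's standard desk-scale
settings, balancing Monte-Carlo error (binomial SE ≈ 0.4 percentage points
for the ROPE rate) against runtime of a few seconds.

## Numerical choices

* Truncated normals by inverse-CDF with clipping of the uniform into
  [1e-15, 1−1e-15], then clipping into the truncation interval; adequate
  for the |z| ≤ ~8 regimes these models visit.
* Ordinal likelihood for cutpoint Metropolis evaluated as
  log Φ(u) + log1p(−exp(logΦ(l) − logΦ(u))) for tail stability.
* HDIs via `arviz.hdi`; `summarize_posterior` requires ≥ 100 draws.
* c-value comparisons use a 1e-12 slack on ≥ so exact ties of the
  permutation statistic count as "as extreme".
* Cutpoint initialization at empirical-frequency probit quantiles with
  strictly-increasing repair; coefficient init 0; group sds init 0.5.
* Chain seeds derive from one `SeedSequence`; every public API that draws
  randomness takes an explicit seed.

## Known limitations

* Categorical fits support 2–3 categories (all the pipeline needs); the
  PG update loop would extend to more but is untested beyond 3.
* Party-extension uncertainty is not propagated (posterior-mean split).
* The personnel side is deliberately model-free (descriptive + permutation
  only); no sampling model is offered for convenience samples.
* No variational or frequentist fitting path; MCMC only.
* Real-data integration (the study deposit with real ACS/CES tables)
  requires downloading the deposit; the repository contains no survey
  data.
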