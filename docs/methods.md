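# Methods

## The growth model

Mean testicular length of animal *i* is the arithmetic mean of the left
and right testicle lengths in cm. It is modelled as normally distributed
around a logistic ("increment") growth curve in age:

    L_i ~ Normal(mu_i, sigma),    mu_i = alpha / (1 + exp(-beta (Age_i - gamma)))

* `alpha` — asymptotic maximum mean length (cm),
* `beta` — increment-rate parameter (per month),
* `gamma` — inflection age (months), the age at which `mu = alpha/2`,
* `sigma` — residual SD (cm), re-estimated per model variant.

Three nested mean structures are fitted: a constant mean (`null`,
parameters alpha and sigma), the curve above (`increment`), and a
body-condition variant (`increment_bcs`) in which the exponent is
multiplied by `BCS_i * delta`, so body condition rescales the increment
rate. In the BCS variant `beta` is not sampled: it is pinned at the
posterior mode of the `increment` fit (Gaussian KDE with Silverman
bandwidth, argmax on a 512-point grid over the pooled chains), and
alpha, gamma, delta and sigma are estimated. Note the identity
`exp(-b(A-g) * BCS * d)`: when `BCS * delta = 1` the variant reduces
exactly to the plain curve, which is asserted in tests.

### Priors

Priors are weakly informative boxes chosen to dominate the data scale of
an alpaca cohort (lengths of a few cm, ages of a few dozen months), all
overridable through `PriorSpec`:

| parameter | default prior      | rationale |
|-----------|--------------------|-----------|
| alpha     | Uniform(0, 20) cm  | an order of magnitude above any plausible testicle |
| beta      | Uniform(0, 1) /mo  | rates above 1/month would saturate within weeks |
| gamma     | Uniform(−50, 120) mo | covers inflections before birth through late maturity |
| delta     | Uniform(0, 5)      | BCS effects far beyond the observed range |
| sigma     | Half-Cauchy(1) cm  | heavy-tailed, weakly informative scale |

A `FixedPrior(value)` pins any parameter (used internally for the BCS
variant's beta, and in tests to fix sigma for conjugate checks).

### Sampler

Random-walk Metropolis with burn-in adaptation, frozen afterwards so the
retained draws come from a fixed kernel and detailed balance holds:

1. **First half of burn-in** — component-wise updates; each proposal
   scale is tuned every 50 iterations toward a 0.44 acceptance rate.
2. **Second half of burn-in** — joint multivariate-normal proposals with
   covariance `(2.38^2/d) * Cov(recent history)`, re-estimated every 200
   iterations, and a global scale factor tuned toward 0.234 acceptance.
3. **After burn-in** — the joint kernel is frozen; draws are retained
   with the configured thinning.

Positive parameters (alpha, beta, delta, sigma) are proposed on the log
scale with the Jacobian included in the target. This matters: the
posterior of the growth curve has a pronounced ridge — small beta trades
off against large alpha and shifted gamma — that is roughly linear in
log coordinates, and axis-aligned proposals alone mix poorly along it
(split R-hat around 1.5 in early experiments; about 1.01 with the joint
log-scale kernel).

Defaults are 3 chains of 20,000 iterations with 5,000 burn-in. Each
chain's RNG is seeded `(seed, chain_index)`, so results are a pure
function of data + config. Chain starts are data-informed but
overdispersed (e.g. alpha uniform over 0.5–1.5 times the maximum
observed length). Convergence is assessed by split R-hat per parameter;
any value above 1.1 sets `converged=False` on the result and emits a
warning — never silently ignored. Cohorts whose lengths are all
identical are rejected up front (sigma unidentifiable).

### DIC

Model comparison uses the classic deviance information criterion with
the posterior mean as plug-in point:

    D(theta) = -2 log L(theta),   p_D = mean(D) - D(theta_bar),
    DIC = mean(D) + p_D

`delta_dic` is reported relative to a reference fit (null for the
increment model, increment for the BCS variant), positive values
favouring the richer model. Caveat, stated rather than hidden: on
strongly ridged posteriors the posterior mean can fall off the ridge,
making `p_D` negative and DIC smaller than the mean deviance. This is a
known property of the plug-in penalty, not a sampler bug; the DIC
*ranking* of variants, which is what the analysis uses, is unaffected in
all simulation checks (the generating variant wins in 20/20 replicate
cohorts).

## The sperm-presence model

Binomial GLMs with logit link, one predictor at a time (mean length in
cm, or age in months), fitted by IRLS through statsmodels to tolerance
1e-12. Reported per fit: intercept/slope with standard errors from the
inverse observed information, the two-sided Wald p-value for the slope,
log-likelihood, `AIC = -2 loglik + 4`, and three pseudo-R² flavours
(McFadden, Nagelkerke, Tjur). All three are computed because "R²" for a
binomial GLM is ambiguous; Nagelkerke is treated as the headline value.
Predictors are compared by AIC (lower wins).

Quasi-complete separation is detected (statsmodels' separation warning,
a diverging |slope| > 50, or IRLS non-convergence) and flagged as
`converged=False`; prediction and threshold inversion refuse to operate
on such fits rather than emit garbage.

### Thresholds

The fitted length curve is inverted at p = 0.99 and p = 0.01:

    x(p) = (logit(p) - intercept) / slope

giving the length above which sperm production is near-certain and
below which it is near-impossible. Raw values satisfy
`predict(invert(p)) = p` to 1e-9; presentation rounds half-up to one
decimal. The point-estimate (MLE) curve defines the default thresholds;
an optional parametric bootstrap (default 2,000 seeded resamples from
the fitted probabilities, refit, invert) yields median-curve thresholds
with 95% percentile intervals. Both are reported when requested; neither
is privileged.

## Descriptive tables

Length bins <3 / 3–3.9 / >4 cm and age bins 12–23 / 24–35 / 36–48
months (on-farm scheme; the excised-organ scheme uses an open-ended
>36). All bins are half-open `[lo, hi)`, which resolves the ambiguity
the printed labels leave between 3.9 and 4.0 cm: 3.95 cm falls in
"3–3.9", exactly 4.0 cm in ">4". The on-farm scheme rejects ages below
12 months (outside its grid); the excised scheme tolerates them because
that cohort includes an 11-month-old. Percentages round half-up to whole
percent (1/6 → 17).

## The synthetic-cohort generator

No per-animal data accompany the study this package models, so the
generator emulates the two study designs from their published margins:

* **On-farm design** (default `experiment1_config`): n = 72 live
  animals, ages uniform on 13–48 months, BCS drawn from a discrete
  distribution over 2.5–5 centred on the observed median of 4, no sperm
  outcome. Calliper measurement through the scrotal layers is mimicked
  by adding 0.5 cm to both sides before averaging — the default offset
  motivated by the published difference in fitted asymptotes between
  live-animal and excised-organ cohorts (4.96 vs 4.43 cm).
* **Excised-organ design** (`experiment2_config`): n = 28 allocated
  exactly 22 castration / 6 necropsy by largest remainder plus a seeded
  shuffle, ages uniform on 11–113 months, no BCS, no offset, and a
  Bernoulli sperm outcome with logit-linear probability in mean length.

Generating parameter values are the published posterior medians of the
on-farm growth fit (alpha = 4.96 cm, beta = 0.078/month, gamma = 5.89
months). The residual SD is not reported anywhere; sigma = 0.3 cm is the
package default, consistent with the spread implied by the published
credible bands, and is an ordinary config knob. The generating logistic
is parameterized so that its true cut-offs are exactly the published
management thresholds: p = 0.99 at 3.8 cm and p = 0.01 at 1.6 cm
(slope = 2·ln 99 / 2.2 ≈ 4.18 per cm). Mean lengths are drawn
Normal(curve, sigma) floored at 0.1 cm; left/right asymmetry is a
mean-preserving ±d split (SD 0.1 cm) so the recorded mean is exactly the
drawn value. Ages are uniform because only a range and median were
published; the config accepts alternative setups.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: between-farm heterogeneity,
seasonality, measurement error beyond a single Gaussian residual,
age-BCS correlation, repeated measures on the same animal, and any
deviation of real growth from the logistic form. Recovery results
validate the estimation machinery under the assumed model, not the
biology.

**Fixtures.** `table_fixture("experiment1"/"experiment2")` are seed-free
cohorts whose binned counts equal the published tables cell for cell.
Within-bin values are frozen representatives: lengths 2.5 / 3.45 / 4.5
cm, ages 18 / 30 / 42 months (60 for the open-ended >36 bin), and for
the on-farm fixture a fixed BCS rotation over 3–4.5. Analyses run on
fixtures (e.g. the 4.3 / 1.5 cm thresholds in the README example) are
regression snapshots of those frozen values, not estimates of the
published quantities.

## Pipeline and reproducibility

`run_full_analysis` executes tabulation, the three growth fits (the BCS
variant only when every record carries a BCS), DIC deltas, the logistic
comparison and thresholds, skipping stages whose inputs are absent with
an explicit notice. A single master seed drives everything; per-stage
seeds derive from `SeedSequence([master, stage_index])` with a fixed
stage numbering so stages can be re-run in isolation. Reports serialize
to JSON byte-identically under the same inputs (wall-clock timings are
logged to stderr, deliberately kept out of the report). YAML configs use
a frozen schema; unknown keys are rejected.

## Problem sizes in tests and the acceptance script

Replicated studies use 20 cohorts of n = 72 (growth recovery, DIC
direction) or n = 200 (threshold recovery), with a 2-chain,
10,000-iteration, 3,000-burn-in sampler for the replicate fits — chosen
as the smallest configuration that passes convergence diagnostics on
these well-specified cohorts; single-fit examples use the production
default. The threshold-recovery study draws mean lengths uniformly over
0.5–5.5 cm rather than through the growth curve: an excised-organ age
range concentrates simulated lengths above 2.9 cm where sperm presence
is near-certain, leaving the lower threshold unidentifiable — a recovery
study must place observations across the probability transition it is
trying to recover.

## Known limitations

* DIC uses the posterior-mean plug-in; `p_D` can go negative on ridged
  posteriors (see above). WAIC/LOO are deliberately out of scope.
* Frequentist coverage of the 95% credible intervals hovers near but
  not exactly at nominal in 20-replicate batches (individual parameters
  occasionally dip to 80–85% for a given seed batch, and longer chains
  do not move them) — finite-sample behaviour of Bayesian intervals
  under box priors on a weakly identified curve, not a sampler defect.
* The BCS variant inherits a fixed beta from the increment fit; no
  uncertainty in beta propagates into its posterior.
* Separation-flagged logistic fits carry last-iteration estimates with
  meaningless standard errors; they are marked, not repaired (no
  penalized fallback such as Firth's correction is attempted).
* Thresholds extrapolate the logistic tail to p = 0.99/0.01; with few
  organs near the cut-offs their sampling variance is substantial, as
  the bootstrap intervals make visible.
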