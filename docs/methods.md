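# Methods

## Data model

The unit of analysis is a dose–response summary table: for each exposure
concentration (mg/L fluoride in water; 14 levels from 0 to 300 in the
bundled dataset) a replicate count `n`, a mean percent response `m` and a
sample SD `s` (denominator n−1). Endpoints are cumulative mortality at
1–5 dpf (cumulative dead ÷ total embryos) and the cumulative malformation
rate at 5 dpf (malformed ÷ hatched, replicates with zero hatched excluded
with a warning). The source table reports x̄ ± SD without the replicate
count; two plates per concentration in each of three independent experiments
makes n = 6 the default assumption, exposed as configuration and recorded in
every output manifest.

## Likelihood

Replicate responses within a dose group are modelled as lognormal around the
model curve with a common log-scale SD σ (a constant coefficient of
variation). The group sufficient statistics enter through matched moments:
μ̂ᵢ = log(mᵢ/√(1+cvᵢ²)), ŝᵢ² = log(1+cvᵢ²) with cvᵢ = sᵢ/mᵢ, and the
log-likelihood is the normal sufficient-statistic form on the log scale
(plus the log-response change-of-variable term, so values are comparable
across error models). Group means are floored at 0.25% before taking logs.

The constant-CV choice is not cosmetic: percent-incidence responses are
strictly positive and their spread grows with the mean until the 100%
ceiling, and the lognormal model is what reproduces the benchmark-dose
behaviour this package is designed to match. A constant-SD normal
likelihood, also in sufficient-statistic form and exactly equal to the sum
of per-replicate normal densities, is available with `likelihood="normal"`;
it weights the saturated high-dose groups as strongly as the tight low-dose
groups and yields benchmark concentrations roughly 40–60% higher on the
bundled data.

## Priors

All priors are scaled from the dataset, flat over bounded boxes unless
noted:

* `a` (background, %): flat on (0, 2·max mean]. An optional normal anchor
  at the observed control mean (`anchor_background=True`) is off by default.
* `b` (slope/steepness, units depend on model): positive — endpoints here
  increase with dose; upper bounds are generous multiples of the response
  scale (exponent models: 10 on the rescaled dose axis).
* `g` (shape exponent): flat on [1, 15]. The lower limit is the standard
  benchmark-dose restriction keeping the dose-0 slope finite; without it the
  power-type models chase supralinear low-dose spikes that drive the BMC to
  arbitrarily small values. `restrict_g_ge_1=False` restores (0, 15].
* `c`: exp4/exp5 plateau-to-background ratio, flat on (1, 20], with the
  joint support additionally truncated at plateau a·c ≤ cap (below). On
  endpoints without a visible plateau these models otherwise develop an
  unidentified b·(c−1) ridge (the curve degenerates toward the linear
  model) that no finite chain can traverse. hill/michaelis_menten
  half-saturation dose: flat on (0, 10] in rescaled dose units, i.e. up to
  10× the largest observed dose.
* σ: half-Cauchy with scale set to the typical within-group spread on the
  likelihood's own scale (mean log-scale SD, floored at 0.25, for
  lognormal; mean SD floored at 1% for normal).
* Joint support cap: the mean curve over the observed dose range must stay
  below 3× the largest observed mean, keeping prior-predictive curves on a
  sane percent scale while leaving room for mildly super-saturated
  exponential fits.

## Sampling

Adaptive random-walk Metropolis on unconstrained coordinates (logit for
boxes, log for σ), 30,000 iterations, one chain, warmup fraction 0.5, seed
65,323 by default; draws are bit-reproducible given the seed. Warmup adapts
a global step size (Robbins–Monro toward 25% acceptance) and the full
proposal covariance, re-accumulated in windows (restarts at 1/6, 1/3 and 1/2
of warmup) so that early transient draws do not pollute the final proposal.
After warmup the proposal is a frozen mixture: 85% random-walk steps plus
15% independence draws from a multivariate t (df 4) centred on the final
warmup window with 2× its covariance. The independence component matters
because several fits (exp5/hill on endpoints whose response rises in two
steps) have genuinely bimodal posteriors: a pure random walk hops between
modes too rarely for a stable split-chain R̂, and a Gaussian independence
proposal creates one-way trapdoors, while the t tails keep hops feasible in
both directions. The acceptance ratio uses the full mixture density, so
detailed balance holds exactly. Initial points are drawn from the prior
(biased toward the control mean for `a`), re-drawn up to 500 times until the
posterior density is finite.

## Diagnostics and gates

* **R̂**: split-chain potential scale reduction per parameter (a single
  chain is split into halves). Gate: R̂ ≤ 1.05.
* **Posterior predictive p-value**: the default realized discrepancy is the
  deviance (−2·log-likelihood) with replicate group means and SDs simulated
  from the fitted model per draw; PPP is the fraction of draws whose
  replicate deviance is at least the observed one. Gate: 0.05–0.95. A
  sharper mean-only χ² statistic (`statistic="mean_chisq"`) is provided for
  targeted lack-of-fit checks; it is deliberately not the gate, because
  group means in real incidence tables are overdispersed relative to the
  within-group SD under any smooth curve, and a gate based on it would
  reject every model wholesale rather than grade relative fit.
* **LOO**: leave-one-group-out elpd by Pareto-smoothed importance sampling
  (arviz), falling back to WAIC with a warning when any Pareto k exceeds
  0.7 — common with only 14 groups. When any model falls back, weights use
  WAIC for all models so the comparison is homogeneous.

## Benchmark quantities

Per draw, the BMC at BMR ε (default 0.10, relative increase over the model
background a) solves f(d) = a(1+ε), and the LC50/EC50 solves f(d) = 50 on
the absolute percent scale, by bisection on [0, 10× max dose] (80
iterations; every model is monotone under the positive-slope priors). Draws
whose curve cannot reach the target inside the bracket are recorded as
undefined and excluded from summaries, with a warning above 1%. Closed-form
inversions for all eight models are shipped alongside and used as
independent oracles in the tests. Absolute-change and SD-multiple BMR
variants are available through `BenchmarkConfig`. Summaries are the median
and the 5th/95th percentiles (linear interpolation between order
statistics); for the BMC these are reported as BMC/BMCL/BMCU, a two-sided
90% credible interval whose lower end matches the usual one-sided 95%
lower bound for empirical posterior quantiles.

## Model averaging

Weights are pseudo-Bayesian-model-averaging: w_m ∝ exp(elpd_m − max elpd),
computed by log-sum-exp, over the models that pass both gates (failing
models are excluded with a warning and weights renormalized; WAIC-based
weights available via configuration). The model-averaged BMC and LC50
distributions are mixture resamples: each of 15,000 mixture draws picks a
model with probability equal to its weight, then one of that model's defined
draws uniformly, from a seed derived independently of the MCMC streams. The
"average LC50" is the mixture median; the arithmetic mean of per-model
medians is also reported for comparison. Cross-species extrapolation
implements UFs_zebrafish = UFs_mammals / 10^mean(log10 LC50_fish / log10
LC50_mammal) and HBGV = NOAEL_humans / UFs_zebrafish.

## NOAEL/LOAEL

One-way ANOVA on the group sufficient statistics (exactly equal to the
raw-replicate ANOVA), then per-dose LSD comparisons against control using
the pooled MSE and error degrees of freedom, two-sided p < 0.05, flagged
only in the adverse (increasing) direction. LOAEL = smallest flagged dose;
NOAEL = largest dose below it. Non-monotone flag patterns are reported
as-is with a warning, and a cross-endpoint majority call summarizes the
per-endpoint LOAELs.

## Synthetic data

`simulate_summary` draws per-replicate responses Normal(f(d), σ) truncated
to [0, 100] and summarizes them — the bundled table's structure (14 doses
0–300 mg/L, n = 6, monotone trend, saturation at 100%). Truncation
introduces boundary bias near 0 and 100 by design; it mimics how percent
endpoints behave, and it means an unbounded truth (e.g. a steep linear
curve) is only the data-generating mean over the dose range where it stays
inside [0, 100] — validation designs should restrict doses accordingly.
`simulate_wells` generates well-level counts: 5 dpf deaths are
Binomial(40, f(d)/100 clamped to [0,1]) per replicate, death days follow a
severity-dependent geometric profile ((1−p)^(k−1), so an immediately lethal
dose kills on day 1 and mild doses spread deaths across days), hatching is
Binomial among survivors (default 0.95) and malformations Binomial among
hatched with the same curve. The generators emulate the statistical
structure the pipeline assumes — they contain no toxicokinetics, no
between-plate effects and no water-chemistry variation, so passing recovery
tests demonstrates correctness of the inference machinery, not realism of
the biology.

## Problem sizes used in the test suite

Table-reproduction checks run the full default configuration (eight models ×
six endpoints × 30,000 iterations, ≈ 2–3 minutes on one CPU). Simulation
studies (parameter/weight/benchmark recovery, PPP calibration) use 2,000 to
8,000 iterations per fit and 20 seeded replicates; at those sizes the
checked quantities are stable, and the reduced budgets keep the whole suite
within a coffee break.

## Known limitations

* The likelihood treats group summaries as lognormal; exact zeros are
  floored rather than modelled, and quantal (binomial) likelihoods with
  litter effects are out of scope.
* Benchmark and LC50 estimates are as good as the model average: weights
  depend on the elpd estimator (PSIS-LOO vs WAIC vs pseudo-marginal
  variants can reallocate weight among near-equivalent models, shifting the
  model-averaged BMCL where per-model estimates disagree).
* Predictions are not truncated at 100%, so fitted curves may exceed the
  ceiling near the top dose; the support cap bounds the excursion.
* Single-chain R̂ (split halves) cannot detect modes a chain never visits.
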