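# Methods

## Model

The population survival function is the two-component mixture

S_pop(t | x, z) = 1 − π(z) + π(z) S(t | x),

with logistic incidence π(z) = expit(γᵀz) (the probability of ever
experiencing the event) and log-normal latency
S(t | x) = 1 − Φ((ln t − βᵀx)/σ) (event timing among the susceptible).
An intercept is always included in both components; in the audit the
single covariate is the group indicator, entered in both components.

The observed-data log-likelihood for right-censored data (tᵢ, dᵢ) is

ℓ = Σᵢ dᵢ [ln π(zᵢ) + ln f(tᵢ|xᵢ)] + (1 − dᵢ) ln[1 − π(zᵢ) F(tᵢ|xᵢ)],

with f and F the log-normal density and CDF. A censored subject is
ambiguous — cured, or susceptible but not yet evented — and the second
term integrates over both, which is what lets the incidence stay
calibrated under administrative censoring.

### Estimation

Direct joint maximization over (γ, β, log σ), not EM: the problem is
low-dimensional and smooth, direct maximization gives simpler
convergence diagnostics, and the analytic gradient is cheap. Specifics:

- **Parameterization.** σ is optimized as log σ (unconstrained).
- **Initialization.** γ from a logistic fit of the ever/never event
  indicator; β from least squares of ln t on x among events; σ from the
  residual SD (floored at 0.05); plus 4 jittered restarts (N(0, 0.5)
  perturbations, seeded). The best of all starts is kept and every
  start's achieved log-likelihood is stored on the fit.
- **Optimizer.** L-BFGS-B with analytic gradient; ftol 1e-11, gtol
  1e-6, max 500 iterations per start. Bootstrap refits may warm-start
  from the full-data optimum (single start, gtol 1e-5).
- **Numerical guards.** Censored terms are computed as
  log1p(−π F) with π F clipped below 1 − 1e-12; per-subject
  log-likelihoods are floored so any finite parameter vector gives a
  finite objective. Probabilities pass through `log_expit` / `ndtr`.
- **Uncertainty.** The covariance is the inverse of a central-difference
  Hessian of −ℓ at the optimum; the percentile bootstrap is the primary
  uncertainty tool for predicted probabilities.
- **Degenerate data.** Zero events (incidence unidentifiable) or zero
  censored rows (cure fraction unidentifiable) raise
  `DegenerateDataError`. Non-convergence is reported via
  `converged=False`, and `predict_incidence` refuses such fits.
- **Identifiability warning.** When the maximum observed time is below
  the fitted latency median, a log warning notes that the cure fraction
  and late survival are weakly separated (see "Known limitations").

## Comparators

The ever/never logistic model, Cox PH and log-normal AFT are delegated
to statsmodels and lifelines; the contract is the predicted-probability
surface `predict_diag_prob(fit, x, t_c)`:

- logistic: the fitted class probability (horizon-free by construction;
  the outcome is event-by-cutoff, i.e. computed after administrative
  censoring is applied). Separation is detected and flagged, never
  silently dropped.
- Cox: 1 − exp(−Λ₀(t_c) e^{βᵀx}) with the Breslow baseline; beyond the
  last event time the baseline is carried flat with a log notice.
  Breslow tie-handling (simulated continuous times make ties
  measure-zero).
- AFT: 1 − S(t_c | x) from the censored log-normal MLE with a common σ.
- mixture cure: π(z), independent of t_c.

Kaplan-Meier curves (lifelines) are used for descriptive stratified
survival and as the pragmatic benchmark for cohort-data runs.

## Synthetic data

### Cohort simulator (`simcohort`)

Defaults are the audited study conditions: n = 10 000 per replicate, 100
replicates, 50/50 groups, event (susceptible) rate 25% (low-rate preset
2.5%), group-1 median event time λ = 4 time units (years), group-2
median λ₂ swept upward from 4 (no timing difference) to 10, loss to
follow-up Uniform(0, 12), administrative cutoffs {4, 6, 8, 10, 12}.
Where the study design leaves a quantity open, it is fixed once here:

- **log-normal shape σ = 0.5** — a moderately skewed timing
  distribution whose group-1 inter-quartile range (≈ 2.9–5.6 years)
  brackets typical developmental-diagnosis ages; configurable.
- **censoring upper bound 12** — exceeds the largest median (10) so
  every scenario retains late follow-up; configurable.
- **cutoff grid {4, 6, 8, 10, 12}** — brackets both medians.
- **groups by deterministic interleaving** — exact group sizes remove
  one nuisance source of replicate variance; a Bernoulli mode exists.
- **RNG** — one root seed; replicate r uses the independent substream
  (seed, r) of NumPy's SeedSequence, so replicates are reproducible
  individually and in parallel.

Medians are exact by construction: the log-normal location is
μ_g = ln(median_g), since the median of LogNormal(μ, σ) is e^μ.
Cured subjects carry true_event_time = +∞ (empty field in CSV).

What the simulator does **not** emulate: covariate-dependent event
rates, informative or group-differential censoring, competing risks,
calendar-time effects, measurement error in event times. Passing tests
therefore show the estimators' behavior under clean timing-only
group differences, not performance on real claims data.

### Claims emulator (`claims_cohort`)

Structure-level emulation of an administrative claims database: births
uniform over one calendar year; enrollment spans beginning within 31
days of birth (3% injected violators) and continuing through 18 months
(zero gap tolerance; 3% early dropouts); the latent event process is
the cohort simulator's. True cases receive the phenotype's
`min_code_count` (default 2) qualifying codes starting at the simulated
diagnosis age with 7–90-day gaps, truncated at coverage end; non-cases
receive at most one noise code (rate 5%). Ages are (date − birth)/365.25
years. The shipped code list is a synthetic placeholder, not a published
phenotype. The latent truth table is retained, so the pipeline identity
(noise-free claims → exactly the latent case set) is testable.

## The audit

For each scenario × replicate × cutoff: generate, truncate, fit the
four models, and record each model's predicted diagnosis probability
per group at that cutoff, with truth = the configured event rate.
Summaries are per-cell means, biases, replicate SDs and the group-1 −
group-2 gap; distributions in the report panels are across replicates.
Failed fits are recorded with a reason and counted, never dropped.
Bootstrap CIs are unstratified subject resampling at full cohort size
with percentile 95% bounds (the simplest method consistent with
percentile reporting); a CI is flagged unreliable when > 20% of
resample fits fail.

Problem sizes: the default profile is 100 replicates of n = 10 000; the
fast profile (20 replicates of n = 2 000) is the package's desk-scale
setting used by the test suite and the acceptance script. Coverage
checks use 200 datasets of n = 1 000 with 200 resamples each.

## Known limitations

- **Weak identification under extreme truncation.** When a group's
  median event time lies far beyond the administrative cutoff (e.g.
  λ₂ = 10 observed only to t = 4 with uniform loss to follow-up),
  essentially no events from that group are observed and the likelihood
  cannot separate "small susceptible fraction" from "everyone
  susceptible but late": the MLE of that group's incidence becomes
  bimodal at the parameter-space boundaries and its replicate mean is
  not a meaningful location. The variance inflation shrinks with sample
  size and with later cutoffs; the identifiability warning fires in
  this regime. This is a property of the model/data combination, not of
  the optimizer (the achieved log-likelihood dominates the generating
  parameters' in such replicates).
- The latency is parametric; if the true timing distribution is far
  from log-normal the incidence estimate inherits misspecification.
- Percentile bootstrap intervals can undercover slightly at small n.
- The claims emulator has no code-set misclassification (wrong-code
  noise is sub-threshold by construction) and no re-enrollment gaps.
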