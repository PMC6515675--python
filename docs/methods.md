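# Methods

## Inference model

Both arms are modelled as independent Bernoulli processes for a binary
event observed 30 days after randomisation (death in the motivating
critical-care application; "treatment superior" means a *lower* event
rate).  Each arm's rate carries a `Beta(α₀, β₀)` prior, `Beta(1, 1)` by
default, i.e. every rate between 0 and 100% equally likely; priors are
configurable per arm.  Conjugacy gives the posterior `Beta(α₀ + d, β₀ + n −
d)` after `d` events among `n` analysed patients.

The decision quantity is `P(p_T < p_C | data)` for independent beta
posteriors.  It is computed:

* by a **closed-form finite sum** when a shape parameter is an integer
  (always true with integer priors), evaluated on the log scale;
* by **adaptive quadrature** of `E_C[F_T(y)]` otherwise, certified to an
  absolute tolerance (default `1e−8`); a quadrature whose error estimate
  exceeds the tolerance raises rather than returning a guess;
* a Monte-Carlo path exists only as an independent cross-check in tests.

The final success rule is *strict*: the trial is successful when the
posterior probability exceeds the threshold (default 0.975); equality does
not succeed.  The event is continuous, so ties have probability zero and
the choice only disambiguates the implementation.

The frequentist summaries mirror standard practice: relative risk
(treatment rate over control rate) with the log-normal (Katz) interval —
any zero cell raises instead of silently applying a continuity correction —
and the continuity-corrected (Fleiss / Casagrande–Pike–Smith)
two-proportion sample size with dropout inflation `n_cc / (1 − dropout)`
and a per-arm ceiling.  With a 45% control rate, 9% absolute reduction,
two-sided α = 0.05, 80% power and 3% dropout this yields 503 per arm (1006
total); the corrected size before inflation is 487.8 (488/arm at zero
dropout).

## Predictive probabilities and stopping rules

At a scheduled look, patients split into *complete* (outcome observed),
*in transit* (enrolled, inside the 30-day window or ultimately missing) and
*future* (not yet enrolled).  Posteriors are built from complete data only.

`P_curr` (success stopping) is the posterior predictive probability that
the final rule holds at the **current** sample size once every enrolled
patient reports: each draw samples `(p_C, p_T)` from the posteriors, then
binomial outcomes for the in-transit patients, and applies the final rule
at the current denominators.  `P_max` (futility stopping) additionally
allocates the remaining `n_max − randomised` patients between arms by a
deterministic largest-remainder split of the allocation ratio (odd patient
to control under 1:1) and tests the rule at the maximum sample size.
Sampling parameters before outcomes makes both quantities genuine
beta-binomial (posterior predictive) integrals, not plug-in binomials.

Dropout handling: in-transit patients are imputed as eventually observed —
they are already enrolled and being followed — while future patients are
first thinned by the anticipated dropout probability (default 3%,
mirroring its role in the sample-size inflation), so the projected final
denominators match the design's planning assumption.  Both behaviours are
switches (`dropout_in_transit`, `dropout`); the defaults are stated here
because the choice is genuinely open.

When at most 20 outcomes are outstanding (and dropout thinning plays no
role) Monte Carlo is replaced by exact enumeration of the per-arm
beta-binomial death totals.  Otherwise 10,000 imputation draws are used by
default; a seed is a mandatory argument everywhere in the API.

Decision precedence at a look: **futility before success** (`P_max < F_i`
tested first, then `P_curr > S_i` where success stopping is allowed).  A
trial that is predictively doomed at the maximum sample size should not be
declared an early success at the same look; the ordering matters only in
boundary cases, which is why it is stated prominently.

## Re-execution engine

A design is replayed over a patient stream in recruitment order.  The look
at recruit count `k` is anchored at the `k`-th patient's recruitment time;
outcomes are visible only if 30 days have elapsed by then (missing outcomes
never become visible).  Recruit-count triggers follow the stream order,
with ties broken by position.  On stopping — or on reaching the maximum
sample size — every randomised patient is followed to 30 days and the final
analysis uses all non-missing outcomes; dropouts are excluded, never
imputed, in final analyses.  A futility-stopped trial is unsuccessful
regardless of its final posterior (the follow-up completes, but accrual
ceased on the stop), and the accrual duration is the trigger patient's
recruitment time.  A stream that ends before the maximum sample size
without any stop raises a truncation error unless truncation is explicitly
allowed.

## Simulation and operating characteristics

Each replicate draws a fresh stream — exponential inter-arrival times at a
mean accrual rate (default 5.5 patients/week, no ramp-up), fair-coin 1:1
allocation, Bernoulli outcomes at the scenario rates, independent 3%
missingness fixed at generation time — and replays the design over it.
Dropouts count toward recruit triggers but never enter analyses.  Type I
error is the successful proportion under the equal-rates scenario; power
under the target-difference scenario.  Trial duration is the accrual end
plus follow-up, or the trigger time for futility stops (the trial is
assumed to cease immediately).

Randomness uses one spawned `SeedSequence` child per replicate, with the
stream and the analysis imputation on separate children: results are
reproducible, independent of evaluation order, identical across designs on
shared seeds (so unreachable-boundary designs reproduce the fixed design
bit-for-bit), and threshold-calibration grids reuse the same replicates
(common random numbers).

The final success rule over integer death counts is served from cached
cutoff curves: for fixed per-arm denominators the rule holds exactly when
the treatment death count is at or below a cutoff non-decreasing in the
control death count, so each curve is built lazily from the exact
probability (binary search plus monotone two-pointer scans) and every
subsequent evaluation is an array lookup.  This is a pure optimisation;
tests assert its agreement with the direct computation.

Default problem sizes: the bundled acceptance runs use 10,000 replicates
per operating-characteristics cell and 10,000 imputation draws per
predictive evaluation; the test suite exercises the sequential design at
2,000 replicates, where the Monte-Carlo standard errors (≈4 patients on a
mean sample size, ≈0.002 on a proportion near 0.99) remain well inside the
tolerances asserted.  Reported tables always carry the binomial standard
errors alongside proportions.

## Synthetic data

`generate_stream` produces the statistical structure the analyses assume
and nothing more: homogeneous Poisson accrual, simple randomisation,
exchangeable Bernoulli outcomes, independent missingness.  It deliberately
omits site effects, covariates, calendar seasonality, accrual ramp-up and
informative dropout — so passing simulations demonstrate the *decision
machinery* under the design's own assumptions, not robustness of any real
trial's data to them.

`generate_fixture` builds streams under exact count constraints so the
engine can be tested against published interim tables when patient-level
data are unavailable.  Completeness at a trigger is controlled by
recruit-time placement: patients constrained to be complete are recruited
at least one follow-up window before the trigger patient, in-transit
patients inside the trailing window.  Death counts are allocated greedily
to the earliest newly-complete cohort; missing patients are placed as late
as possible (tail first, then the last in-transit cohort).  Constraints
that are infeasible — non-monotone counts, deaths outgrowing newly complete
patients, triggers closer together than one follow-up window, a trigger
with nobody in transit (the trigger patient cannot have completed
follow-up), or dropouts required before the last look — raise an error
naming the first violated inequality.  Every fixture is verified in tests
by an independent snapshot recount.

## Numerical and design choices

* Probabilities are reported in [0, 1]; rendered tables show 4 decimals for
  probabilities and 2 for relative risks, with full precision in JSON.
* The closed-form superiority sum is capped at 10⁵ terms before quadrature
  takes over; quadrature anchors an interior point at the control-posterior
  mode.
* `sd_n` uses the sample (ddof = 1) standard deviation.
* Future-patient allocation inside `P_max` is deterministic (largest
  remainder, odd patient to control) rather than randomised: it matches
  randomisation in expectation and removes one noise source from interim
  decisions.
* Fixture randomisation order within a trigger block is shuffled
  deterministically by seed to avoid degenerate arm runs.

## Known limitations

* Simulated trial *duration* depends on the accrual process, and a
  homogeneous Poisson process at the stated mean rate is the simplest
  defensible choice; published duration figures for the motivating trial
  imply a more complex (unstated) accrual model, so durations here are
  internally consistent but not comparable to those figures.
* Expected sample sizes of sequential designs are sensitive to exactly
  where a stopping boundary sits inside the predictive-probability
  distribution at a look.  The exact posterior-predictive computation used
  here stops at the first look somewhat more often than the original
  simulation software appears to have done under the same stated
  assumptions; stopping *proportions*, power and type I error agree, but
  expected sample sizes under effect scenarios come out 4–6% lower.  The
  package reports what the exact construction implies.
* Early stopping biases the naive treatment-effect estimate; no
  bias-corrected estimator is provided.
* Covariate adjustment, odds-ratio summaries, exact frequentist intervals
  and time-to-event endpoints are out of scope.
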