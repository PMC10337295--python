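# Methods

## The trial being emulated

A 30-day micro-randomized trial with two parallel arms. Users are
allocated 60/20/20 to (i) the MRT, where each day at 8 PM they are
randomized among a standard message (0.3), a message from a new bank
(0.3), or nothing (0.4); (ii) a fixed policy sending the standard message
daily at 11 AM; (iii) a no-notification policy. The primary proximal
outcome is a binary indicator of opening the app in [20:00, 21:00) after
the decision point; a secondary 24-hour outcome covers
[20:00, 20:00 next day). The between-policy endpoint is time to
disengagement: the earliest day starting a run of at least 7 consecutive
days with no screen views, defined over the first 23 days of the 30-day
follow-up and censored at 23 otherwise.

## Generative model for the synthetic trial

Each user carries a log-scale random intercept `u_i ~ N(0, user_sd²)`.
On day `d` (1-based since download), with `A ∈ {0,1}` indicating an 8 PM
notification, `H` a notification delivered yesterday (habituation) and
`E` an 8–9 PM open yesterday (already engaged), the probability of an
8–9 PM open is

```
min(0.99, exp(u_i + log p0 + A·(b0 + (d−1)·b1 + h·H + g·E)))
```

Disengagement is an absorbing state entered with constant daily hazard
(checked at the start of each day); after entry every open probability is
zero, which makes the ≥7-day rule a deterministic detector of the state.
Independent daytime ([00:00, 20:00)) and late ([21:00, 24:00)) opens
drive the two time-varying precision covariates. Each open is serialized
as one session: start uniform in its window, `1 + Poisson(mean − 1)`
views, exponential inter-view gaps truncated below 1800 s, and views
clipped to the window end, so (a) the 30-minute sessionizer recovers
generated sessions exactly and (b) every derived window indicator
round-trips exactly from the emitted event stream (this equivalence is
tested, and lets the power simulations skip event serialization).

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| `base_window_prob` | 0.036 | observed no-notification 8–9 PM open proportion |
| `log_rr_day1` | ln 3.5 | headline near-term notification effect |
| `log_rr_decay_per_day` | ln 0.993 | estimated per-day multiplicative change |
| `habituation_log_ratio`, `engaged_log_ratio` | 0 | moderation was not statistically detectable |
| `user_sd` | 0.7 | substantial between-user engagement spread (~2× factor per SD), typical of app-usage data |
| `daytime_open_prob` | 0.35 | yields session counts per user in the observed median range |
| `late_open_prob` | 0.15 | evening-heavy usage profile |
| `diseng_hazard` | 0.055 | gives ~70% disengaged by day 23 and median time ~11–12 days, matching the trial's scale |
| `views_per_session_mean` | 5, gaps mean 10 s | median session length ~35–40 s |
| `missing_rate` | 60/566 | observed sex/employment missingness |

Arm-specific details: parallel-arm users get degenerate "randomization"
records (probability 1 of their policy). The 11 AM standard-arm message
is treated as outside the 8 PM window model (those users contribute
`A = 0` dynamics); only MRT rows enter the excursion-effect analysis, so
this affects nothing downstream. All users share a configurable download
date; day windows are offsets from it, and a flag emits timestamps
shifted −60 min to exercise the UTC→local correction.

What the generator does **not** emulate: notification content, weekly or
holiday seasonality, staggered download dates, drinking-diary values, the
dependence of disengagement on notification burden, or users disabling
notifications. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its inference under a log-linear
world with random intercepts — not robustness to every pattern of real
app-usage data.

## Preprocessing conventions

* "Opened the app" means any screen view in the window, not only session
  starts (a notification tap lands on the app's landing page and logs a
  view).
* All windows are half-open `[start, end)`; a view at exactly 21:00:00 is
  not an 8–9 PM open but sets the next day's after-9-PM covariate.
* The sessionizer starts a new session when a gap is strictly greater
  than 1800 s.
* The disengagement horizon stays at 23 days even though a 7-day run
  starting day 24 would fit in a 30-day follow-up; the trial's convention
  is adopted as stated. The pipeline clamps the horizon to
  `min(23, n_days − run_days + 1)` so shorter synthetic runs stay valid.
* Modal imputation computes the mode over the pooled analysis set (ties
  break alphabetically); the second-most-common fill is the sensitivity
  analysis. Imputation counts are reported per arm.

## Estimation

The excursion-effect estimating equations (see README for the formulas)
are solved by damped Newton–Raphson with the analytic Jacobian:
initialization `β = 0`, intercept of `α` at the log weighted outcome mean
among untreated points; step-halving (up to 12 halvings) enforces descent
of the squared equation norm; convergence when the largest update is
below 1e−8, with a 50-iteration cap and a warning (never a silent
failure) otherwise. Degenerate inputs are rejected with specific errors:
no treated or no untreated successes (relative risk inestimable), rank
deficiency (collinear columns are named), and fewer than two treatment
levels after contrast subsetting.

Type-specific contrasts subset to {that type, none} and condition the
randomization probability on the remaining options (3/7 under
0.3/0.3/0.4). The centering probability defaults to the randomization
probability, making all weights 1; the general weighted path is retained
and exercised in tests because the estimator is defined with it.
Moderation fits automatically add the moderator's main effect to the
control set. Day enters the moderator set centered at day 1, so the
reported `rr_day1` is the effect on the first day after download.

Variance: sandwich `B⁻¹MB⁻ᵀ/n` over per-user contributions. The
small-sample correction (on by default, off for oracle tests) inflates
each user's residual vector by `(I − H_i)⁻¹` with
`H_i = G_i (ΣM'G)⁻¹ M_i'`, the estimating-equation analogue of the
Mancl–DeRouen GEE adjustment. Simulation at the trial's scale (349 users
× 30 days) shows the 5%-level Wald test of the time-moderation
coefficient rejecting at ≈4–5% under a null generator — the correction
is mildly conservative here, which is its documented behavior with a few
hundred clusters — and 95% Wald intervals for the marginal relative risk
covering at ≈94–95%.

With the default per-day decay the day-specific generating effect varies,
so the marginal (intercept-only) estimand is compared against the
day-averaged generating log relative risk
`b0 + mean(d−1)·b1` (RR 3.16 under the defaults); the residual gap
between that average and the outcome-weighted estimand is ~0.02 on the
log scale, well inside the recovery tolerance used in tests.

## Survival comparison

Kaplan–Meier product-limit estimates per arm with Greenwood variance.
Confidence bands use a normal interval on `log S` clipped to `[0, 1]`
(bounded, and the convention of the survival-plotting stack the original
analysis used); the plain-Greenwood alternative was the open choice. Ties
are handled discretely; users censored at a day remain at risk through
it. The median is the first day with survival ≤ 0.5, giving integer-day
medians. The k-sample log-rank test is delegated to `lifelines`
(`multivariate_logrank_test`); an independent 2×2-accumulation oracle
validates it in the tests.

## Design computations

`two_prop_n` uses the normal-approximation formula
`(z_α + z_power)²·(p1q1 + p2q2)/(p1 − p2)²` with the two-decimal table
critical values 1.96 and 0.84 and nearest-integer rounding — the
convention under which (0.55, 0.65) sizes to exactly 372 per group (the
exact quantile 0.8416 would give 373). Both the critical values and the
rounding are configurable.

`simulate_rejection_rate` draws replicate MRT arms from this package's
generator (the original power simulation's generative inputs are not
recoverable), fits the scenario's model, and reports the Wald rejection
fraction with its binomial Monte-Carlo SE. Replicate seeds derive
deterministically from one master seed; replicates whose fit degenerates
are counted and more than 5% of them abort the run. The power-simulation
nuisance model is `[1, day−1, opened_before_8pm, opened_after_9pm_prev]`:
baseline covariates are omitted because they do not drive the synthetic
outcome and the estimator is insensitive to the nuisance model — this
keeps each of the ≥500 replicate fits fast. Simulation sizes in the test
suite (500 replicates for type-I error and parameter recovery, 200 for
the log-rank null) were chosen as the smallest runs whose Monte-Carlo
error is well inside the asserted bands.

## Numerical and degenerate-input choices

* Generated open probabilities are clipped at 0.99; clipped user-days are
  counted and surfaced as a warning (under the defaults clipping touches
  ~0.1% of treated user-days of the most engaged users).
* Assignment-probability triples may contain exact 0/1 entries in the
  generator (degenerate policies are legitimate study conditions), but
  estimation requires probabilities strictly inside (0, 1).
* An empty arm is an error for curve estimation, a warning plus omitted
  row for usage summaries; a log-rank call with no events returns
  statistic 0 with p = 1 and a warning.
* Timestamps are serialized at microsecond resolution; all derived
  quantities round-trip exactly through the CSV artifacts.

## Known limitations

* Availability is universal (every user is randomized every day); there
  is no availability indicator.
* The type-specific contrast conditions on the two-option subset; whether
  the original analysis did the same cannot be determined from the
  published tables, and the alternative (marginal 0.3-vs-0.4 structure)
  is expressible through the centering/weight path.
* The small-sample variance correction is one member of a family; the
  square-root (Kauermann–Carroll-type) variant is not implemented.
* Power numbers for moderation refer to this generator, not to the
  original trial's (unavailable) simulation model, and are a calibration
  exercise rather than a reproduction.
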