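# mrtengage

Analysis pipeline for a micro-randomized trial (MRT) of push notifications
in a behavior change app for higher-risk drinkers. In an MRT each user is
randomized repeatedly over time — here, daily at 8 PM for the first 30 days
after download, among a standard reminder message (probability 0.3), a
message from a new motivational bank (0.3), or no notification (0.4) — and
the proximal outcome is whether the user opens the app in the following
hour. Two parallel arms (a fixed daily 11 AM message; no notifications)
support a between-policy comparison of time to disengagement.

The package provides, as importable modules and a thin CLI:

* **`synthetic_data`** — a generative model of the full three-arm trial
  (baseline table, daily randomization records, raw screen-view streams)
  with user-level heterogeneity, habituation/engagement dynamics and an
  absorbing disengagement process, so the entire pipeline is testable
  without any data download;
* **`preprocess`** — sessionization of screen-view logs (new session after
  >30 min inactivity), derivation of per-decision-point outcomes and
  time-varying covariates, time to disengagement (first day of ≥7
  consecutive unused days, over the first 23 days), modal imputation of
  missing baseline categories, and usage summaries;
* **`emee`** — the estimator of causal excursion effects for binary
  proximal outcomes on the relative-risk scale: weighted-and-centered
  estimating equations solved by damped Newton–Raphson, with
  cluster-robust sandwich inference and a small-sample correction;
* **`survival`** — Kaplan–Meier curves with Greenwood variance and a
  log-rank comparison of the three notification policies;
* **`design`** — the trial's two-proportion sample-size formula and
  simulation-based power / type-I-error calculations for the
  excursion-effect Wald tests.

## The model

For user *i* at decision point *t*, let `A_t ∈ {0,1}` indicate an 8 PM
notification, `Y_{t+1}` the 8–9 PM app-open indicator, `H_t` the observed
history, and `p_t = P(A_t = 1)` the known randomization probability. The
causal excursion effect on the relative-risk scale is modeled as

```
log E[Y_{t+1} | H_t, A_t] = g(H_t)'α + A_t · f(S_t)'β
```

with moderators `f(S_t)` (intercept; optionally day since download,
habituation, or "already engaged") and nuisance controls `g(H_t)` (age,
AUDIT score, day, sex, employment, and the opened-before-8-PM /
opened-after-9-PM-yesterday indicators). Estimation solves

```
Σ_i Σ_t W_t · (e^{−A_t f_t'β} Y_t − e^{g_t'α}) · stack(g_t, (A_t − p̃_t) f_t) = 0
```

where `W_t = (p̃_t/p_t)^{A_t}((1−p̃_t)/(1−p_t))^{1−A_t}` and `p̃_t` is a
centering probability (defaulting to `p_t`, so all weights are 1). The
centering term `(A_t − p̃_t)` makes `β̂` consistent for the excursion
effect even when the control model is misspecified. `exp(β)` terms are
reported as relative risks; variances come from the sandwich
`B⁻¹MB⁻ᵀ/n` over per-user estimating-function contributions, by default
with each user's residual vector inflated by the inverse of its hat matrix
(the Mancl–DeRouen small-sample adjustment).

## Worked example

```bash
mrtengage run-all --outdir out/
cat out/summary_report.txt
```

simulates a 566-user trial at the default seed (331 MRT / 118 standard /
117 none after the 60/20/20 split), derives 30 daily decision points per
user, and fits all effect models. Excerpts of the report:

```
[near_term]
        contrast outcome       label    rr  ci_low  ci_high
          pooled  y_hour marginal_rr 2.968   2.383    3.696
standard_vs_none  y_hour marginal_rr 2.940   2.319    3.728
     new_vs_none  y_hour marginal_rr 2.986   2.362    3.774

[time_trend]
        contrast outcome          label    rr  ci_low  ci_high
          pooled  y_hour        rr_day1 2.774   1.948    3.949
          pooled  y_hour change_per_day 1.007   0.979    1.035

[time to disengagement]
log-rank chi2 = 6.140 on 2 df, p = 0.046
median day by arm: {'mrt': 12.0, 'none': 9.0, 'standard': 9.0}

[design]
computation   p1   p2  n_per_group
 two_prop_n 0.55 0.65          372
```

Reading this: receiving any notification at 8 PM roughly triples the
probability of opening the app in the next hour (`marginal_rr` 2.97,
95% CI 2.38–3.70); the generator's day-averaged true relative risk is
3.16, so this seed's draw is within one standard error. The two message
types perform similarly, and the effect shows no significant drift over
time (`change_per_day` CI spans 1). One 331-user arm gives wide intervals
for moderation and survival contrasts — at this sample size a borderline
log-rank p under identical generative hazards is an ordinary fluctuation,
which is exactly the power limitation the `design` module quantifies. The
`two_prop_n` row is the analytic sizing of the policy arms: detecting 55%
vs 65% disengagement by day 22 with 80% power at a 5% level needs 372
users per arm.

Per-stage subcommands (`simulate`, `sessionize`, `derive`, `fit-emee`,
`survival`, `power`) operate on the same artifact directory, and a YAML
file passed via `--config` can override any trial, generator, analysis or
power setting. All artifacts are plain CSV/JSON; re-running a
configuration reproduces them byte-identically.

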