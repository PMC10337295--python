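"""Sample-size and power computations for the trial design.

Two pieces: the classical two-proportion normal-approximation sample size
used to size the parallel policy arms (55% vs 65% disengagement by day 22,
80% power, 5% two-sided alpha -> 372 users per arm with the two-decimal
table critical values 1.96 and 0.84), and a simulation-based power /
type-I-error calculation for the excursion-effect Wald tests, driven by
this package's synthetic trial generator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import emee
from .synthetic_data import GenerativeParams, TrialConfig, \
    simulate_decision_table, generate_baseline

#: nuisance (control) model used by the power simulations: intercept,
#: linear day trend and the two time-varying precision covariates.  The
#: synthetic outcome is not driven by the baseline covariates, and the
#: estimator is robust to the nuisance model, so they are omitted here.
POWER_SIM_CONTROLS = ("1", "day_m1", "opened_before_8pm",
                      "opened_after_9pm_prev")


@dataclass(frozen=True)
class TwoPropDesign:
    """Two-proportion sizing inputs.

    ``z_alpha``/``z_power`` default to the two-decimal table values 1.96
    and 0.84 with nearest-integer rounding, which is the convention that
    makes (0.55, 0.65) size to 372 per group.
    """

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80
    z_alpha: float = 1.96
    z_power: float = 0.84
    rounding: str = "nearest"

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 < p < 1.0:
                raise ValueError(f"proportions must lie in (0, 1), got {p}")
        if self.p1 == self.p2:
            raise ValueError("p1 and p2 must differ for a two-proportion design")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rounding not in ("nearest", "ceil"):
            raise ValueError("rounding must be 'nearest' or 'ceil'")


def two_prop_n(design: TwoPropDesign) -> int:
    """Per-group sample size for detecting p1 vs p2.

    n = (z_alpha + z_power)^2 (p1 q1 + p2 q2) / (p1 - p2)^2, rounded per
    the design (nearest by default).
    """
    num = (design.z_alpha + design.z_power) ** 2 * (
        design.p1 * (1 - design.p1) + design.p2 * (1 - design.p2))
    n = num / (design.p1 - design.p2) ** 2
    if design.rounding == "ceil":
        return int(math.ceil(n))
    return int(math.floor(n + 0.5))


class SimulationError(RuntimeError):
    """Raised when too many power-simulation replicates fail to fit."""


@dataclass(frozen=True)
class PowerScenario:
    """One simulation scenario for an excursion-effect Wald test.

    ``effect_day1`` is the generative day-1 relative risk and
    ``decay_per_day`` its multiplicative change per day (the trial was
    sized under 2.16 and 0.911).  ``test`` selects the null hypothesis:
    ``marginal`` tests the pooled effect, ``time_moderation`` the
    change-over-time coefficient.
    """

    effect_day1: float = 2.16
    decay_per_day: float = 0.911
    n_users: int = 349
    n_days: int = 30
    alpha: float = 0.05
    reps: int = 500
    test: str = "time_moderation"
    params: GenerativeParams = field(default_factory=GenerativeParams)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in ("marginal", "time_moderation"):
            raise ValueError("test must be 'marginal' or 'time_moderation'")
        if self.effect_day1 <= 0 or self.decay_per_day <= 0:
            raise ValueError("effect sizes must be positive")


def _scenario_spec(scenario: PowerScenario) -> emee.EmeeSpec:
    mods = ("1",) if scenario.test == "marginal" else ("1", "day_m1")
    return emee.EmeeSpec(contrast="pooled", moderators=mods,
                         controls=POWER_SIM_CONTROLS, outcome="y_hour")


def simulate_rejection_rate(scenario: PowerScenario, seed: int = 0,
                            max_divergent_frac: float = 0.05
                            ) -> tuple[float, float, int]:
    """Empirical rejection rate of the scenario's Wald test.

    Each replicate simulates a fresh MRT arm (n_users x n_days) under the
    scenario's generative effect, fits the excursion-effect model, and
    applies the two-sided Wald test at ``scenario.alpha``.  Returns
    (rejection rate, binomial Monte-Carlo SE, number of divergent
    replicates).  Replicate seeds are derived deterministically from
    ``seed``; more than ``max_divergent_frac`` divergent fits raises.
    """
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2 ** 31 - 1, size=scenario.reps)
    spec = _scenario_spec(scenario)
    test_index = 0 if scenario.test == "marginal" else 1
    params = dataclasses.replace(
        scenario.params,
        log_rr_day1=float(np.log(scenario.effect_day1)),
        log_rr_decay_per_day=float(np.log(scenario.decay_per_day)))
    rejections, divergent = 0, 0
    for s in rep_seeds:
        config = TrialConfig(n_users=scenario.n_users, n_days=scenario.n_days,
                             arm_split=(1.0, 0.0, 0.0), seed=int(s))
        baseline = generate_baseline(config, params)
        table = simulate_decision_table(config, params, baseline)
        try:
            es = emee.build_contrast(table, spec)
            fit = emee.fit_emee(es, spec)
            if not fit.converged:
                raise emee.DivergenceError("no convergence")
            _, pval = emee.wald_test(fit, test_index)
        except (emee.DivergenceError, emee.EstimationSetError,
                emee.DesignError):
            divergent += 1
            continue
        rejections += pval < scenario.alpha
    n_ok = scenario.reps - divergent
    if divergent > max_divergent_frac * scenario.reps or n_ok == 0:
        raise SimulationError(
            f"{divergent}/{scenario.reps} replicates diverged")
    rate = rejections / n_ok
    se = math.sqrt(rate * (1 - rate) / n_ok)
    return rate, se, divergent
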