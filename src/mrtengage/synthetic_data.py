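"""Synthetic three-arm notification trial generator.

Emulates a 30-day micro-randomized trial (MRT) of push notifications in an
alcohol-reduction app, with two parallel policy arms:

* 60% of users enter the MRT and are randomized daily at 8 PM among a
  standard message (30%), a message from a new bank (30%), or no
  notification (40%);
* 20% receive the standard message every day at 11 AM;
* 20% never receive a notification.

The proximal outcome is whether the user opens the app in the 8-9 PM hour.
The generative model for that window is log-linear on the relative-risk
scale with a per-user random intercept:

    P(open in window) = min(0.99, exp(u_i + log p0
                            + A * (b0 + (d-1)*b1 + h*H + g*E)))

where ``u_i ~ N(0, user_sd)``, ``p0`` is the baseline window-open
probability, ``A`` indicates any 8 PM notification, ``d`` is the day since
download, ``H`` indicates a notification delivered the previous day
(habituation) and ``E`` indicates an 8-9 PM open the previous day (already
engaged).  An absorbing "disengaged" state is entered with a constant daily
hazard; after entry every open probability is zero, so the downstream
">=7 consecutive unused days" rule detects disengagement deterministically.

Opens are serialized as raw screen-view streams: each open emits a session
whose start is uniform in its window, with 1 + Poisson views and
exponential inter-view gaps truncated below the 30-minute sessionization
threshold, so sessionization recovers generated sessions exactly.
Independent daytime (before 8 PM) and late (after 9 PM) opens drive the
time-varying covariates used by the analysis model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

ARMS = ("mrt", "standard", "none")
OPTIONS = ("standard", "new", "none")

SECONDS_PER_DAY = 86_400
DAYTIME_WINDOW = (0.0, 72_000.0)        # [00:00, 20:00)
EVENING_WINDOW = (72_000.0, 75_600.0)   # [20:00, 21:00)
LATE_WINDOW = (75_600.0, 86_400.0)      # [21:00, 24:00)

#: column schema of the baseline table
BASELINE_COLUMNS = ("user_id", "age", "sex", "employment", "audit", "arm")
#: column schema of the randomization table
RANDOMIZATION_COLUMNS = ("user_id", "day", "option",
                         "p_standard", "p_new", "p_none")
#: column schema of the screen-view log
EVENT_COLUMNS = ("user_id", "timestamp")

# AUDIT risk zones: hazardous, harmful, at risk of dependence
AUDIT_ZONES = ((8, 15), (16, 19), (20, 40))
AUDIT_ZONE_PROBS = (0.49, 0.20, 0.31)
EMPLOYMENT_PROBS = {"nonmanual": 0.70, "manual": 0.14, "other": 0.16}
AGE_MEAN, AGE_SD, AGE_RANGE = 44.0, 12.0, (18, 90)


class ConfigurationError(ValueError):
    """Raised when a trial configuration violates its invariants."""


def _check_probs(name: str, probs, n: int) -> None:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n:
        raise ConfigurationError(f"{name} must have {n} entries")
    if any(p < 0 or p > 1 for p in probs):
        raise ConfigurationError(f"{name} entries must lie in [0, 1]: {probs}")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1: {probs}")


@dataclass(frozen=True)
class TrialConfig:
    """Trial-level design parameters.

    ``assign_probs`` are the daily MRT randomization probabilities
    (standard, new, none); ``arm_split`` allocates users to
    (MRT, standard-policy, no-notification) arms.  ``n_days >= 8`` so the
    7-day disengagement rule is definable inside follow-up.
    """

    n_users: int
    n_days: int = 30
    assign_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)
    arm_split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    decision_time: str = "20:00"
    standard_arm_time: str = "11:00"
    start_date: str = "2020-02-01"
    emit_utc: bool = False
    utc_offset_minutes: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ConfigurationError("n_users must be nonnegative")
        if self.n_days < 8:
            raise ConfigurationError("n_days must be >= 8")
        _check_probs("assign_probs", self.assign_probs, 3)
        _check_probs("arm_split", self.arm_split, 3)


@dataclass(frozen=True)
class GenerativeParams:
    """Effect sizes, baseline rates and dynamics of the synthetic trial.

    Defaults anchor the trial's observed scale: baseline 8-9 PM open
    probability 0.036, day-1 notification relative risk 3.5 decaying by a
    factor 0.993 per day, and a disengagement hazard giving roughly
    two-thirds of users disengaged within 23 days.
    """

    base_window_prob: float = 0.036
    log_rr_day1: float = float(np.log(3.5))
    log_rr_decay_per_day: float = float(np.log(0.993))
    habituation_log_ratio: float = 0.0
    engaged_log_ratio: float = 0.0
    user_sd: float = 0.7
    daytime_open_prob: float = 0.35
    late_open_prob: float = 0.15
    diseng_hazard: float = 0.055
    views_per_session_mean: float = 5.0
    interview_gap_mean_s: float = 10.0
    missing_rate: float = 60 / 566

    def __post_init__(self) -> None:
        for name in ("base_window_prob", "daytime_open_prob",
                     "late_open_prob", "diseng_hazard", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.user_sd < 0:
            raise ConfigurationError("user_sd must be nonnegative")
        if self.views_per_session_mean < 1:
            raise ConfigurationError("views_per_session_mean must be >= 1")
        if self.interview_gap_mean_s <= 0:
            raise ConfigurationError("interview_gap_mean_s must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one stage of the simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_baseline(config: TrialConfig,
                      params: GenerativeParams) -> pd.DataFrame:
    """Draw the baseline covariate table (one row per user).

    Age ~ N(44, 12) truncated to [18, 90]; sex ~ 50/50; AUDIT score drawn
    by risk zone (hazardous/harmful/dependence at 0.49/0.20/0.31, uniform
    integer within zone); employment 70/14/16 nonmanual/manual/other; arm
    by independent draws with ``config.arm_split``.  Sex and employment
    are then set to missing with ``params.missing_rate``.
    """
    rng = _rng(config.seed, 0)
    n = config.n_users
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object if c in
                                          ("user_id", "sex", "employment",
                                           "arm") else int)
                             for c in BASELINE_COLUMNS})
    arm = rng.choice(ARMS, size=n, p=config.arm_split)
    a, b = ((AGE_RANGE[0] - AGE_MEAN) / AGE_SD,
            (AGE_RANGE[1] - AGE_MEAN) / AGE_SD)
    age = np.rint(stats.truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD,
                                      size=n, random_state=rng)).astype(int)
    sex = rng.choice(["male", "female"], size=n)
    zone = rng.choice(len(AUDIT_ZONES), size=n, p=AUDIT_ZONE_PROBS)
    lo = np.array([z[0] for z in AUDIT_ZONES])[zone]
    hi = np.array([z[1] for z in AUDIT_ZONES])[zone]
    audit = rng.integers(lo, hi + 1)
    employment = rng.choice(list(EMPLOYMENT_PROBS), size=n,
                            p=list(EMPLOYMENT_PROBS.values()))
    baseline = pd.DataFrame({
        "user_id": [f"u{i:05d}" for i in range(n)],
        "age": age, "sex": sex, "employment": employment,
        "audit": audit, "arm": arm,
    })
    return inject_missingness(baseline, params.missing_rate, rng=rng)


def inject_missingness(baseline: pd.DataFrame, rate: float,
                       rng: Optional[np.random.Generator] = None,
                       seed: int = 0) -> pd.DataFrame:
    """Set sex and employment to missing independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"missingness rate must lie in [0, 1], got {rate}")
    if rng is None:
        rng = _rng(seed, 9)
    out = baseline.copy()
    n = len(out)
    for col in ("sex", "employment"):
        mask = rng.random(n) < rate
        out[col] = out[col].where(~mask, other=np.nan)
    return out


def simulate_decision_table(config: TrialConfig, params: GenerativeParams,
                            baseline: pd.DataFrame) -> pd.DataFrame:
    """Simulate the per-user-day decision-point table directly.

    Returns one row per user per day 1..n_days for *all* arms, with the
    assigned option, assignment probabilities, proximal outcomes
    (``y_hour``, ``y_24h``) and time-varying covariates, plus the joined
    baseline covariates.  This is the ground truth the preprocessor
    recovers from the emitted screen-view log.
    """
    rng = _rng(config.seed, 1)
    n, d_total = len(baseline), config.n_days
    arm = baseline["arm"].to_numpy()
    is_mrt = arm == "mrt"
    is_std = arm == "standard"

    u = rng.normal(0.0, params.user_sd, size=n)
    # assigned option per user-day; parallel arms get degenerate policies
    opt = rng.choice(3, size=(n, d_total), p=config.assign_probs)
    opt[is_std, :] = 0           # standard policy: standard message daily
    opt[arm == "none", :] = 2    # no-notification policy

    alive = np.ones(n, dtype=bool)
    habit = np.zeros(n, dtype=bool)
    engaged = np.zeros(n, dtype=bool)
    y_ev = np.zeros((n, d_total), dtype=bool)
    day_open = np.zeros((n, d_total), dtype=bool)
    late_open = np.zeros((n, d_total), dtype=bool)
    habit_mat = np.zeros((n, d_total), dtype=bool)
    engaged_mat = np.zeros((n, d_total), dtype=bool)
    n_clipped = 0

    log_p0 = np.log(params.base_window_prob) if params.base_window_prob > 0 \
        else -np.inf
    for d in range(d_total):
        enter = alive & (rng.random(n) < params.diseng_hazard)
        alive &= ~enter
        habit_mat[:, d] = habit
        engaged_mat[:, d] = engaged
        a_evening = is_mrt & (opt[:, d] != 2)   # 8 PM notification delivered
        eta = (u + log_p0
               + a_evening * (params.log_rr_day1
                              + d * params.log_rr_decay_per_day
                              + params.habituation_log_ratio * habit
                              + params.engaged_log_ratio * engaged))
        with np.errstate(over="ignore"):
            p = np.exp(eta)
        n_clipped += int(np.count_nonzero(alive & (p > 0.99)))
        p = np.minimum(p, 0.99)
        y_ev[:, d] = alive & (rng.random(n) < p)
        day_open[:, d] = alive & (rng.random(n) < params.daytime_open_prob)
        late_open[:, d] = alive & (rng.random(n) < params.late_open_prob)
        delivered = (is_mrt & (opt[:, d] != 2)) | is_std
        habit = delivered
        engaged = y_ev[:, d]

    if n_clipped:
        warnings.warn(
            f"{n_clipped} user-day open probabilities exceeded 0.99 before "
            "clipping", RuntimeWarning, stacklevel=2)

    next_daytime = np.zeros_like(day_open)
    next_daytime[:, :-1] = day_open[:, 1:]
    y24 = y_ev | late_open | next_daytime
    prev_late = np.zeros_like(late_open)
    prev_late[:, 1:] = late_open[:, :-1]

    ps, pn, pz = config.assign_probs
    p_standard = np.where(is_mrt, ps, np.where(is_std, 1.0, 0.0))
    p_new = np.where(is_mrt, pn, 0.0)
    p_none = np.where(is_mrt, pz, np.where(is_std, 0.0, 1.0))

    days = np.tile(np.arange(1, d_total + 1), n)
    rep = np.repeat(np.arange(n), d_total)
    table = pd.DataFrame({
        "user_id": baseline["user_id"].to_numpy()[rep],
        "day": days,
        "option": np.array(OPTIONS)[opt.ravel()],
        "p_standard": p_standard[rep],
        "p_new": p_new[rep],
        "p_none": p_none[rep],
        "y_hour": y_ev.ravel().astype(int),
        "y_24h": y24.ravel().astype(int),
        "opened_before_8pm": day_open.ravel().astype(int),
        "opened_after_9pm_prev": prev_late.ravel().astype(int),
        "already_engaged_prev": engaged_mat.ravel().astype(int),
        "habituation": habit_mat.ravel().astype(int),
    })
    return table.merge(baseline, on="user_id", how="left")


def _emit_window_sessions(rng, flags, window, params, user_ids, t0):
    """Turn a boolean user x day open matrix into screen-view timestamps."""
    lo, hi = window
    ui, dj = np.nonzero(flags)
    k = len(ui)
    if k == 0:
        return [], np.array([], dtype="datetime64[ns]")
    n_views = 1 + rng.poisson(params.views_per_session_mean - 1.0, size=k)
    start = lo + rng.uniform(0.0, hi - lo, size=k)
    total = int(n_views.sum())
    gaps = np.minimum(
        rng.exponential(params.interview_gap_mean_s, size=total - k), 1799.0)
    sess = np.repeat(np.arange(k), n_views)
    first = np.ones(total, dtype=bool)
    first[1:] = sess[1:] != sess[:-1]
    g = np.zeros(total)
    g[~first] = gaps
    cs = np.cumsum(g)
    base = np.repeat(cs[first], n_views)
    offset = cs - base
    tod = np.minimum(start[sess] + offset, hi - 1.0)
    tod = np.round(tod, 6)
    seconds = (dj[sess].astype(np.int64) * SECONDS_PER_DAY) + tod
    ts = t0 + pd.to_timedelta(seconds, unit="s")
    return list(np.asarray(user_ids)[ui[sess]]), ts.to_numpy()


def simulate_trial(config: TrialConfig, params: GenerativeParams,
                   baseline: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the trial, returning (randomization table, screen-view log).

    The randomization table holds one row per user-day with the assigned
    option and the assignment probabilities; the screen-view log is the
    raw engagement stream consistent with the generated outcomes.  With a
    fixed ``config.seed`` both outputs are bit-identical across calls.
    """
    table = simulate_decision_table(config, params, baseline)
    rng = _rng(config.seed, 2)
    t0 = pd.Timestamp(config.start_date)
    n, d_total = len(baseline), config.n_days

    def _matrix(col):
        return (table[col].to_numpy().reshape(n, d_total) > 0)

    uids: list = []
    stamps: list = []
    for col, window in (("opened_before_8pm", DAYTIME_WINDOW),
                        ("y_hour", EVENING_WINDOW),
                        ("opened_after_9pm_prev", None)):
        if window is None:
            # late opens are stored shifted by one day; recover day-d flags
            flags = np.zeros((n, d_total), dtype=bool)
            flags[:, :-1] = _matrix(col)[:, 1:]
            # final-day late opens are only visible through y_24h
            last = (table[table["day"] == d_total]
                    .set_index("user_id"))
            y24 = last["y_24h"].to_numpy() > 0
            yev = last["y_hour"].to_numpy() > 0
            flags[:, -1] = y24 & ~yev
            window = LATE_WINDOW
        else:
            flags = _matrix(col)
        ids, ts = _emit_window_sessions(rng, flags, window, params,
                                        baseline["user_id"].to_numpy(), t0)
        uids.extend(ids)
        stamps.append(ts)

    events = pd.DataFrame({
        "user_id": uids,
        "timestamp": np.concatenate(stamps) if stamps else [],
    })
    events = events.sort_values(["user_id", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    if config.emit_utc:
        events["timestamp"] = (events["timestamp"]
                               - pd.Timedelta(minutes=config.utc_offset_minutes))
    rand = table[list(RANDOMIZATION_COLUMNS)].copy()
    return rand, events


def write_run_manifest(path, config: TrialConfig,
                       params: GenerativeParams) -> None:
    """Echo the seed and full parameter set to a JSON manifest."""
    manifest = {"trial_config": asdict(config),
                "generative_params": asdict(params)}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
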