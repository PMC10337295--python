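"""Turn raw screen-view logs into analysis-ready tables.

The raw engagement signal is a stream of (user_id, timestamp) screen views.
This module sessionizes it with a 30-minute inactivity rule, derives the
per-decision-point outcomes and time-varying covariates, locates the time
to disengagement (first day of a run of >= 7 unused days within the first
23 days), imputes missing baseline categories, and summarizes usage.

All clock windows are half-open: the proximal-outcome hour is
[20:00, 21:00), the daytime covariate window [00:00, 20:00) and the
late-evening window [21:00, 24:00).  A view at exactly 21:00:00 therefore
does not count as an 8-9 PM open but does set the next day's
"opened after 9 PM" covariate.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic_data import (EVENING_WINDOW, LATE_WINDOW, SECONDS_PER_DAY,
                             TrialConfig)

#: column schema of the session table
SESSION_COLUMNS = ("user_id", "start", "end", "duration_s", "n_views")
#: column schema of the per-user disengagement table
DISENGAGEMENT_COLUMNS = ("user_id", "arm", "time", "event")

DEFAULT_GAP_S = 1800.0


class TimestampError(ValueError):
    """Raised when event timestamps cannot be parsed."""


class ImputationError(ValueError):
    """Raised when modal imputation is undefined."""


def _parse_events(events: pd.DataFrame) -> pd.DataFrame:
    out = events.loc[:, ["user_id", "timestamp"]].copy()
    if not pd.api.types.is_datetime64_any_dtype(out["timestamp"]):
        parsed = pd.to_datetime(out["timestamp"], errors="coerce",
                                format="ISO8601")
        bad = np.flatnonzero(parsed.isna() & out["timestamp"].notna())
        if len(bad):
            raise TimestampError(
                "non-parseable timestamps at input lines "
                f"{[int(i) for i in bad[:10]]}"
                f"{' ...' if len(bad) > 10 else ''}")
        out["timestamp"] = parsed
    return out


def to_local(events: pd.DataFrame, offset_minutes: int) -> pd.DataFrame:
    """Shift all timestamps by ``offset_minutes`` (e.g. UTC -> BST is +60)."""
    out = _parse_events(events)
    if offset_minutes:
        out["timestamp"] = out["timestamp"] + pd.Timedelta(minutes=offset_minutes)
    return out


def sessionize(events: pd.DataFrame, gap_s: float = DEFAULT_GAP_S
               ) -> pd.DataFrame:
    """Group screen views into sessions with an inactivity-gap rule.

    Consecutive views of the same user with a gap of at most ``gap_s``
    seconds (default 30 minutes) belong to one session; a strictly larger
    gap starts a new one.  Session duration is last view minus first view,
    so a single-view session has duration zero and every duration is an
    underestimate of true attention time.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    df = _parse_events(events)
    if df.empty:
        return pd.DataFrame(columns=list(SESSION_COLUMNS))
    df = df.sort_values(["user_id", "timestamp"],
                        kind="mergesort").reset_index(drop=True)
    gap = df.groupby("user_id", sort=False)["timestamp"].diff()
    new_session = gap.isna() | (gap.dt.total_seconds() > gap_s)
    sid = new_session.cumsum()
    agg = df.groupby(sid, sort=False).agg(
        user_id=("user_id", "first"),
        start=("timestamp", "first"),
        end=("timestamp", "last"),
        n_views=("timestamp", "size"),
    ).reset_index(drop=True)
    agg["duration_s"] = (agg["end"] - agg["start"]).dt.total_seconds()
    return agg[list(SESSION_COLUMNS)]


def _event_day_flags(events: pd.DataFrame, user_index: pd.Index,
                     start_date: str, n_days: int):
    """Boolean user x day matrices of opens per clock window.

    Day ``d`` covers [start_date + (d-1) days, +1 day); matrices span
    days 1..n_days+1 (the extra day feeds the 24-hour outcome).
    """
    df = _parse_events(events)
    known = df["user_id"].isin(user_index)
    if (~known).any():
        dropped = df.loc[~known, "user_id"].unique()
        warnings.warn(
            f"dropping {len(dropped)} user(s) present in events but absent "
            f"from the randomization table: {sorted(map(str, dropped))[:5]}",
            RuntimeWarning, stacklevel=3)
        df = df[known]
    n_u = len(user_index)
    shape = (n_u, n_days + 1)
    evening = np.zeros(shape, dtype=bool)
    daytime = np.zeros(shape, dtype=bool)
    late = np.zeros(shape, dtype=bool)
    if df.empty:
        return evening, daytime, late
    sec = (df["timestamp"] - pd.Timestamp(start_date)).dt.total_seconds()
    day = np.floor_divide(sec.to_numpy(), SECONDS_PER_DAY).astype(np.int64)
    tod = sec.to_numpy() - day * SECONDS_PER_DAY
    in_range = (day >= 0) & (day <= n_days)
    ui = user_index.get_indexer(df["user_id"])[in_range]
    day = day[in_range]
    tod = tod[in_range]
    ev = (tod >= EVENING_WINDOW[0]) & (tod < EVENING_WINDOW[1])
    lt = tod >= LATE_WINDOW[0]
    dt_ = tod < EVENING_WINDOW[0]
    evening[ui[ev], day[ev]] = True
    daytime[ui[dt_], day[dt_]] = True
    late[ui[lt], day[lt]] = True
    return evening, daytime, late


def derive_decision_points(events: pd.DataFrame,
                           randomization: pd.DataFrame,
                           baseline: pd.DataFrame,
                           config: TrialConfig) -> pd.DataFrame:
    """Build the decision-point table: outcomes + time-varying covariates.

    For each user-day in the randomization table: ``y_hour`` is 1 iff any
    screen view falls in [20:00, 21:00) of that day; ``y_24h`` iff any view
    in [20:00 day d, 20:00 day d+1).  Covariates: opened before 8 PM the
    same day, opened after 9 PM the previous day, opened 8-9 PM the
    previous day (already engaged), and habituation (any notification
    delivered the previous day, read off the randomization table).  Day-1
    history covariates are 0.  Users with no events get all-zero outcomes.
    """
    rand = randomization.sort_values(["user_id", "day"],
                                     kind="mergesort").reset_index(drop=True)
    users = pd.Index(rand["user_id"].unique())
    n_days = int(rand["day"].max())
    evening, daytime, late = _event_day_flags(events, users,
                                              config.start_date, n_days)
    ui = users.get_indexer(rand["user_id"])
    dj = rand["day"].to_numpy() - 1

    y_hour = evening[ui, dj]
    y_24h = y_hour | late[ui, dj] | daytime[ui, dj + 1]
    before8 = daytime[ui, dj]
    prev = dj - 1
    has_prev = prev >= 0
    after9_prev = np.where(has_prev, late[ui, np.maximum(prev, 0)], False)
    engaged_prev = np.where(has_prev, evening[ui, np.maximum(prev, 0)], False)

    delivered = (rand["option"].to_numpy() != "none")
    deliv_mat = np.zeros((len(users), n_days), dtype=bool)
    deliv_mat[ui, dj] = delivered
    habituation = np.where(has_prev, deliv_mat[ui, np.maximum(prev, 0)], False)

    out = rand.copy()
    out["y_hour"] = y_hour.astype(int)
    out["y_24h"] = y_24h.astype(int)
    out["opened_before_8pm"] = before8.astype(int)
    out["opened_after_9pm_prev"] = after9_prev.astype(int)
    out["already_engaged_prev"] = engaged_prev.astype(int)
    out["habituation"] = habituation.astype(int)
    return out.merge(baseline, on="user_id", how="left")


def derive_disengagement(events: pd.DataFrame, baseline: pd.DataFrame,
                         start_date: str, horizon_days: int = 23,
                         run_days: int = 7, followup_days: int = 30
                         ) -> pd.DataFrame:
    """Per-user time to disengagement with censoring.

    A user disengages on the earliest day ``d`` in 1..horizon_days such
    that days d..d+run_days-1 all have zero screen views; users with no
    qualifying day are censored at ``horizon_days``.
    """
    if horizon_days + run_days - 1 > followup_days:
        raise ValueError(
            "horizon_days + run_days - 1 must not exceed followup_days")
    users = pd.Index(baseline["user_id"])
    df = _parse_events(events)
    used = np.zeros((len(users), followup_days), dtype=bool)
    if not df.empty:
        df = df[df["user_id"].isin(users)]
        sec = (df["timestamp"] - pd.Timestamp(start_date)).dt.total_seconds()
        day = np.floor_divide(sec.to_numpy(), SECONDS_PER_DAY).astype(np.int64)
        keep = (day >= 0) & (day < followup_days)
        ui = users.get_indexer(df["user_id"])[keep]
        used[ui, day[keep]] = True
    unused = (~used).astype(np.int64)
    csum = np.concatenate([np.zeros((len(users), 1), dtype=np.int64),
                           np.cumsum(unused, axis=1)], axis=1)
    # qualifies[:, d] : days d+1 .. d+run_days all unused
    qualifies = (csum[:, run_days:horizon_days + run_days]
                 - csum[:, :horizon_days]) == run_days
    has_event = qualifies.any(axis=1)
    time = np.where(has_event, qualifies.argmax(axis=1) + 1, horizon_days)
    return pd.DataFrame({
        "user_id": baseline["user_id"].to_numpy(),
        "arm": baseline["arm"].to_numpy(),
        "time": time.astype(int),
        "event": has_event.astype(int),
    })


def impute_modal(baseline: pd.DataFrame, strategy: str = "modal"
                 ) -> tuple[pd.DataFrame, dict]:
    """Fill missing sex/employment with the (second) most frequent category.

    The mode is computed over the pooled analysis set; ties break
    alphabetically for determinism.  Returns the imputed table and a report
    with the fill value and the number of imputations per arm.
    """
    if strategy not in ("modal", "second_modal"):
        raise ValueError(f"unknown imputation strategy: {strategy!r}")
    out = baseline.copy()
    report: dict = {}
    for col in ("sex", "employment"):
        counts = out[col].value_counts(dropna=True)
        if counts.empty:
            raise ImputationError(f"all values of {col!r} are missing")
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rank = 0 if strategy == "modal" else 1
        if rank >= len(ordered):
            raise ImputationError(
                f"{col!r} has fewer than {rank + 1} observed categories")
        fill = ordered[rank][0]
        miss = out[col].isna()
        by_arm = (out.loc[miss].groupby("arm").size().to_dict()
                  if "arm" in out.columns else {})
        out.loc[miss, col] = fill
        report[col] = {"fill": fill, "n_imputed": int(miss.sum()),
                       "n_imputed_by_arm": {str(k): int(v)
                                            for k, v in by_arm.items()}}
    return out, report


def usage_summary(sessions: pd.DataFrame, baseline: pd.DataFrame,
                  start_date: Optional[str] = None,
                  followup_days: int = 30) -> pd.DataFrame:
    """Per-arm medians and IQRs of session counts and session lengths.

    Counts are per user over the first ``followup_days`` days (users with
    no sessions count zero); durations are pooled over sessions in the arm.
    """
    sess = sessions.copy()
    if start_date is not None and not sess.empty:
        t0 = pd.Timestamp(start_date)
        keep = ((sess["start"] >= t0)
                & (sess["start"] < t0 + pd.Timedelta(days=followup_days)))
        sess = sess[keep]
    sess = sess.merge(baseline[["user_id", "arm"]], on="user_id", how="left")
    rows = []
    for arm_name, grp in baseline.groupby("arm", sort=True):
        arm_sessions = sess[sess["arm"] == arm_name]
        if arm_sessions.empty:
            warnings.warn(f"arm {arm_name!r} has no sessions; row omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        counts = (arm_sessions.groupby("user_id").size()
                  .reindex(grp["user_id"], fill_value=0).to_numpy())
        dur = arm_sessions["duration_s"].to_numpy()
        rows.append({
            "arm": arm_name,
            "n_users": len(grp),
            "sessions_median": float(np.median(counts)),
            "sessions_q1": float(np.quantile(counts, 0.25)),
            "sessions_q3": float(np.quantile(counts, 0.75)),
            "duration_median_s": float(np.median(dur)),
            "duration_q1_s": float(np.quantile(dur, 0.25)),
            "duration_q3_s": float(np.quantile(dur, 0.75)),
        })
    return pd.DataFrame(rows)
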