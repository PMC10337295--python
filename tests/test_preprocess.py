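"""Sessionization, outcome derivation, disengagement and imputation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mrtengage as m
from mrtengage import preprocess as pp
from _oracles import disengagement_oracle
from conftest import events_frame

D1 = "2020-02-01"


# ---------------------------------------------------------------- sessions

@pytest.mark.parametrize("stamps, expected", [
    # single view: one zero-length session
    ([f"{D1}T20:05:00"], [(1, 0.0)]),
    # 1740 s gap stays within the 30-minute rule
    ([f"{D1}T20:00:00", f"{D1}T20:29:00"], [(2, 1740.0)]),
    # 1860 s gap splits; the second session has two views 60 s apart
    ([f"{D1}T20:00:00", f"{D1}T20:31:00", f"{D1}T20:32:00"],
     [(1, 0.0), (2, 60.0)]),
    # exactly 1800 s is still the same session (strictly-greater rule)
    ([f"{D1}T20:00:00", f"{D1}T20:30:00"], [(2, 1800.0)]),
])
def test_sessionize_gap_rule(stamps, expected):
    sessions = pp.sessionize(events_frame([("u1", s) for s in stamps]))
    got = list(zip(sessions["n_views"], sessions["duration_s"]))
    assert got == expected


def test_sessionize_is_order_invariant_and_counts_views():
    pairs = [("u1", f"{D1}T10:00:00"), ("u2", f"{D1}T10:10:00"),
             ("u1", f"{D1}T10:05:00"), ("u1", f"{D1}T11:30:00")]
    shuffled = events_frame(pairs)
    sessions = pp.sessionize(shuffled)
    by_user = sessions.groupby("user_id").size().to_dict()
    assert by_user == {"u1": 2, "u2": 1}


def test_sessionize_rejects_bad_timestamps():
    bad = pd.DataFrame({"user_id": ["u1", "u1"],
                        "timestamp": ["2020-02-01T10:00:00", "not-a-time"]})
    with pytest.raises(pp.TimestampError, match="line"):
        pp.sessionize(bad)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=30_000), min_size=1,
                max_size=25))
def test_sessionize_start_boundaries_are_stable(offsets):
    """Re-sessionizing session starts preserves the session count:
    consecutive starts are always separated by more than the gap."""
    events = events_frame(
        [("u", pd.Timestamp(D1) + pd.Timedelta(seconds=s))
         for s in offsets])
    sessions = pp.sessionize(events)
    again = pp.sessionize(sessions.rename(columns={"start": "timestamp"})
                          [["user_id", "timestamp"]])
    assert len(again) == len(sessions)
    assert (sessions["end"] >= sessions["start"]).all()
    assert sessions["n_views"].sum() == len(events)


# ---------------------------------------------------------------- to_local

def test_to_local_shifts_window_membership():
    ev = events_frame([("u1", "2020-02-01T19:30:00")])
    assert pp.to_local(ev, 0)["timestamp"].iloc[0] == ev["timestamp"].iloc[0]
    shifted = pp.to_local(ev, 60)
    assert shifted["timestamp"].iloc[0] == pd.Timestamp("2020-02-01T20:30:00")
    back = pp.to_local(pp.to_local(ev, -60), 60)
    pd.testing.assert_frame_equal(back, pp.to_local(ev, 0))


# ---------------------------------------------------- decision-point table

def _rand_table(users, n_days, option="none"):
    rows = [{"user_id": u, "day": d, "option": option,
             "p_standard": 0.3, "p_new": 0.3, "p_none": 0.4}
            for u in users for d in range(1, n_days + 1)]
    return pd.DataFrame(rows)


def _baseline(users):
    return pd.DataFrame({"user_id": users, "age": 44, "sex": "female",
                         "employment": "nonmanual", "audit": 12,
                         "arm": "mrt"})


def test_no_events_give_all_zero_outcomes():
    cfg = m.TrialConfig(n_users=2, n_days=8, start_date=D1)
    empty = events_frame([])
    pts = pp.derive_decision_points(empty, _rand_table(["a", "b"], 8),
                                    _baseline(["a", "b"]), cfg)
    assert len(pts) == 16
    assert (pts[["y_hour", "y_24h", "opened_before_8pm"]] == 0).all().all()


def test_window_membership_and_lagged_covariates():
    """A 20:59:59 view on day 3 is an 8-9 PM open and makes day 4
    'already engaged'; a view at exactly 21:00:00 is not an open but sets
    the next day's after-9-PM covariate (half-open windows)."""
    cfg = m.TrialConfig(n_users=2, n_days=8, start_date=D1)
    ev = events_frame([
        ("a", "2020-02-03T20:59:59"),   # day 3 evening
        ("b", "2020-02-03T21:00:00"),   # day 3, exactly 21:00
    ])
    pts = pp.derive_decision_points(ev, _rand_table(["a", "b"], 8),
                                    _baseline(["a", "b"]), cfg)
    pts = pts.set_index(["user_id", "day"])
    assert pts.loc[("a", 3), "y_hour"] == 1
    assert pts.loc[("a", 4), "already_engaged_prev"] == 1
    assert pts.loc[("b", 3), "y_hour"] == 0
    assert pts.loc[("b", 3), "y_24h"] == 1
    assert pts.loc[("b", 4), "opened_after_9pm_prev"] == 1


def test_habituation_reads_the_randomization_table():
    cfg = m.TrialConfig(n_users=1, n_days=8, start_date=D1)
    rand = _rand_table(["a"], 8)
    rand.loc[rand["day"] == 2, "option"] = "new"
    pts = pp.derive_decision_points(events_frame([]), rand,
                                    _baseline(["a"]), cfg)
    habit = pts.set_index("day")["habituation"]
    assert habit[1] == 0 and habit[2] == 0 and habit[3] == 1 and habit[4] == 0


def test_unknown_event_users_are_dropped_with_warning():
    cfg = m.TrialConfig(n_users=1, n_days=8, start_date=D1)
    ev = events_frame([("ghost", "2020-02-01T20:30:00")])
    with pytest.warns(RuntimeWarning, match="absent"):
        pts = pp.derive_decision_points(ev, _rand_table(["a"], 8),
                                        _baseline(["a"]), cfg)
    assert (pts["y_hour"] == 0).all()


def test_y24h_dominates_y_hour_on_generated_data(small_trial):
    pts = pp.derive_decision_points(small_trial["events"],
                                    small_trial["rand"],
                                    small_trial["baseline"],
                                    small_trial["config"])
    assert (pts["y_24h"] >= pts["y_hour"]).all()


def test_generated_sessions_are_recovered_exactly():
    """With daytime/late opens disabled, the sessionizer recovers the
    generated per-user session count exactly."""
    params = m.GenerativeParams(daytime_open_prob=0.0, late_open_prob=0.0)
    cfg = m.TrialConfig(n_users=50, n_days=10, seed=19)
    base = m.generate_baseline(cfg, params)
    tab = m.simulate_decision_table(cfg, params, base)
    _, events = m.simulate_trial(cfg, params, base)
    sessions = pp.sessionize(events)
    generated = tab.groupby("user_id")["y_hour"].sum()
    recovered = (sessions.groupby("user_id").size()
                 .reindex(generated.index, fill_value=0))
    assert (recovered == generated).all()


# ----------------------------------------------------------- disengagement

@pytest.mark.parametrize("used, expected", [
    ({1, 2, 3}, (4, 1)),       # days 4-10 empty
    (set(range(1, 31)), (23, 0)),
    ({1, 9}, (2, 1)),          # days 2-8 is already a 7-day gap
    (set(), (1, 1)),
])
def test_disengagement_earliest_qualifying_day(used, expected):
    ev = events_frame([("u", pd.Timestamp(D1)
                        + pd.Timedelta(days=d - 1, hours=12))
                       for d in sorted(used)])
    base = _baseline(["u"])
    out = pp.derive_disengagement(ev, base, D1)
    assert (int(out["time"].iloc[0]), int(out["event"].iloc[0])) == expected
    assert expected == disengagement_oracle(used)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.sets(st.integers(min_value=1, max_value=30), max_size=30))
def test_disengagement_matches_exhaustive_scan(used):
    ev = events_frame([("u", pd.Timestamp(D1)
                        + pd.Timedelta(days=d - 1, hours=9))
                       for d in sorted(used)])
    out = pp.derive_disengagement(ev, _baseline(["u"]), D1)
    t, e = disengagement_oracle(used)
    assert int(out["time"].iloc[0]) == t
    assert int(out["event"].iloc[0]) == e
    assert 1 <= t <= 23


def test_disengagement_configuration_error():
    with pytest.raises(ValueError):
        pp.derive_disengagement(events_frame([]), _baseline(["u"]), D1,
                                horizon_days=25, run_days=7,
                                followup_days=30)


def test_disengagement_partition_over_users(small_trial):
    cfg = small_trial["config"]
    out = pp.derive_disengagement(small_trial["events"],
                                  small_trial["baseline"], cfg.start_date,
                                  horizon_days=6, run_days=7,
                                  followup_days=cfg.n_days)
    assert len(out) == len(small_trial["baseline"])
    assert out["time"].between(1, 6).all()
    assert ((out["event"] == 1) | (out["time"] == 6)).all()


# -------------------------------------------------------------- imputation

def _table_with_missing():
    sex = ["female"] * 259 + ["male"] * 247 + [np.nan] * 60
    emp = (["nonmanual"] * 300 + ["manual"] * 140 + ["other"] * 66
           + [np.nan] * 60)
    return pd.DataFrame({"user_id": [f"u{i}" for i in range(566)],
                         "age": 44, "sex": sex, "employment": emp,
                         "audit": 12, "arm": ["mrt"] * 566})


def test_modal_imputation_fills_most_common_category():
    out, report = pp.impute_modal(_table_with_missing(), "modal")
    assert (out["sex"].iloc[506:] == "female").all()
    assert report["sex"]["fill"] == "female"
    assert report["sex"]["n_imputed"] == 60
    assert report["employment"]["fill"] == "nonmanual"


def test_second_modal_imputation_is_the_sensitivity_analysis():
    out, _ = pp.impute_modal(_table_with_missing(), "second_modal")
    assert (out["sex"].iloc[506:] == "male").all()
    assert (out["employment"].iloc[506:] == "manual").all()


def test_imputation_identity_without_missing_and_error_when_all_missing():
    full = _table_with_missing().iloc[:506]
    out, report = pp.impute_modal(full, "modal")
    pd.testing.assert_frame_equal(out, full)
    assert report["sex"]["n_imputed"] == 0
    empty = _table_with_missing()
    empty["sex"] = np.nan
    with pytest.raises(pp.ImputationError):
        pp.impute_modal(empty, "modal")


# ------------------------------------------------------------------- usage

def test_usage_summary_order_statistics():
    base = pd.DataFrame({"user_id": ["a", "b", "c"], "age": 44,
                         "sex": "female", "employment": "manual",
                         "audit": 10, "arm": ["mrt", "mrt", "standard"]})
    t0 = pd.Timestamp(D1)
    sessions = pd.DataFrame({
        "user_id": ["a", "a", "b", "c"],
        "start": [t0 + pd.Timedelta(hours=h) for h in (1, 2, 3, 4)],
        "end": [t0 + pd.Timedelta(hours=h) for h in (1, 2, 3, 4)],
        "duration_s": [9.0, 36.0, 115.0, 10.0],
        "n_views": [2, 2, 2, 2],
    })
    out = pp.usage_summary(sessions, base, start_date=D1).set_index("arm")
    assert out.loc["mrt", "sessions_median"] == 1.5
    assert out.loc["mrt", "duration_median_s"] == 36.0
    assert out.loc["mrt", "duration_q1_s"] == pytest.approx(22.5)
    assert out.loc["standard", "sessions_median"] == 1.0
    assert out.loc["standard", "duration_median_s"] == 10.0


def test_usage_summary_median_matches_sort_oracle():
    rng = np.random.default_rng(3)
    users = [f"u{i}" for i in range(21)]
    counts = rng.integers(1, 25, size=21)
    rows = [{"user_id": u, "start": pd.Timestamp(D1), "end": pd.Timestamp(D1),
             "duration_s": float(j), "n_views": 1}
            for u, c in zip(users, counts) for j in range(c)]
    sessions = pd.DataFrame(rows)
    base = pd.DataFrame({"user_id": users, "age": 44, "sex": "f",
                         "employment": "m", "audit": 9, "arm": "mrt"})
    out = pp.usage_summary(sessions, base)
    assert out.loc[0, "sessions_median"] == float(np.sort(counts)[10])


def test_usage_summary_warns_on_empty_arm():
    base = pd.DataFrame({"user_id": ["a", "b"], "age": 44, "sex": "f",
                         "employment": "m", "audit": 9,
                         "arm": ["mrt", "none"]})
    sessions = pd.DataFrame({"user_id": ["a"], "start": [pd.Timestamp(D1)],
                             "end": [pd.Timestamp(D1)],
                             "duration_s": [10.0], "n_views": [1]})
    with pytest.warns(RuntimeWarning, match="none"):
        out = pp.usage_summary(sessions, base)
    assert list(out["arm"]) == ["mrt"]
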