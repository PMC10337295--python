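import sys
import warnings
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import mrtengage as m


@pytest.fixture(scope="session")
def default_params():
    return m.GenerativeParams()


@pytest.fixture(scope="session")
def small_trial():
    """A 60-user, 12-day trial with events, shared across read-only tests."""
    config = m.TrialConfig(n_users=60, n_days=12, seed=7)
    params = m.GenerativeParams()
    baseline = m.generate_baseline(config, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = m.simulate_decision_table(config, params, baseline)
        rand, events = m.simulate_trial(config, params, baseline)
    imputed, _ = m.impute_modal(baseline)
    table_imputed = (table.drop(columns=["sex", "employment"])
                     .merge(imputed[["user_id", "sex", "employment"]],
                            on="user_id"))
    return {"config": config, "params": params, "baseline": baseline,
            "table": table, "table_imputed": table_imputed,
            "rand": rand, "events": events}


def events_frame(pairs):
    """Build an event log from (user_id, iso-timestamp) pairs."""
    return pd.DataFrame({
        "user_id": [p[0] for p in pairs],
        "timestamp": pd.to_datetime([p[1] for p in pairs]),
    })
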