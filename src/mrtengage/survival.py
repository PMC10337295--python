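"""Time-to-disengagement comparison across notification policies.

Product-limit (Kaplan-Meier) estimation of the disengagement survival
curve per arm, with Greenwood variance and log-transformed confidence
bands, and a k-sample log-rank test.  Event times are integer days in
[1, 23]; users with no qualifying 7-day gap are censored at day 23.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

Z95 = 1.959963984540054


@dataclass
class SurvivalCurve:
    """Kaplan-Meier curve over the distinct event times of one arm.

    ``survival[j]`` is the product-limit estimate just after ``times[j]``;
    ``variance`` is the Greenwood estimate; the CI comes from a normal
    interval on log S, clipped to [0, 1].  ``median`` is the first time at
    which survival drops to 0.5 or below (NaN if it never does).
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_risk": self.n_risk, "n_event": self.n_event,
        })


def km_estimate(time, event) -> SurvivalCurve:
    """Product-limit survival estimate for one arm.

    Ties are handled in the standard discrete-time way (all events at a
    day processed together); users censored at a day remain at risk
    through it.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("cannot estimate a survival curve from an empty arm")
    if len(time) != len(event):
        raise ValueError("time and event must have equal length")
    n = len(time)
    etimes = np.unique(time[event == 1])
    if len(etimes) == 0:
        return SurvivalCurve(times=etimes, n_risk=np.array([], dtype=int),
                             n_event=np.array([], dtype=int),
                             survival=np.array([]), variance=np.array([]),
                             ci_low=np.array([]), ci_high=np.array([]),
                             median=float("nan"))
    n_risk = np.array([(time >= t).sum() for t in etimes])
    n_event = np.array([((time == t) & (event == 1)).sum() for t in etimes])
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        green_terms = n_event / (n_risk * (n_risk - n_event))
        cum = np.cumsum(np.where(np.isfinite(green_terms), green_terms,
                                 np.inf))
        var = np.where(surv > 0, surv ** 2 * cum, 0.0)
        se_log = np.sqrt(cum)
        log_s = np.log(np.where(surv > 0, surv, 1.0))
        lo = np.where(surv > 0, np.exp(log_s - Z95 * se_log), 0.0)
        hi = np.where(surv > 0, np.exp(log_s + Z95 * se_log), 0.0)
    lo = np.clip(lo, 0.0, 1.0)
    hi = np.clip(hi, 0.0, 1.0)
    below = surv <= 0.5
    median = float(etimes[below.argmax()]) if below.any() else float("nan")
    return SurvivalCurve(times=etimes, n_risk=n_risk, n_event=n_event,
                         survival=surv, variance=var, ci_low=lo, ci_high=hi,
                         median=median)


def logrank(data: pd.DataFrame) -> tuple[float, int, float]:
    """k-sample log-rank test of equal disengagement distributions.

    ``data`` needs columns ``time``, ``event``, ``arm``.  Returns
    (chi2, df, p) with df = k - 1.
    """
    arms = data["arm"].unique()
    k = len(arms)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 arms")
    df = k - 1
    if int(data["event"].sum()) == 0:
        warnings.warn("no events in any arm; log-rank statistic is 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0, df, 1.0
    res = multivariate_logrank_test(data["time"], data["arm"], data["event"])
    return float(res.test_statistic), df, float(res.p_value)


def arm_curves(data: pd.DataFrame) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier curve per arm, keyed by arm label."""
    return {str(arm): km_estimate(grp["time"], grp["event"])
            for arm, grp in data.groupby("arm", sort=True)}


def curves_frame(curves: dict[str, SurvivalCurve]) -> pd.DataFrame:
    """Stack per-arm curves into one long CSV-ready frame."""
    frames = []
    for arm, curve in curves.items():
        f = curve.to_frame()
        f.insert(0, "arm", arm)
        frames.append(f)
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["arm", "time", "survival", "ci_low",
                                       "ci_high", "n_risk", "n_event"]))


def plot_curves(curves: dict[str, SurvivalCurve], path,
                horizon: Optional[int] = None) -> None:
    """Step-plot of the per-arm survival curves with CI bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, c in curves.items():
        t = np.r_[0.0, c.times]
        s = np.r_[1.0, c.survival]
        ax.step(t, s, where="post", label=arm)
        if len(c.times):
            ax.fill_between(np.r_[0.0, c.times], np.r_[1.0, c.ci_low],
                            np.r_[1.0, c.ci_high], step="post", alpha=0.15)
    ax.set_xlabel("days since download")
    ax.set_ylabel("fraction not yet disengaged")
    ax.set_ylim(0, 1.02)
    if horizon is not None:
        ax.set_xlim(0, horizon)
    ax.legend(title="policy")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
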