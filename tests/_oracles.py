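"""Independent brute-force oracles used to validate the estimators.

These deliberately avoid the package's solver paths: the excursion-effect
root is found by profiling the control intercept and bisecting the
centered treatment equation; the log-rank statistic is accumulated from
explicit per-event-time k x 2 tables; disengagement times come from an
exhaustive day-by-day scan.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def emee_root_oracle(A, Y, pt, W=None, span=15.0, n_grid=4001):
    """Root of the intercept-only excursion estimating equations.

    For fixed beta the alpha-equation sum W (e^{-A beta} Y - e^alpha) = 0
    gives e^alpha in closed form; the profiled beta-equation
    sum W (e^{-A beta} Y - e^alpha(beta)) (A - pt) = 0 is then solved by a
    grid scan for a sign change followed by bisection.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    pt = np.broadcast_to(np.asarray(pt, dtype=float), A.shape)
    W = np.ones_like(A) if W is None else np.asarray(W, dtype=float)

    def exp_alpha(beta):
        return float(np.sum(W * np.exp(-A * beta) * Y) / np.sum(W))

    def u_beta(beta):
        return float(np.sum(
            W * (np.exp(-A * beta) * Y - exp_alpha(beta)) * (A - pt)))

    grid = np.linspace(-span, span, n_grid)
    vals = np.array([u_beta(b) for b in grid])
    sign = np.sign(vals)
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(idx) == 0:
        exact = np.flatnonzero(vals == 0.0)
        if len(exact):
            beta = float(grid[exact[0]])
            return float(np.log(exp_alpha(beta))), beta
        raise RuntimeError("oracle found no sign change for beta")
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    beta = brentq(u_beta, lo, hi, xtol=1e-12)
    return float(np.log(exp_alpha(beta))), float(beta)


def logrank_oracle(time, event, group):
    """k-sample log-rank chi-square via explicit table accumulation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = np.array([(at_risk & (group == g)).sum() for g in labels],
                     dtype=float)
        d = np.array([((time == t) & (event == 1) & (group == g)).sum()
                      for g in labels], dtype=float)
        N, D = n.sum(), d.sum()
        O += d
        E += D * n / N
        if N > 1:
            frac = n / N
            V += (D * (N - D) / (N - 1)) * (np.diag(frac)
                                            - np.outer(frac, frac))
    diff = (O - E)[:-1]
    chi2 = float(diff @ np.linalg.solve(V[:-1, :-1], diff))
    return chi2, k - 1


def disengagement_oracle(used_days, horizon_days=23, run_days=7):
    """Earliest day starting a run of `run_days` unused days, by full scan."""
    used = set(int(d) for d in used_days)
    for d in range(1, horizon_days + 1):
        if all((d + j) not in used for j in range(run_days)):
            return d, 1
    return horizon_days, 0
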