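"""Causal excursion effects of notifications on the relative-risk scale.

Implements the weighted-and-centered estimating-equation estimator for the
marginal excursion effect of a binary time-varying treatment on a binary
proximal outcome.  The model is

    log E[Y_{t+1} | H_t, A_t] = g(H_t)' alpha + A_t f(S_t)' beta

so exp(beta) terms are relative risks.  With per-decision-point weight

    W_t = (ptilde_t / p_t)^{A_t} ((1 - ptilde_t) / (1 - p_t))^{1 - A_t}

the per-user estimating function is

    U_i(alpha, beta) = sum_t W_t (e^{-A_t f_t' beta} Y_t - e^{g_t' alpha})
                       * stack(g_t, (A_t - ptilde_t) f_t)

and (alpha_hat, beta_hat) is the root of the stacked equations
sum_i U_i = 0.  The key property of this construction is that beta remains
a consistent estimate of the (possibly moderated) causal excursion effect
even when the control model g' alpha is misspecified, because the centering
(A_t - ptilde_t) makes the beta-equations orthogonal to the nuisance model
under the known randomization probabilities.

Inference uses the sandwich covariance B^{-1} M B^{-T} / n built from
per-user contributions, with an optional small-sample correction that
inflates each user's residual vector by (I - H_i)^{-1}, the inverse of the
per-user hat matrix (the Mancl-DeRouen adjustment familiar from GEE),
recommended for trials with a few hundred users.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

CONTRASTS = ("pooled", "standard_vs_none", "new_vs_none")

#: default control (nuisance) adjustment set: baseline covariates plus the
#: two time-varying precision covariates
DEFAULT_CONTROLS = ("1", "age", "audit", "day_m1", "sex", "employment",
                    "opened_before_8pm", "opened_after_9pm_prev")


class EstimationSetError(ValueError):
    """Raised when a valid estimation set cannot be constructed."""


class DesignError(ValueError):
    """Raised for rank-deficient or degenerate design matrices."""


class DivergenceError(RuntimeError):
    """Raised when the estimating equations have no usable root."""


@dataclass(frozen=True)
class EmeeSpec:
    """Definition of one excursion-effect model.

    ``moderators`` define f(S_t) (intercept first; optional terms
    ``day_m1``, ``habituation``, ``already_engaged``); ``controls`` define
    g(H_t).  ``centering`` is the centering probability ptilde: ``None``
    means "equal to the randomization probability of treatment under the
    contrast" (all weights become 1), a float fixes it globally, and a
    callable receives the estimation-set frame and returns a vector.
    Non-intercept moderators are automatically added to the control set
    (their main effect must be adjusted for).
    """

    contrast: str = "pooled"
    moderators: tuple[str, ...] = ("1",)
    controls: tuple[str, ...] = DEFAULT_CONTROLS
    outcome: str = "y_hour"
    centering: Union[None, float, Callable] = None
    small_sample_correction: bool = True

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if not self.moderators or self.moderators[0] != "1":
            raise ValueError("moderators must be nonempty with intercept first")
        if not self.controls or self.controls[0] != "1":
            raise ValueError("controls must be nonempty with intercept first")


@dataclass
class EstimationSet:
    """Materialized arrays for one contrast, grouped contiguously by user."""

    user_codes: np.ndarray     # int codes, contiguous blocks
    user_ids: np.ndarray       # distinct ids in code order
    A: np.ndarray              # binary treatment
    p: np.ndarray              # randomization probability of A=1
    ptilde: np.ndarray         # centering probability
    W: np.ndarray              # weights
    Y: np.ndarray              # binary outcome
    F: np.ndarray              # moderator design (n x p)
    G: np.ndarray              # control design (n x q)
    f_names: tuple[str, ...]
    g_names: tuple[str, ...]

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    @property
    def n_points(self) -> int:
        return len(self.Y)


@dataclass
class EmeeFit:
    """Fitted excursion-effect model.

    ``beta`` is on the log-relative-risk scale; ``vcov`` is the sandwich
    covariance over the stacked (alpha, beta) vector.
    """

    alpha: np.ndarray
    beta: np.ndarray
    vcov: np.ndarray
    f_names: tuple[str, ...]
    g_names: tuple[str, ...]
    n_users: int
    n_points: int
    converged: bool
    iterations: int

    @property
    def vcov_beta(self) -> np.ndarray:
        q = len(self.alpha)
        return self.vcov[q:, q:]

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))


_TERM_BUILDERS = {
    "1": lambda df: np.ones(len(df)),
    "day_m1": lambda df: df["day"].to_numpy(dtype=float) - 1.0,
    "age": lambda df: df["age"].to_numpy(dtype=float),
    "audit": lambda df: df["audit"].to_numpy(dtype=float),
    "opened_before_8pm": lambda df: df["opened_before_8pm"].to_numpy(dtype=float),
    "opened_after_9pm_prev":
        lambda df: df["opened_after_9pm_prev"].to_numpy(dtype=float),
    "habituation": lambda df: df["habituation"].to_numpy(dtype=float),
    "already_engaged":
        lambda df: df["already_engaged_prev"].to_numpy(dtype=float),
}


def _design(df: pd.DataFrame, terms: Sequence[str]):
    """Expand feature terms into a design matrix with named columns."""
    cols, names = [], []
    for term in terms:
        if term == "sex":
            vals = df["sex"]
            if vals.isna().any():
                raise DesignError("sex has missing values; impute first")
            cols.append((vals == "male").to_numpy(dtype=float))
            names.append("sex_male")
        elif term == "employment":
            vals = df["employment"]
            if vals.isna().any():
                raise DesignError("employment has missing values; impute first")
            for cat in ("manual", "other"):
                cols.append((vals == cat).to_numpy(dtype=float))
                names.append(f"employment_{cat}")
        elif term in _TERM_BUILDERS:
            x = _TERM_BUILDERS[term](df)
            if np.isnan(x).any():
                raise DesignError(f"{term} has missing values; impute first")
            cols.append(x)
            names.append("intercept" if term == "1" else term)
        else:
            raise DesignError(f"unknown feature term: {term!r}")
    return np.column_stack(cols), tuple(names)


def build_contrast(records: pd.DataFrame, spec: EmeeSpec) -> EstimationSet:
    """Materialize the estimation set for one treatment contrast.

    ``pooled`` contrasts any notification vs none (p = p_standard + p_new);
    the type-specific contrasts drop the other type's rows and condition
    the randomization probability on the two remaining options
    (p = p_type / (p_type + p_none), 3/7 under the default 0.3/0.3/0.4).
    """
    if "arm" in records.columns:
        if (records["arm"] != "mrt").any():
            raise EstimationSetError(
                "estimation records must come from the MRT arm only; "
                "filter arm == 'mrt' first")
    df = records.sort_values(["user_id", "day"],
                             kind="mergesort").reset_index(drop=True)
    opt = df["option"].to_numpy()
    if spec.contrast == "pooled":
        A = (opt != "none").astype(float)
        p = (df["p_standard"] + df["p_new"]).to_numpy(dtype=float)
    else:
        kind = "standard" if spec.contrast == "standard_vs_none" else "new"
        drop = "new" if kind == "standard" else "standard"
        keep = opt != drop
        df = df[keep].reset_index(drop=True)
        opt = opt[keep]
        A = (opt == kind).astype(float)
        pk = df[f"p_{kind}"].to_numpy(dtype=float)
        pz = df["p_none"].to_numpy(dtype=float)
        p = pk / (pk + pz)
    if df.empty or len(np.unique(A)) < 2:
        raise EstimationSetError(
            "fewer than two distinct treatment levels after subsetting")
    if np.any((p <= 0) | (p >= 1)):
        raise EstimationSetError(
            "randomization probabilities must lie strictly in (0, 1)")

    if spec.centering is None:
        ptilde = p.copy()
    elif callable(spec.centering):
        ptilde = np.asarray(spec.centering(df), dtype=float)
    else:
        ptilde = np.full(len(df), float(spec.centering))
    if np.any((ptilde <= 0) | (ptilde >= 1)):
        raise EstimationSetError("centering probabilities must lie in (0, 1)")
    W = (ptilde / p) ** A * ((1 - ptilde) / (1 - p)) ** (1 - A)

    controls = list(spec.controls)
    for term in spec.moderators[1:]:
        if term not in controls:
            controls.append(term)
    F, f_names = _design(df, spec.moderators)
    G, g_names = _design(df, controls)
    codes, uniques = pd.factorize(df["user_id"])
    return EstimationSet(
        user_codes=codes, user_ids=np.asarray(uniques),
        A=A, p=p, ptilde=ptilde, W=W,
        Y=df[spec.outcome].to_numpy(dtype=float),
        F=F, G=G, f_names=f_names, g_names=g_names)


def _check_rank(es: EstimationSet) -> None:
    X = np.hstack([es.G, es.A[:, None] * es.F])
    names = list(es.g_names) + [f"A:{n}" for n in es.f_names]
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    bad = [names[j] for j in np.flatnonzero(diag < max(tol, 1e-10))]
    if bad:
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")


def _estimating_pieces(theta, es: EstimationSet):
    """Residuals e, stacked moment matrix m (weighted), and -de/dtheta."""
    q = es.G.shape[1]
    alpha, beta = theta[:q], theta[q:]
    with np.errstate(over="ignore"):
        mu = np.exp(es.G @ alpha)
        blipY = es.Y * np.exp(-es.A * (es.F @ beta))
    e = blipY - mu
    m = es.W[:, None] * np.hstack([es.G, (es.A - es.ptilde)[:, None] * es.F])
    d = np.hstack([mu[:, None] * es.G, (es.A * blipY)[:, None] * es.F])
    return e, m, d


def fit_emee(es: EstimationSet, spec: Optional[EmeeSpec] = None,
             max_iter: int = 50, tol: float = 1e-8) -> EmeeFit:
    """Solve the estimating equations by damped Newton-Raphson.

    Initialization: beta = 0 and the alpha intercept at the log of the
    weighted outcome mean among untreated points.  Each step solves the
    analytic Jacobian system and halves the step until the squared norm of
    the stacked equations decreases.  Convergence is declared when the
    largest absolute update falls below ``tol``.
    """
    correction = spec.small_sample_correction if spec is not None else True
    q, p_dim = es.G.shape[1], es.F.shape[1]
    sw1 = float(np.sum(es.W * es.A * es.Y))
    sw0 = float(np.sum(es.W * (1 - es.A) * es.Y))
    if sw1 == 0.0 or sw0 == 0.0:
        which = "treated" if sw1 == 0.0 else "untreated"
        raise DivergenceError(
            f"no {which} successes in the estimation set; the relative "
            "risk is not estimable")
    _check_rank(es)

    theta = np.zeros(q + p_dim)
    theta[0] = np.log(sw0 / float(np.sum(es.W * (1 - es.A))))
    e, m, d = _estimating_pieces(theta, es)
    U = m.T @ e
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        J = -(m.T @ d)
        try:
            step = np.linalg.solve(J, -U)
        except np.linalg.LinAlgError as err:
            raise DivergenceError(f"singular Jacobian at iteration {it}") \
                from err
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        norm0 = float(U @ U)
        scale, accepted = 1.0, False
        for _ in range(12):
            cand = theta + scale * step
            e, m_c, d_c = _estimating_pieces(cand, es)
            U_c = m_c.T @ e
            if np.isfinite(U_c).all() and float(U_c @ U_c) < norm0:
                theta, U, m, d = cand, U_c, m_c, d_c
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("estimating-equation solver did not converge to "
                      f"tolerance {tol} in {it} iterations", RuntimeWarning,
                      stacklevel=2)

    vcov = _sandwich(theta, es, correction)
    return EmeeFit(alpha=theta[:q], beta=theta[q:], vcov=vcov,
                   f_names=es.f_names, g_names=es.g_names,
                   n_users=es.n_users, n_points=es.n_points,
                   converged=converged, iterations=it)


def _sandwich(theta, es: EstimationSet, correction: bool) -> np.ndarray:
    """Sandwich covariance with optional per-user residual inflation."""
    e, m, d = _estimating_pieces(theta, es)
    bread = m.T @ d                      # n * B
    bread_inv = np.linalg.inv(bread)
    codes = es.user_codes
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    counts = np.diff(np.r_[starts, len(codes)])
    if not correction:
        Ui = np.add.reduceat(m * e[:, None], starts, axis=0)
        meat = Ui.T @ Ui
    elif counts.min() == counts.max():
        T = int(counts[0])
        n_u = len(starts)
        dim = m.shape[1]
        Mr = m.reshape(n_u, T, dim)
        Dr = d.reshape(n_u, T, dim)
        er = e.reshape(n_u, T)
        H = np.einsum("utd,dk,usk->uts", Dr, bread_inv, Mr, optimize=True)
        eye = np.eye(T)
        adj = np.linalg.solve(eye[None, :, :] - H, er[:, :, None])
        Ui = np.einsum("utd,ut->ud", Mr, adj[:, :, 0])
        meat = Ui.T @ Ui
    else:
        dim = m.shape[1]
        meat = np.zeros((dim, dim))
        for s, c in zip(starts, counts):
            sl = slice(s, s + c)
            Hi = d[sl] @ bread_inv @ m[sl].T
            ei = np.linalg.solve(np.eye(c) - Hi, e[sl])
            ui = m[sl].T @ ei
            meat += np.outer(ui, ui)
    vcov = bread_inv @ meat @ bread_inv.T
    return (vcov + vcov.T) / 2.0


def wald_test(fit: EmeeFit, index: int) -> tuple[float, float]:
    """Two-sided Wald z-test of one excursion-effect coefficient."""
    if not 0 <= index < len(fit.beta):
        raise IndexError(f"beta index {index} out of range "
                         f"(model has {len(fit.beta)} effect coefficients)")
    se = float(np.sqrt(fit.vcov_beta[index, index]))
    if se == 0.0:
        z = 0.0 if fit.beta[index] == 0.0 else np.inf * np.sign(fit.beta[index])
    else:
        z = float(fit.beta[index]) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def _rr_row(label, fit, combo, z_crit=1.959963984540054):
    combo = np.asarray(combo, dtype=float)
    est = float(combo @ fit.beta)
    var = float(combo @ fit.vcov_beta @ combo)
    se = np.sqrt(max(var, 0.0))
    return {"label": label, "rr": float(np.exp(est)),
            "ci_low": float(np.exp(est - z_crit * se)),
            "ci_high": float(np.exp(est + z_crit * se)),
            "log_estimate": est, "se_log": float(se)}


def report_effects(fit: EmeeFit, spec: EmeeSpec) -> pd.DataFrame:
    """Render a fitted model as relative risks with 95% Wald intervals.

    * marginal model (f = [1]): one pooled relative-risk row;
    * time model (f = [1, day-1]): relative risk on the first day after
      download plus the multiplicative change in effect per day;
    * binary-moderator model: relative risk in the "no" and "yes" states
      and their ratio, with delta-method CIs on the log scale.
    """
    mods = spec.moderators
    if tuple(mods) == ("1",):
        rows = [_rr_row("marginal_rr", fit, [1.0])]
    elif tuple(mods) == ("1", "day_m1"):
        rows = [_rr_row("rr_day1", fit, [1.0, 0.0]),
                _rr_row("change_per_day", fit, [0.0, 1.0])]
    elif len(mods) == 2:
        rows = [_rr_row("rr_no", fit, [1.0, 0.0]),
                _rr_row("rr_yes", fit, [1.0, 1.0]),
                _rr_row("ratio_yes_vs_no", fit, [0.0, 1.0])]
    else:
        raise ValueError(
            f"no reporting template for moderator set {mods}; use _rr_row "
            "with an explicit contrast vector")
    out = pd.DataFrame(rows)
    out.insert(0, "contrast", spec.contrast)
    out.insert(1, "outcome", spec.outcome)
    return out
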