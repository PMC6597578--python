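"""Survival machinery: Kaplan–Meier, log-rank, Cox partial likelihood,
and component-wise likelihood-based boosting.

The Kaplan–Meier estimator and the (unweighted) log-rank test are standard
and delegated to lifelines behind this module's surface.  The Cox
partial-likelihood Newton–Raphson fit and the boosting variable selector
are implemented here: boosting needs per-candidate score/information of the
partial likelihood at an arbitrary linear-predictor offset, which no
off-the-shelf fitting interface exposes.

Ties are handled with the Efron approximation by default (Breslow optional).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats


class FitError(RuntimeError):
    """Raised when an iterative fit fails to converge."""

    def __init__(self, msg, beta=None, grad_norm=None):
        super().__init__(msg)
        self.beta = beta
        self.grad_norm = grad_norm


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV with columns sample, time_months, event, grade,
    size_cm, nodes_positive, cohort."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["time_months"] < 0).any():
        raise ValueError("negative survival times")
    return df


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_estimate(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray | None = None
) -> dict:
    """Product-limit survival estimate per group.

    Returns ``{group: {"survival": Series indexed by time, "median": float,
    "n": int, "events": int}}``; the median is NaN when the curve never
    crosses 0.5 (reported as undefined rather than guessed)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if groups is None:
        groups = np.zeros(len(time), dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        surv = kmf.survival_function_.iloc[:, 0]
        out[g] = {
            "survival": surv,
            "median": float(kmf.median_survival_time_),
            "n": int(m.sum()),
            "events": int(event[m].sum()),
        }
    return out


def logrank_test(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[float, int, float]:
    """Unweighted k-group log-rank test; returns (chi2, df, p)."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    if np.asarray(event).sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(np.asarray(time, float), groups, np.asarray(event, int))
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def rmst(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Restricted mean survival time of the KM curve up to ``horizon``."""
    kmf = KaplanMeierFitter().fit(np.asarray(time, float), np.asarray(event, int))
    return float(restricted_mean_survival_time(kmf, t=horizon))


def fast_logrank(time: np.ndarray, event: np.ndarray, groups: np.ndarray):
    """Numpy k-group log-rank (same statistic as :func:`logrank_test`);
    used on hot paths where per-gene lifelines overhead matters."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    codes, labels = pd.factorize(np.asarray(groups))
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs at least two groups")
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], codes[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    # at-risk counts per group just before each unique time
    counts = np.zeros((len(uniq), k))
    deaths = np.zeros((len(uniq), k))
    at_risk_total = n - start
    for j in range(k):
        cum = np.concatenate([[0], np.cumsum(g == j)])
        counts[:, j] = (g == j).sum() - cum[start]
        dcum = np.concatenate([[0], np.cumsum((g == j) & (e == 1))])
        deaths[:, j] = dcum[np.append(start[1:], n)] - dcum[start]
    d_tot = deaths.sum(axis=1)
    use = d_tot > 0
    Nt = at_risk_total[use].astype(float)
    Dt = d_tot[use]
    P = counts[use] / Nt[:, None]
    O = deaths[use].sum(axis=0)
    E = (Dt[:, None] * P).sum(axis=0)
    c = Dt * (Nt - Dt) / np.maximum(Nt - 1, 1)
    V = -np.einsum("t,ti,tj->ij", c, P, P)
    V[np.diag_indices(k)] += (c[:, None] * P).sum(axis=0)
    diff = (O - E)[: k - 1]
    chi2 = float(diff @ np.linalg.solve(V[: k - 1, : k - 1], diff))
    return chi2, k - 1, float(stats.chi2.sf(chi2, k - 1))


def fast_km_rmst(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Restricted mean survival time from a numpy product-limit curve
    (equals :func:`rmst`); hot-path companion of :func:`fast_logrank`."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    uniq, start = np.unique(t, return_index=True)
    n_at_risk = len(t) - start
    d = np.add.reduceat(e, start)
    surv = np.cumprod(1.0 - d / n_at_risk)
    knots = np.concatenate([[0.0], uniq])
    s_vals = np.concatenate([[1.0], surv])
    knots_c = np.clip(knots, None, horizon)
    widths = np.diff(np.append(knots_c, horizon))
    return float(np.sum(s_vals * widths))


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties), Newton-Raphson


def _risk_groups(time: np.ndarray, event: np.ndarray):
    """Sort by time; yield per-unique-event-time risk-set / tie-group index
    arrays.  Returns (order, list of (risk_idx, death_idx)) in sorted space."""
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    groups = []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = np.arange(i, j)[e[i:j] == 1]
        if len(deaths):
            groups.append((np.arange(i, n), deaths))
        i = j
    return order, groups


def cox_partial_loglik(
    time: np.ndarray, event: np.ndarray, eta: np.ndarray, ties: str = "efron"
) -> float:
    """Cox partial log-likelihood at linear predictor eta (Efron tie
    correction by default)."""
    order, groups = _risk_groups(np.asarray(time, float), np.asarray(event, int))
    eta = np.asarray(eta, float)[order]
    w = np.exp(eta)
    ll = 0.0
    for risk, deaths in groups:
        d = len(deaths)
        s_risk = w[risk].sum()
        s_death = w[deaths].sum()
        ll += eta[deaths].sum()
        ell = np.arange(d) / d if ties == "efron" else np.zeros(d)
        ll -= np.log(s_risk - ell * s_death).sum()
    return float(ll)


def _cox_derivatives(time, event, X, beta, ties="efron"):
    """(loglik, gradient, Hessian) of the Cox partial likelihood
    (Efron tie correction by default; Breslow sets the correction to 0)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    order, groups = _risk_groups(time, event)
    Xs = X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    p = X.shape[1]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for risk, deaths in groups:
        d = len(deaths)
        wr = w[risk]
        xr = Xs[risk]
        s0_r = wr.sum()
        s1_r = wr @ xr
        s2_r = (wr[:, None] * xr).T @ xr
        wd = w[deaths]
        xd = Xs[deaths]
        s0_d = wd.sum()
        s1_d = wd @ xd
        s2_d = (wd[:, None] * xd).T @ xd
        ll += eta[deaths].sum()
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            s0 = s0_r - f * s0_d
            s1 = s1_r - f * s1_d
            s2 = s2_r - f * s2_d
            ll -= np.log(s0)
            mu = s1 / s0
            grad -= mu
            hess -= s2 / s0 - np.outer(mu, mu)
        grad += xd.sum(axis=0)
    return ll, grad, hess


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    names: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": np.exp(self.coef),
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.names or [f"x{i}" for i in range(len(self.coef))],
        )


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    ties: str = "efron",
) -> CoxFit:
    """Newton–Raphson maximization of the Efron-tied Cox partial likelihood.

    Converges when the gradient norm drops below ``tol``; raises
    :class:`FitError` (carrying the last iterate) otherwise.  Warns when
    the number of events is below the number of covariates.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate in Cox design matrix")
    event = np.asarray(event, int)
    if event.sum() < X.shape[1]:
        import warnings

        warnings.warn("fewer events than covariates; estimates may be unstable")
    beta = np.zeros(X.shape[1])
    ll = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_derivatives(time, event, X, beta, ties=ties)
        gnorm = np.linalg.norm(grad)
        if gnorm < tol:
            cov = np.linalg.inv(-hess)
            return CoxFit(beta, np.sqrt(np.diag(cov)), ll, it, names)
        step = np.linalg.solve(-hess, grad)
        # step-halving to keep the likelihood non-decreasing
        for _ in range(30):
            cand = beta + step
            ll_new = cox_partial_loglik(time, event, X @ cand, ties=ties)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta = beta + step
    raise FitError(
        f"Cox Newton-Raphson did not converge in {max_iter} iterations "
        f"(gradient norm {gnorm:.3g})",
        beta=beta, grad_norm=gnorm,
    )


# ---------------------------------------------------------------------------
# Component-wise likelihood-based boosting


def _univariate_score_info(time, event, X, eta):
    """Per-candidate score U_j and information I_j of the Efron partial
    likelihood with respect to a single coefficient at offset eta.

    U_j = sum_events [x_dj - E_w(x_j)],  I_j = sum_events Var_w(x_j),
    with risk-set weights w = exp(eta); vectorized over candidates.
    """
    order, groups = _risk_groups(np.asarray(time, float), np.asarray(event, int))
    Xs = np.asarray(X, float)[order]
    w = np.exp(np.asarray(eta, float)[order])
    p = Xs.shape[1]
    U = np.zeros(p)
    I = np.zeros(p)
    for risk, deaths in groups:
        d = len(deaths)
        wr = w[risk]
        xr = Xs[risk]
        s0_r = wr.sum()
        s1_r = wr @ xr
        s2_r = wr @ (xr**2)
        wd = w[deaths]
        xd = Xs[deaths]
        s0_d = wd.sum()
        s1_d = wd @ xd
        s2_d = wd @ (xd**2)
        U += xd.sum(axis=0)
        for l in range(d):
            f = l / d
            s0 = s0_r - f * s0_d
            s1 = s1_r - f * s1_d
            s2 = s2_r - f * s2_d
            mu = s1 / s0
            U -= mu
            I += s2 / s0 - mu**2
    return U, I


@dataclass
class BoostFit:
    """Sparse boosted Cox model: coefficient vector plus the path metadata."""

    coef: pd.Series
    selection_order: list[tuple[int, str]]
    n_steps: int
    penalty: float
    cv_curve: np.ndarray | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        nz = self.coef[self.coef != 0]
        payload = {
            "coefficients": {g: float(v) for g, v in nz.items()},
            "selection_order": [[s, g] for s, g in self.selection_order],
            "n_steps": self.n_steps,
            "penalty": self.penalty,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _boost_path(time, event, X, penalty, n_steps):
    """Run component-wise boosting; yields (selected index, delta) per step."""
    n = X.shape[0]
    eta = np.zeros(n)
    path = []
    for _ in range(n_steps):
        U, I = _univariate_score_info(time, event, X, eta)
        delta = U / (I + penalty)
        # penalized-likelihood gain of a one-parameter quadratic step:
        # U*delta - 0.5*(I+penalty)*delta^2 = 0.5 * U^2 / (I + penalty)
        gain = 0.5 * U**2 / (I + penalty)
        j = int(np.argmax(gain))
        eta = eta + delta[j] * X[:, j]
        path.append((j, float(delta[j])))
        yield j, float(delta[j]), eta


def coxboost_select(
    time: np.ndarray,
    event: np.ndarray,
    X: pd.DataFrame,
    penalty: float | None = None,
    max_steps: int = 200,
    cv_folds: int = 10,
    seed: int = 0,
    patience: int = 20,
    n_steps: int | None = None,
) -> BoostFit:
    """Component-wise likelihood-based boosting with CV-chosen step count.

    At every step the penalized univariate update ``delta_j = U_j/(I_j+pen)``
    is computed for each candidate against the current linear predictor; the
    candidate with the largest penalized-likelihood gain is updated.  The
    number of steps maximizes the mean event-stratified ``cv_folds``-fold
    cross-validated validation partial log-likelihood (difference between
    the full-fit and train-fit partial likelihoods at the trained
    coefficients), searched up to ``max_steps`` with early stopping after
    ``patience`` consecutive non-improving steps.

    Candidates are standardized internally (mean 0, unit variance);
    coefficients are reported on the standardized scale.  Default penalty
    follows the 9-times-number-of-events convention of likelihood-based
    boosting for the Cox model.  Passing ``n_steps`` fixes the step count
    and skips cross-validation.
    """
    if penalty is not None and penalty <= 0:
        raise ValueError("boosting penalty must be > 0")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    genes = list(X.columns)
    Xm = np.asarray(X, float)
    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xm = (Xm - mu) / sd
    if penalty is None:
        penalty = 9.0 * max(int(event.sum()), 1)

    if n_steps is not None:
        best_step = int(n_steps)
        cv_curve = None
        return _boost_refit(time, event, Xm, genes, penalty, best_step, None, seed)

    # --- CV over the step count
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(event, cv_folds, rng)
    fold_state = []

    def _fold_val(st):
        # validation pl: pl(train+test) - pl(train), the standard CV
        # partial-likelihood contribution of the held-out fold
        tr, te = st["tr"], st["te"]
        full = np.concatenate([tr, te])
        return cox_partial_loglik(
            time[full], event[full], Xm[full] @ st["beta"]
        ) - cox_partial_loglik(time[tr], event[tr], Xm[tr] @ st["beta"])

    for tr, te in folds:
        fold_state.append(
            {
                "tr": tr, "te": te,
                "gen": _boost_path(time[tr], event[tr], Xm[tr], penalty, max_steps),
                "beta": np.zeros(Xm.shape[1]),
            }
        )
    cv_curve = [float(np.mean([_fold_val(st) for st in fold_state]))]  # null model
    best_step, best_val = 0, cv_curve[0]
    for step in range(1, max_steps + 1):
        vals = []
        for st in fold_state:
            j, delta, _ = next(st["gen"])
            st["beta"][j] += delta
            vals.append(_fold_val(st))
        cv_curve.append(float(np.mean(vals)))
        if cv_curve[-1] > best_val:
            best_val, best_step = cv_curve[-1], step
        if step - best_step >= patience:
            break

    return _boost_refit(
        time, event, Xm, genes, penalty, best_step, np.asarray(cv_curve), seed
    )


def _boost_refit(time, event, Xm, genes, penalty, best_step, cv_curve, seed):
    """Full-data boosting run for a fixed step count."""
    beta = np.zeros(Xm.shape[1])
    order_list: list[tuple[int, str]] = []
    for s, (j, delta, _) in enumerate(
        _boost_path(time, event, Xm, penalty, best_step), start=1
    ):
        if beta[j] == 0:
            order_list.append((s, genes[j]))
        beta[j] += delta
    return BoostFit(
        coef=pd.Series(beta, index=genes),
        selection_order=order_list,
        n_steps=best_step,
        penalty=float(penalty),
        cv_curve=cv_curve,
        seed=seed,
    )


def _stratified_folds(event: np.ndarray, k: int, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    """Event-stratified k-fold index split (each fold holds events)."""
    idx_e = np.flatnonzero(event == 1)
    idx_c = np.flatnonzero(event == 0)
    rng.shuffle(idx_e)
    rng.shuffle(idx_c)
    folds = [np.concatenate([idx_e[i::k], idx_c[i::k]]) for i in range(k)]
    out = []
    all_idx = np.arange(len(event))
    for f in folds:
        mask = np.ones(len(event), bool)
        mask[f] = False
        out.append((all_idx[mask], np.sort(f)))
    return out
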