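"""Survival analysis and the k-of-n methylation marker panel.

Kaplan-Meier curves and the log-rank test are computed with lifelines;
the Cox proportional-hazards fit for cumulative risk of multiple binary
methylation factors is a partial-likelihood Newton maximisation authored
here (Breslow handling of tied event times, convergence at gradient norm
< 1e-8) so that the score can be inspected at the optimum.

The marker panel predicts metastasis when at least k of n binary
hypermethylation calls are positive.  Sweeping k from n+1 (predict
nobody) down to 0 (predict everybody) traces a ROC with n+2 operating
points; AUC is the trapezoidal area under that discrete curve, which is
the natural choice for a count-of-markers classifier with only ordinal
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


class ConvergenceError(RuntimeError):
    """Cox fit failed to converge (possible separation)."""


@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray          # distinct event times, ascending
    at_risk: np.ndarray        # subjects at risk just before each time
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    names: tuple[str, ...]
    coef: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    p: np.ndarray
    score_norm: float
    n_iter: int


@dataclass(frozen=True)
class PanelEvaluation:
    genes: tuple[str, ...]
    k: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    roc: tuple[tuple[float, float], ...]   # (FPR, TPR) for k = n+1 .. 0
    auc: float


def _check_times(times: np.ndarray) -> None:
    if (times <= 0).any():
        raise ValueError("survival times must be positive")


def km_curve(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimator.

    Tied events are handled simultaneously; censored subjects leave the
    risk set just after their time.  With no events the curve is S(t) = 1
    throughout (empty step list).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("at least one record is required")
    _check_times(t)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times_out = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy()
    # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d)))
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
    var = surv**2 * gw
    return SurvivalCurve(
        times=times_out, at_risk=n.astype(int), survival=surv, variance=var
    )


def logrank(
    times_a: Sequence[float], events_a: Sequence[bool],
    times_b: Sequence[float], events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    _check_times(ta)
    _check_times(tb)
    res = _ll_logrank(
        ta, tb,
        event_observed_A=np.asarray(events_a, dtype=bool),
        event_observed_B=np.asarray(events_b, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


def _cox_score_hess(
    beta: np.ndarray, t: np.ndarray, e: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, score and information.

    Arrays must be sorted by time descending so that the risk set at an
    event time is a prefix and cumulative sums apply.
    """
    eta = X @ beta
    eta -= eta.max()  # guard overflow; PL invariant to the shift within a risk set sum ratio
    w = np.exp(eta)
    cw = np.cumsum(w)
    cxw = np.cumsum(X * w[:, None], axis=0)
    p = X.shape[1]
    cxxw = np.cumsum(X[:, :, None] * X[:, None, :] * w[:, None, None], axis=0)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # rows i..j-1 share this time; risk set = rows 0..j-1
        ev = np.arange(i, j)[e[i:j]]
        d = ev.size
        if d:
            S0 = cw[j - 1]
            S1 = cxw[j - 1]
            S2 = cxxw[j - 1]
            xbar = S1 / S0
            loglik += float(eta[ev].sum() - d * np.log(S0))
            score += X[ev].sum(axis=0) - d * xbar
            info += d * (S2 / S0 - np.outer(xbar, xbar))
        i = j
    return loglik, score, info


def cox_cumulative(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame | np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton iteration (Breslow ties).

    Intended for the cumulative-risk assessment of a few binary
    methylation factors.  Raises ConvergenceError on non-convergence or
    (quasi-)separation instead of returning a silently bad fit.  p-values
    are two-sided Wald.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    _check_times(t)
    if isinstance(covariates, pd.DataFrame):
        names = tuple(map(str, covariates.columns))
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[0] != t.size:
        raise ValueError("covariate rows must match the number of subjects")
    const = [names[j] for j in range(X.shape[1]) if np.unique(X[:, j]).size == 1]
    if const:
        raise ValueError(f"covariates constant across subjects: {const}")

    order = np.argsort(-t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]

    beta = np.zeros(X.shape[1])
    score_norm = np.inf
    for it in range(1, max_iter + 1):
        _, score, info = _cox_score_hess(beta, ts, es, Xs)
        score_norm = float(np.linalg.norm(score))
        if score_norm < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 15:
            raise ConvergenceError(
                "coefficients diverged (possible separation): "
                f"beta={np.round(beta, 2)}"
            )
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} Newton iterations "
            f"(score norm {score_norm:.2e})"
        )
    _, _, info = _cox_score_hess(beta, ts, es, Xs)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    from scipy.stats import norm as _norm

    z = beta / se
    p = 2 * _norm.sf(np.abs(z))
    return CoxResult(
        names=names, coef=beta, hazard_ratio=np.exp(beta),
        se=se, p=p, score_norm=score_norm, n_iter=it,
    )


def cox_score_norm(
    beta: np.ndarray,
    times: Sequence[float],
    events: Sequence[bool],
    covariates: np.ndarray,
) -> float:
    """Norm of the partial-likelihood score at ``beta`` (stationarity check)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(-t, kind="stable")
    _, score, _ = _cox_score_hess(np.asarray(beta, dtype=float), t[order], e[order], X[order])
    return float(np.linalg.norm(score))


def panel_evaluate(
    calls: pd.DataFrame,
    truth: Sequence[bool],
    k: int = 4,
) -> PanelEvaluation:
    """Evaluate the k-of-n methylation marker panel.

    ``calls`` is a boolean patients x genes matrix of hypermethylation
    calls; ``truth`` the observed metastasis status.  A patient is
    predicted positive when at least ``k`` markers are methylated.  The
    ROC is traced by sweeping the threshold from n+1 down to 0 and AUC is
    the trapezoid under it.
    """
    n_genes = calls.shape[1]
    if not 0 <= k <= n_genes:
        raise ValueError(f"k must lie in 0..{n_genes}")
    y = np.asarray(truth, dtype=bool)
    if y.size != calls.shape[0]:
        raise ValueError("truth must be defined for every patient")
    counts = calls.to_numpy(dtype=bool).sum(axis=1)

    def confusion(k_thr: int) -> tuple[int, int, int, int]:
        pred = counts >= k_thr
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        tn = int(np.sum(~pred & ~y))
        fn = int(np.sum(~pred & y))
        return tp, fp, tn, fn

    def rates(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
        tpr = tp / (tp + fn) if tp + fn else float("nan")
        fpr = fp / (fp + tn) if fp + tn else float("nan")
        return fpr, tpr

    roc = []
    for k_thr in range(n_genes + 1, -1, -1):
        roc.append(rates(*confusion(k_thr)))
    fpr = np.array([r[0] for r in roc])
    tpr = np.array([r[1] for r in roc])
    auc = float(np.trapezoid(tpr, fpr))

    tp, fp, tn, fn = confusion(k)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return PanelEvaluation(
        genes=tuple(map(str, calls.columns)), k=k,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        roc=tuple((float(a), float(b)) for a, b in roc),
        auc=auc,
    )
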