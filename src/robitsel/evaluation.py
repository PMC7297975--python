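"""Cross-validatory scoring of feature subsets.

Each candidate subset is refit with a logistic regression whose non-intercept
coefficients carry a Student-t (by default Cauchy) log-density penalty — the
heavy tail keeps estimates finite under separation without flattening large
effects — and scored by leave-one-out cross-validation on the training cases.
Four metrics are reported: error rate at a 0.5 cut, AMLP (average minus log
predictive probability at the true labels, in nats; a cross-entropy-style
score that punishes confident misclassification), AUROC and AUPRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSet",
    "PLRFit",
    "fit_plr_t_penalty",
    "loocv_subset",
    "metric_set",
    "amlp",
    "auroc",
    "auprc",
]

_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class MetricSet:
    """The four predictive scores for one set of probability predictions."""

    error_rate: float
    amlp: float
    auroc: float
    auprc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "error_rate": self.error_rate,
            "amlp": self.amlp,
            "auroc": self.auroc,
            "auprc": self.auprc,
        }


@dataclass
class PLRFit:
    """Result of a t-penalized logistic fit."""

    beta: np.ndarray
    converged: bool
    grad_norm: float
    objective: float


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log1pexp(z):
    """log(1 + exp(z)) without overflow."""
    out = np.where(z > 0, z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return out


def _objective_grad_hess(beta, X, y, df, scale):
    """Penalized logistic log-likelihood (to maximize), gradient, Hessian.

    Penalty: sum_j log t(beta_j; df, scale) over non-intercept coefficients,
    up to constants.
    """
    z = X @ beta
    # log-lik = sum y*z - log(1+exp(z))
    ll = float(np.sum(y * z - _log1pexp(z)))
    mu = _sigmoid(z)
    grad = X.T @ (y - mu)
    W = mu * (1.0 - mu)
    hess = -(X.T * W) @ X
    b = beta[1:]
    s2 = scale * scale
    denom = df * s2 + b * b
    ll += float(np.sum(-(df + 1.0) / 2.0 * np.log1p(b * b / (df * s2))))
    grad[1:] += -(df + 1.0) * b / denom
    hess[1:, 1:] += np.diag(-(df + 1.0) * (df * s2 - b * b) / denom**2)
    return ll, grad, hess


def _newton(beta0, X, y, df, scale, max_iter, tol):
    beta = beta0.copy()
    f, g, H = _objective_grad_hess(beta, X, y, df, scale)
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            break
        # Damp the (possibly indefinite) Hessian until it is negative definite.
        tau = 0.0
        A = -H
        for _ in range(60):
            try:
                L = np.linalg.cholesky(A + tau * np.eye(A.shape[0]))
                break
            except np.linalg.LinAlgError:
                tau = max(2.0 * tau, 1e-6)
        step = np.linalg.solve(A + tau * np.eye(A.shape[0]), g)
        # Backtracking line search on the objective (we maximize f).
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            fc, gc, Hc = _objective_grad_hess(cand, X, y, df, scale)
            if fc > f + 1e-4 * t * float(g @ step):
                beta, f, g, H = cand, fc, gc, Hc
                break
            t *= 0.5
        else:
            break
    return beta, f, float(np.linalg.norm(g))


def fit_plr_t_penalty(
    X: np.ndarray,
    y: np.ndarray,
    penalty_df: float = 1.0,
    penalty_scale: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PLRFit:
    """Maximize the t-penalized logistic log-likelihood by damped Newton.

    ``X`` is an n x (k+1) design with intercept column; the intercept is
    unpenalized.  The penalized objective is non-concave at subset scale, so
    the optimizer restarts from zero and from a ridge-regularized solution
    and keeps the better stationary point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    k1 = X.shape[1]
    starts = [np.zeros(k1)]
    # Ridge start: a few Newton steps on an L2-penalized logistic objective.
    bridge = np.zeros(k1)
    for _ in range(25):
        z = X @ bridge
        mu = _sigmoid(z)
        g = X.T @ (y - mu) - 1.0 * np.r_[0.0, bridge[1:]]
        W = np.clip(mu * (1 - mu), 1e-6, None)
        H = (X.T * W) @ X + np.diag(np.r_[1e-8, np.ones(k1 - 1)])
        bridge = bridge + np.linalg.solve(H, g)
        if np.linalg.norm(g) < 1e-8:
            break
    starts.append(bridge)

    best = None
    for b0 in starts:
        beta, f, gnorm = _newton(b0, X, y, penalty_df, penalty_scale, max_iter, tol)
        if best is None or f > best[1]:
            best = (beta, f, gnorm)
    beta, f, gnorm = best
    converged = gnorm < tol
    if not converged:
        logger.warning("t-penalized logistic fit stopped with gradient norm %.2e", gnorm)
    return PLRFit(beta=beta, converged=converged, grad_norm=gnorm, objective=f)


def loocv_subset(
    data: Dataset,
    subset,
    covariates=None,
    penalty_df: float = 1.0,
    penalty_scale: float = 1.0,
    return_probs: bool = False,
):
    """Leave-one-out cross-validated metrics for one feature subset.

    ``subset`` holds 0-based feature indices (column j of the feature block,
    i.e. column j+1 of ``data.X``); ``covariates`` are extra feature indices
    appended to every refit.  For each held-out case the model is refit on
    the remaining n-1 cases and P(y=1) recorded; the pooled probabilities
    give the MetricSet.
    """
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if data.n < 3:
        raise ValueError("need at least three cases for LOOCV")
    cols = [0] + [j + 1 for j in subset]
    if covariates is not None:
        cols += [j + 1 for j in covariates if (j + 1) not in cols]
    X = data.X[:, cols]
    y = data.y
    probs = np.empty(data.n)
    for i in range(data.n):
        keep = np.arange(data.n) != i
        if len(np.unique(y[keep])) < 2:
            logger.info("LOOCV fold %d has a single class; penalty regularizes the fit", i)
        fit = fit_plr_t_penalty(X[keep], y[keep], penalty_df, penalty_scale)
        probs[i] = _sigmoid_scalar(X[i] @ fit.beta)
    m = metric_set(probs, y)
    if return_probs:  # per-fold probabilities, e.g. for audit dumps
        return m, probs
    return m


def _sigmoid_scalar(z: float) -> float:
    return float(_sigmoid(np.array([z]))[0])


def metric_set(prob_class1: np.ndarray, y: np.ndarray) -> MetricSet:
    """All four metrics from P(y=1) predictions and true labels."""
    prob_class1 = np.asarray(prob_class1, dtype=float)
    y = np.asarray(y)
    err = float(np.mean((prob_class1 > 0.5).astype(int) != y))
    p_true = np.where(y == 1, prob_class1, 1.0 - prob_class1)
    return MetricSet(
        error_rate=err,
        amlp=amlp(p_true),
        auroc=auroc(prob_class1, y),
        auprc=auprc(prob_class1, y),
    )


def amlp(prob_at_true_label) -> float:
    """Average minus log predictive probability at the observed labels."""
    p = np.asarray(prob_at_true_label, dtype=float)
    if np.any(p <= 0):
        logger.warning("zero predictive probability clipped to %.0e", _PROB_FLOOR)
        p = np.clip(p, _PROB_FLOOR, None)
    return float(np.mean(-np.log(p)))


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        logger.warning("AUROC undefined with a single class")
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        logger.warning("AUPRC undefined with a single class")
        return float("nan")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))
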