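"""Robit (t-link) binary regression: likelihood, gradients, predictions.

The robit model replaces the Gaussian latent noise of a probit model with a
scaled Student-t variable::

    y_i = 1{z_i > 0},   z_i = x_i @ beta + eps_i,   eps_i ~ T(alpha0, omega0)

where ``T(alpha, omega)`` is the Student-t distribution with ``alpha`` degrees
of freedom and scale ``sqrt(omega)``.  Integrating ``z_i`` out gives

    P(y_i = 1 | x_i, beta) = T_cdf(x_i @ beta; alpha0, omega0).

With ``alpha0 = 1`` (the default, a Cauchy latent) the link has far heavier
tails than probit or logit, so a handful of extreme outlying cases cannot
dominate the fit.  Only ``beta / sqrt(omega0)`` is likelihood-identifiable, so
``omega0`` is fixed; the default 0.5 makes the link resemble the logistic near
the origin while keeping the heavy tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RobitConfig",
    "Dataset",
    "student_t_cdf",
    "student_t_logcdf",
    "log_likelihood",
    "neg_log_posterior_and_gradient",
    "posterior_average_prediction",
]

# Guard against overflow in z**2 inside the Cauchy-CDF closed forms; far
# beyond this the CDF is constant at machine precision anyway.
_Z_CLAMP = 1e150


@dataclass(frozen=True)
class RobitConfig:
    """Fixed hyperparameters of the robit likelihood and coefficient prior.

    alpha0, omega0
        Degrees of freedom and squared scale of the latent noise t
        distribution.  alpha0=1 (Cauchy) and omega0=0.5 are the defaults.
    alpha1, omega1
        Degrees of freedom and squared scale of the coefficient prior t
        distribution.  alpha1=1 with sqrt(omega1)=e^-5 gives the small-scale
        Cauchy ("hyper-LASSO") prior that shrinks noise coefficients hard
        while leaving large signals essentially unshrunk.
    """

    alpha0: float = 1.0
    omega0: float = 0.5
    alpha1: float = 1.0
    omega1: float = math.exp(-10.0)

    def __post_init__(self) -> None:
        for name in ("alpha0", "omega0", "alpha1", "omega1"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive finite number")


@dataclass
class Dataset:
    """Design matrix with an explicit intercept column plus binary labels.

    ``X`` is n x (p+1) with column 0 identically 1; ``y`` holds 0/1 labels.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of cases")
        if not np.all(self.X[:, 0] == 1.0):
            raise ValueError("column 0 of X must be the all-ones intercept")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        labels = np.unique(self.y)
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("y must contain only 0/1 labels")
        self.y = self.y.astype(int)
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(1, self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1] - 1:
            raise ValueError("feature_names must have one entry per non-intercept column")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1] - 1


def _validate_t_params(alpha: float, omega: float) -> None:
    if alpha <= 0 or omega <= 0:
        raise ValueError("alpha and omega must be positive")


def student_t_cdf(x, alpha: float = 1.0, omega: float = 0.5):
    """CDF of the scaled Student-t distribution T(alpha, omega) at ``x``.

    For alpha=1 (Cauchy) the closed form 1/2 + arctan(x/sqrt(omega))/pi is
    used; other degrees of freedom go through the generic scaled-t CDF.
    """
    _validate_t_params(alpha, omega)
    z = np.clip(np.asarray(x, dtype=float) / math.sqrt(omega), -_Z_CLAMP, _Z_CLAMP)
    if alpha == 1.0:
        return 0.5 + np.arctan(z) / np.pi
    return stats.t.cdf(z, df=alpha)


def student_t_logcdf(x, alpha: float = 1.0, omega: float = 0.5):
    """log CDF of T(alpha, omega), stable deep into the lower tail.

    A naive ``log(cdf(x))`` underflows to -inf once the CDF rounds to zero
    (|x| around 1e16 for the Cauchy).  For alpha=1 the lower tail satisfies
    T(x) = arctan(1/|z|)/pi for z < 0, which stays accurate down to
    z ~ -1e150, so extreme linear predictors produced by heavy-tailed
    coefficient draws keep finite log-likelihoods.
    """
    _validate_t_params(alpha, omega)
    z = np.clip(np.asarray(x, dtype=float) / math.sqrt(omega), -_Z_CLAMP, _Z_CLAMP)
    if alpha == 1.0:
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = np.log(0.5 + np.arctan(z[pos]) / np.pi)
        zn = z[~pos]
        out[~pos] = np.log(np.arctan(-1.0 / zn) / np.pi)
        return out
    return stats.t.logcdf(z, df=alpha)


def _t_logpdf(z, alpha: float):
    """log density of the standard t at z (unit scale)."""
    if alpha == 1.0:
        return -np.log(np.pi) - np.log1p(z * z)
    return stats.t.logpdf(z, df=alpha)


def log_likelihood(beta: np.ndarray, data: Dataset, cfg: RobitConfig = RobitConfig()) -> float:
    """Robit log likelihood sum_i [y_i log T(x_i b) + (1-y_i) log T(-x_i b)]."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != data.X.shape[1]:
        raise ValueError("beta length does not match the design matrix")
    m = data.X @ beta
    u = 2 * data.y - 1  # +1 for y=1, -1 for y=0; T(-m) = 1 - T(m)
    return float(np.sum(student_t_logcdf(u * m, cfg.alpha0, cfg.omega0)))


def _dneg_lp_dm(m, y, cfg: RobitConfig):
    """d(-log P(y_i | m_i))/dm_i, evaluated stably.

    Equals t_pdf(m) / (1 - y - T(m)): for y=1 this is -pdf/T(m), for y=0 it is
    +pdf/T(-m).  The ratio is computed on the log scale so that cases far in
    the tail (|m| huge) give the correct O(1/|m|) slope instead of 0/0.
    """
    u = 2 * np.asarray(y) - 1
    z = np.clip(np.asarray(m, dtype=float) / math.sqrt(cfg.omega0), -_Z_CLAMP, _Z_CLAMP)
    log_ratio = (
        _t_logpdf(z, cfg.alpha0)
        - math.log(math.sqrt(cfg.omega0))
        - student_t_logcdf(u * np.asarray(m), cfg.alpha0, cfg.omega0)
    )
    return -u * np.exp(log_ratio)


def neg_log_posterior_and_gradient(
    beta_U: np.ndarray,
    lambda_U: np.ndarray,
    X_U: np.ndarray,
    y: np.ndarray,
    cached_XF_betaF: np.ndarray,
    cfg: RobitConfig = RobitConfig(),
) -> tuple[float, np.ndarray]:
    """Potential energy and gradient for the active coefficient block.

    The target is the conditional posterior of ``beta_U`` given the frozen
    block and the freshly drawn latent variances:

        energy = -sum_i lp(y_i | x_{i,U} b_U + x_{i,F} b_F)
                 + sum_{j in U} b_j^2 / (2 lambda_j)      (+ const)

    ``cached_XF_betaF`` is the precomputed contribution of the frozen
    coefficients; it is *not* recomputed here, which is what makes restricted
    updates cheap.  The gradient component j is the likelihood sum plus
    ``beta_j / lambda_j``.
    """
    beta_U = np.asarray(beta_U, dtype=float)
    lambda_U = np.asarray(lambda_U, dtype=float)
    if np.any(lambda_U <= 0):
        raise ValueError("latent variances must be positive")
    m = cached_XF_betaF + X_U @ beta_U
    u = 2 * np.asarray(y) - 1
    nll = -np.sum(student_t_logcdf(u * m, cfg.alpha0, cfg.omega0))
    energy = float(nll + 0.5 * np.sum(beta_U**2 / lambda_U))
    s = _dneg_lp_dm(m, y, cfg)
    grad = X_U.T @ s + beta_U / lambda_U
    return energy, grad


def posterior_average_prediction(chain, X_new: np.ndarray, cfg: RobitConfig = RobitConfig()) -> np.ndarray:
    """Posterior-predictive P(y=1 | x) averaged over retained MCMC draws.

    ``X_new`` rows must include the intercept element and be on the same
    feature scale the chain was fit on (the chain's own ``predict`` method
    handles standardization; this helper averages the robit CDF directly).
    """
    B = np.asarray(chain.beta_draws if hasattr(chain, "beta_draws") else chain, dtype=float)
    if B.ndim == 1:
        B = B[None, :]
    if B.shape[0] == 0:
        raise ValueError("empty chain: no retained draws to average over")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    probs = student_t_cdf(X_new @ B.T, cfg.alpha0, cfg.omega0)
    return probs.mean(axis=1)
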