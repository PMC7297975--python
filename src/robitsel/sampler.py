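"""Restricted Gibbs sampling with Hamiltonian Monte Carlo for robit models.

One Gibbs sweep alternates:

1. draw every latent prior variance ``lambda_j | beta_j`` in closed form
   (Inverse-Gamma);
2. from the *fresh* ``lambda_hat`` alone, pick the active set ``U`` — the
   intercept plus the coefficients with the largest latent variances
   (equivalently ``U = {j : lambda_hat_j > eta}`` for the matching order
   statistic ``eta``);
3. update ``beta_U`` jointly with one HMC trajectory on its conditional
   posterior, keeping ``beta_F`` frozen and reusing the cached ``X_F beta_F``
   vector so the per-step cost scales with |U|, not p;
4. commit and repeat.

Because the update set depends only on the freshly drawn variances — never on
the current coefficient values — the restricted update leaves the joint
posterior invariant.  Coefficients sitting near zero are cheap to skip: their
conditional is essentially their (tiny-variance) prior, while the heavy
Inverse-Gamma tail still lets any of them pop back into the active set.

The HMC proposal uses a diagonal mass matrix
``M_jj = 1/lambda_hat_j + kappa * sum_i x_ij^2`` (kappa bounds the likelihood
curvature per unit x^2).  The conditional posterior mixes coordinate scales
spanning many orders of magnitude (sqrt(lambda) ~ e^-5 for noise vs ~1 for
signal); a fixed mass, set before the trajectory from quantities independent
of the current beta, keeps the kernel valid while making a single global step
size workable across that range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from .model import Dataset, RobitConfig, student_t_logcdf, neg_log_posterior_and_gradient
from .priors import lambda_prior_logpdf, sample_lambda_given_beta, sample_lambda_prior

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerSettings",
    "SamplerState",
    "MCMCChain",
    "select_update_set",
    "leapfrog",
    "hmc_update",
    "run_mcmc",
    "two_stage_fit",
    "geweke_z",
]


@dataclass(frozen=True)
class SamplerSettings:
    """Tuning knobs for the restricted Gibbs/HMC sampler.

    n_iter / n_burnin
        Total Gibbs iterations and how many to discard (default: half).
    update_fraction
        Target fraction of the p penalized coefficients refreshed per
        iteration; defines the variance threshold eta as an order statistic.
    leapfrog_steps / step_size / target_accept
        HMC trajectory length; "auto" adapts the global step size during
        burn-in by Robbins-Monro toward ``target_accept`` and then freezes it.
    p_star
        Number of features kept after the stage-1 screening run.
    n_iter_stage2
        Iteration count of the stage-2 run in :func:`two_stage_fit`.
    intercept_variance
        Fixed prior variance of the intercept (and of any ``unpenalized``
        columns); never resampled, so these coefficients are effectively
        unshrunk and always updated.
    standardize
        Center/scale features internally (coefficients are reported on the
        standardized scale).  A fixed prior scale sqrt(omega1)=e^-5 only has
        meaning relative to a common feature scale.
    thin
        Keep every ``thin``-th post-burn-in draw to cap memory.
    """

    n_iter: int = 2000
    n_burnin: int | None = None
    update_fraction: float = 0.1
    leapfrog_steps: int = 50
    step_size: float | str = "auto"
    target_accept: float = 0.8
    p_star: int = 100
    n_iter_stage2: int = 5000
    seed: int | None = None
    intercept_variance: float = 100.0
    unpenalized: tuple[int, ...] = ()
    standardize: bool = True
    thin: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.update_fraction <= 1.0):
            raise ValueError("update_fraction must be in (0, 1]")
        if self.leapfrog_steps < 1:
            raise ValueError("leapfrog_steps must be >= 1")
        if self.p_star < 1:
            raise ValueError("p_star must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def burnin(self) -> int:
        return self.n_iter // 2 if self.n_burnin is None else self.n_burnin


@dataclass
class SamplerState:
    """Current position of the chain plus the frozen-block cache."""

    beta: np.ndarray
    lam: np.ndarray
    U: np.ndarray
    F: np.ndarray
    cached_XF_betaF: np.ndarray


@dataclass
class MCMCChain:
    """Retained posterior draws with enough context to predict new cases."""

    beta_draws: np.ndarray        # R x (p+1), standardized scale
    lambda_draws: np.ndarray      # R x p
    logpost_draws: np.ndarray     # R, joint log posterior up to a constant
    accept_rate: float
    feature_names: list[str]
    center: np.ndarray            # length p+1 (0 for the intercept)
    scale: np.ndarray             # length p+1 (1 for the intercept)
    step_size: float
    thin: int = 1

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def posterior_mean(self) -> np.ndarray:
        return self.beta_draws.mean(axis=0)

    def design(self, features: np.ndarray) -> np.ndarray:
        """Standardized design (with intercept) for raw feature rows."""
        F = np.atleast_2d(np.asarray(features, dtype=float))
        X = np.column_stack([np.ones(F.shape[0]), F])
        return (X - self.center) / self.scale

    def predict(self, features: np.ndarray, cfg: RobitConfig = RobitConfig()) -> np.ndarray:
        """Posterior-averaged P(y=1 | x) for raw (unstandardized) features."""
        from .model import posterior_average_prediction

        return posterior_average_prediction(self, self.design(features), cfg)


def select_update_set(lambda_hat: np.ndarray, fraction: float) -> np.ndarray:
    """Active coefficient indices given fresh latent variances.

    ``lambda_hat`` holds the p penalized variances (features 1..p); the
    returned index set contains 0 (the intercept) plus the ``ceil(fraction*p)``
    features with the largest variances, ties broken toward the lower index.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    lam = np.asarray(lambda_hat, dtype=float)
    p = lam.shape[0]
    k = min(p, math.ceil(fraction * p))
    order = np.lexsort((np.arange(p), -lam))
    active = np.sort(order[:k]) + 1
    return np.concatenate(([0], active))


def leapfrog(beta0, q0, grad_fn, step_size, n_steps, coord_scale):
    """Leapfrog trajectory with unit momenta and per-coordinate scales.

    ``coord_scale`` is M^{-1/2} for the diagonal mass matrix M; the momenta
    ``q`` are standard normal.  Returns the trajectory endpoint.
    """
    beta = np.array(beta0, dtype=float)
    q = np.array(q0, dtype=float)
    eps = step_size * coord_scale
    g = grad_fn(beta)
    q = q - 0.5 * eps * g
    for step in range(n_steps):
        beta = beta + eps * q
        g = grad_fn(beta)
        if step < n_steps - 1:
            q = q - eps * g
    q = q - 0.5 * eps * g
    return beta, q


def _curvature_bound(cfg: RobitConfig) -> float:
    """Upper bound on d^2(-log P(y|m))/dm^2 over m, per unit x_ij^2."""
    m = np.linspace(-30.0, 30.0, 6001)
    ll = student_t_logcdf(m, cfg.alpha0, cfg.omega0)
    h = m[1] - m[0]
    curv = -(ll[2:] - 2 * ll[1:-1] + ll[:-2]) / h**2
    return 1.2 * float(np.max(np.abs(curv)))


def hmc_update(
    state: SamplerState,
    data: Dataset,
    cfg: RobitConfig,
    settings: SamplerSettings,
    rng: np.random.Generator,
    step_size: float | None = None,
    col_sumsq: np.ndarray | None = None,
    kappa: float | None = None,
):
    """One HMC trajectory on the active block ``beta_U``; frozen block untouched.

    Returns ``(state, accepted, accept_prob)``.  A non-finite proposal energy
    counts as a rejection.
    """
    eps = settings.step_size if step_size is None else step_size
    if not isinstance(eps, (int, float)):
        raise ValueError("step_size must be resolved to a number before hmc_update")
    U = state.U
    X_U = data.X[:, U]
    lam_U = state.lam[U]
    if col_sumsq is None:
        col_sumsq = np.sum(X_U**2, axis=0)
    if kappa is None:
        kappa = _curvature_bound(cfg)
    mass = 1.0 / lam_U + kappa * col_sumsq
    coord_scale = 1.0 / np.sqrt(mass)

    def energy_grad(b):
        return neg_log_posterior_and_gradient(b, lam_U, X_U, data.y, state.cached_XF_betaF, cfg)

    beta0 = state.beta[U].copy()
    e0, _ = energy_grad(beta0)
    q0 = rng.standard_normal(U.shape[0])
    h0 = e0 + 0.5 * np.dot(q0, q0)
    beta1, q1 = leapfrog(beta0, q0, lambda b: energy_grad(b)[1], eps, settings.leapfrog_steps, coord_scale)
    if np.all(np.isfinite(beta1)):
        e1, _ = energy_grad(beta1)
        h1 = e1 + 0.5 * np.dot(q1, q1)
    else:
        h1 = np.inf
    if np.isfinite(h1):
        accept_prob = min(1.0, math.exp(min(0.0, h0 - h1)))
    else:
        accept_prob = 0.0
        logger.debug("non-finite proposal energy; trajectory rejected")
    accepted = rng.uniform() < accept_prob
    if accepted:
        state.beta[U] = beta1
    return state, accepted, accept_prob


def _standardize(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p1 = X.shape[1]
    center = np.zeros(p1)
    scale = np.ones(p1)
    if enabled and p1 > 1:
        mu = X[:, 1:].mean(axis=0)
        sd = X[:, 1:].std(axis=0)
        sd[sd == 0] = 1.0
        center[1:] = mu
        scale[1:] = sd
    Xs = (X - center) / scale
    return Xs, center, scale


def _log_posterior(Xbeta, y, beta, lam, penalized, cfg):
    u = 2 * y - 1
    ll = float(np.sum(student_t_logcdf(u * Xbeta, cfg.alpha0, cfg.omega0)))
    lp_beta = float(np.sum(-0.5 * np.log(lam) - 0.5 * beta**2 / lam))
    lp_lam = float(np.sum(lambda_prior_logpdf(lam[penalized], cfg)))
    return ll + lp_beta + lp_lam


def run_mcmc(
    data: Dataset,
    cfg: RobitConfig = RobitConfig(),
    settings: SamplerSettings = SamplerSettings(),
    rng: np.random.Generator | None = None,
) -> MCMCChain:
    """Run the restricted Gibbs/HMC sampler and return the retained draws.

    Starts from ``beta = 0`` with latent variances drawn from their prior;
    the step size (if "auto") is adapted only during burn-in.  The same seed
    yields an identical chain.
    """
    if data.n < 2:
        raise ValueError("need at least two cases")
    if len(np.unique(data.y)) < 2:
        raise ValueError("labels are degenerate: only one class present")
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    Xs, center, scale = _standardize(data.X, settings.standardize)
    n, p1 = Xs.shape
    p = p1 - 1
    col_sumsq = np.sum(Xs**2, axis=0)
    kappa = _curvature_bound(cfg)

    unpen = np.unique(np.concatenate(([0], np.asarray(settings.unpenalized, dtype=int))))
    penalized = np.setdiff1d(np.arange(p1), unpen)

    beta = np.zeros(p1)
    lam = np.empty(p1)
    lam[unpen] = settings.intercept_variance
    lam[penalized] = sample_lambda_prior(cfg, penalized.size, rng)
    Xbeta = np.zeros(n)

    burnin = settings.burnin
    eps = 0.5 if settings.step_size == "auto" else float(settings.step_size)
    adapt = settings.step_size == "auto"
    log_eps = math.log(eps) if eps > 0 else -math.inf

    keep = [i for i in range(settings.n_iter) if i >= burnin and (i - burnin) % settings.thin == 0]
    R = len(keep)
    beta_draws = np.empty((R, p1))
    lambda_draws = np.empty((R, p))
    logpost_draws = np.empty(R)
    keep_pos = 0
    n_accept = 0
    n_post = 0

    for it in range(settings.n_iter):
        # Step 1: refresh all penalized latent variances given current beta.
        lam[penalized] = sample_lambda_given_beta(beta[penalized], cfg, rng)
        # Step 2: active set from the fresh variances only.
        U = select_update_set(lam[1:], settings.update_fraction)
        U = np.unique(np.concatenate((U, unpen)))
        # Step 3: HMC on beta_U with X_F beta_F cached.
        X_U = Xs[:, U]
        cached = Xbeta - X_U @ beta[U]
        beta, accepted, accept_prob = _hmc_step(
            beta, lam, U, X_U, data.y, cached, cfg, settings, rng, eps, col_sumsq[U], kappa
        )
        Xbeta = cached + X_U @ beta[U]
        if adapt and it < burnin:
            log_eps += (accept_prob - settings.target_accept) / (1.0 + 0.1 * it) ** 0.6
            eps = math.exp(log_eps)
        if it >= burnin:
            n_post += 1
            n_accept += int(accepted)
            if keep_pos < R and it == keep[keep_pos]:
                beta_draws[keep_pos] = beta
                lambda_draws[keep_pos] = lam[1:]
                logpost_draws[keep_pos] = _log_posterior(Xbeta, data.y, beta, lam, penalized, cfg)
                keep_pos += 1
        if (it + 1) % max(1, settings.n_iter // 10) == 0:
            logger.debug(
                "iter %d/%d |U|=%d eps=%.3g accept_prob=%.2f",
                it + 1, settings.n_iter, U.size, eps, accept_prob,
            )

    accept_rate = n_accept / max(1, n_post)
    return MCMCChain(
        beta_draws=beta_draws,
        lambda_draws=lambda_draws,
        logpost_draws=logpost_draws,
        accept_rate=accept_rate,
        feature_names=list(data.feature_names),
        center=center,
        scale=scale,
        step_size=eps,
        thin=settings.thin,
    )


def _hmc_step(beta, lam, U, X_U, y, cached, cfg, settings, rng, eps, col_sumsq_U, kappa):
    """Inner HMC step used by run_mcmc (operates on raw arrays for speed)."""
    lam_U = lam[U]
    mass = 1.0 / lam_U + kappa * col_sumsq_U
    coord_scale = 1.0 / np.sqrt(mass)
    beta0 = beta[U].copy()
    q0 = rng.standard_normal(U.shape[0])

    if _kernel.HAVE_NUMBA and cfg.alpha0 == 1.0:
        u = (2.0 * y - 1.0).astype(float)
        beta1, q1, h0, h1 = _kernel.hmc_trajectory_t1(
            X_U, u, lam_U, cached, beta0, q0, coord_scale,
            eps, settings.leapfrog_steps, math.sqrt(cfg.omega0),
        )
        if not np.isfinite(h1):
            h1 = np.inf
    else:
        def grad(b):
            return neg_log_posterior_and_gradient(b, lam_U, X_U, y, cached, cfg)[1]

        e0 = neg_log_posterior_and_gradient(beta0, lam_U, X_U, y, cached, cfg)[0]
        h0 = e0 + 0.5 * np.dot(q0, q0)
        beta1, q1 = leapfrog(beta0, q0, grad, eps, settings.leapfrog_steps, coord_scale)
        if np.all(np.isfinite(beta1)):
            e1 = neg_log_posterior_and_gradient(beta1, lam_U, X_U, y, cached, cfg)[0]
            h1 = e1 + 0.5 * np.dot(q1, q1)
        else:
            h1 = np.inf
    if np.isfinite(h1):
        accept_prob = min(1.0, math.exp(min(0.0, h0 - h1)))
    else:
        accept_prob = 0.0
        logger.debug("non-finite proposal energy; trajectory rejected")
    accepted = rng.uniform() < accept_prob
    if accepted:
        beta = beta.copy()
        beta[U] = beta1
    return (beta, accepted, accept_prob)


def two_stage_fit(
    data: Dataset,
    cfg: RobitConfig = RobitConfig(),
    settings: SamplerSettings = SamplerSettings(),
    rng: np.random.Generator | None = None,
) -> tuple[MCMCChain, np.ndarray]:
    """Screening run on all p features, then a definitive run on the top p*.

    Stage 1 samples the full posterior and ranks features by the absolute
    posterior mean of their (standardized) coefficients; the top
    ``min(p_star, p)`` survive.  Stage 2 reruns the sampler on the reduced
    design (intercept always retained) for ``n_iter_stage2`` iterations.
    Returns the stage-2 chain (feature names preserved from the original
    data) and the selected 0-based feature indices.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    p = data.p
    if p <= settings.p_star:
        selected = np.arange(p)
    else:
        chain1 = run_mcmc(data, cfg, settings, rng)
        abs_means = np.abs(chain1.beta_draws[:, 1:].mean(axis=0))
        order = np.lexsort((np.arange(p), -abs_means))
        selected = np.sort(order[: settings.p_star])
    sub = Dataset(
        X=data.X[:, np.concatenate(([0], selected + 1))],
        y=data.y,
        feature_names=[data.feature_names[j] for j in selected],
    )
    settings2 = replace(settings, n_iter=settings.n_iter_stage2, n_burnin=None)
    chain2 = run_mcmc(sub, cfg, settings2, rng)
    return chain2, selected


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Uses batch-means variance estimates so autocorrelation does not deflate
    the standard error.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]

    def batch_var(seg):
        nb = max(2, int(math.sqrt(seg.shape[0])))
        usable = (seg.shape[0] // nb) * nb
        means = seg[:usable].reshape(nb, -1).mean(axis=1)
        return np.var(means, ddof=1) / nb

    se = math.sqrt(batch_var(a) + batch_var(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)
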