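"""Cauchy coefficient prior as a scale mixture of normals.

A t prior ``beta_j ~ T(alpha1, omega1)`` is equivalent to

    beta_j | lambda_j ~ N(0, lambda_j),
    lambda_j ~ Inverse-Gamma(alpha1/2, alpha1*omega1/2)   (shape, rate),

which turns the heavy-tailed prior into a conditionally Gaussian one and
makes a Gibbs update of the latent variances available in closed form:

    lambda_j | beta_j ~ Inverse-Gamma((alpha1+1)/2, (alpha1*omega1 + beta_j^2)/2).

All Inverse-Gamma parameters in this module are (shape, rate): the density is
proportional to x^(-shape-1) * exp(-rate/x).
"""

from __future__ import annotations

import math

import numpy as np

from .model import RobitConfig

__all__ = [
    "sample_lambda_given_beta",
    "sample_lambda_prior",
    "lambda_prior_logpdf",
    "cauchy_magnitude_quantile",
]


def _invgamma_draw(shape: float, rate, rng: np.random.Generator):
    """Inverse-Gamma(shape, rate) draws via the reciprocal Gamma identity."""
    rate = np.asarray(rate, dtype=float)
    g = rng.standard_gamma(shape, size=rate.shape if rate.ndim else None)
    return rate / g


def sample_lambda_given_beta(beta_j, cfg: RobitConfig, rng: np.random.Generator):
    """Gibbs draw of the latent prior variance(s) given coefficient value(s).

    Vectorized over ``beta_j``; returns strictly positive draws from
    Inverse-Gamma((alpha1+1)/2, (alpha1*omega1 + beta_j^2)/2).
    """
    beta_j = np.asarray(beta_j, dtype=float)
    shape = (cfg.alpha1 + 1.0) / 2.0
    rate = (cfg.alpha1 * cfg.omega1 + beta_j**2) / 2.0
    return _invgamma_draw(shape, rate, rng)


def sample_lambda_prior(cfg: RobitConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draws from the marginal prior lambda_j ~ IG(alpha1/2, alpha1*omega1/2)."""
    shape = cfg.alpha1 / 2.0
    rate = np.full(size, cfg.alpha1 * cfg.omega1 / 2.0)
    return _invgamma_draw(shape, rate, rng)


def lambda_prior_logpdf(lambda_j, cfg: RobitConfig):
    """log f(lambda_j) up to an additive constant.

    Equals -(alpha1/2 + 1) log(lambda_j) - alpha1*omega1 / (2 lambda_j).
    """
    lam = np.asarray(lambda_j, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda_j must be positive")
    return -(cfg.alpha1 / 2.0 + 1.0) * np.log(lam) - cfg.alpha1 * cfg.omega1 / (2.0 * lam)


def cauchy_magnitude_quantile(upper_prob: float, scale: float) -> float:
    """Upper-tail quantile of |beta| for beta ~ Cauchy(0, scale).

    Returns the x with P(|beta| >= x) = upper_prob, i.e.
    x = scale / tan(pi * upper_prob / 2).  Used to read off how many
    coefficients the prior scale postulates to be large: e.g. with
    scale = e^-5, the 1e-4 upper-tail quantile is 42.895, so the prior
    expects about 1 in 10,000 coefficients to exceed that magnitude.
    """
    if not (0.0 < upper_prob <= 1.0):
        raise ValueError("upper_prob must lie in (0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    # Two algebraically equivalent branches, each evaluated where the tan
    # argument is small and therefore accurate.
    if upper_prob < 0.5:
        return scale / math.tan(math.pi * upper_prob / 2.0)
    return scale * math.tan(math.pi * (1.0 - upper_prob) / 2.0)
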