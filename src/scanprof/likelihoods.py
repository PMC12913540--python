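"""Log-likelihoods for the four candidate count models.

All four families — Poisson, negative binomial (NB2: variance
``mu + alpha*mu**2``), zero-inflated Poisson (ZIP) and zero-inflated
negative binomial (ZINB) — share a log link on the count-part mean
``mu = exp(X beta)`` and, for the zero-inflated members, a logit link on
the structural-zero probability ``pi = expit(Z gamma)``.

Per-observation log-likelihood vectors (needed by the Vuong test) and
analytic gradients (needed for fast maximum-likelihood fitting and
bootstrap refits) are exposed alongside the summed log-likelihoods.
The families nest continuously: ZINB -> ZIP and NB -> Poisson as
``alpha -> 0``; ZINB -> NB and ZIP -> Poisson as ``pi -> 0``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

_ETA_MAX = 500.0  # exp() overflow guard on the linear predictor


def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if np.any(yf % 1 != 0) or np.any(~np.isfinite(yf)):
            raise ValueError("y must contain non-negative integers")
        y = yf.astype(int)
    if np.any(y < 0):
        raise ValueError("y must contain non-negative integers")
    return y


def _mu(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = X @ beta
    if np.any(np.abs(eta) > _ETA_MAX) or not np.all(np.isfinite(eta)):
        raise FloatingPointError("count-part linear predictor overflow")
    return np.exp(eta)


# ----------------------------------------------------------------------
# per-observation log-pmf vectors
# ----------------------------------------------------------------------

def poisson_logpmf(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return y * np.log(mu) - mu - gammaln(y + 1.0)


#: below this dispersion the NB2 pmf is evaluated as its Poisson limit
#: (the lgamma difference at r = 1/alpha ~ 1e10 loses more precision than
#: the limit approximation gives up)
ALPHA_POISSON_LIMIT = 1e-8


def negbin_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 log-pmf; collapses to the exact Poisson limit for tiny alpha."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha <= ALPHA_POISSON_LIMIT:
        return poisson_logpmf(y, mu)
    r = 1.0 / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _zi_logpmf(y: np.ndarray, count_logpmf0: np.ndarray, count_logpmf: np.ndarray,
               zeta: np.ndarray) -> np.ndarray:
    """Zero-inflated mixture on the log scale, numerically stable.

    log f(0) = log(pi + (1-pi) p0) = -log1p(e^-zeta) + log1p(e^(-zeta) p0... )

    Implemented via logaddexp on logit-scale terms:
        log f(0) = logaddexp(zeta, log p0) - log1p(exp(zeta))
        log f(y>0) = log(1-pi) + log pmf = -log1p(exp(zeta)) + log pmf
    """
    log1p_ez = np.logaddexp(0.0, zeta)  # log(1 + e^zeta)
    out = count_logpmf - log1p_ez
    zero = y == 0
    out[zero] = np.logaddexp(zeta[zero], count_logpmf0[zero]) - log1p_ez[zero]
    return out


def zip_logpmf_obs(y, mu, zeta):
    lp = poisson_logpmf(y, mu)
    return _zi_logpmf(y, -mu, lp, zeta)


def zinb_logpmf_obs(y, mu, alpha, zeta):
    lp = negbin_logpmf(y, mu, alpha)
    if alpha <= ALPHA_POISSON_LIMIT:
        logp0 = -mu
    else:
        r = 1.0 / alpha
        logp0 = r * np.log(r / (r + mu))
    return _zi_logpmf(y, logp0, lp, zeta)


# ----------------------------------------------------------------------
# summed log-likelihoods (public contract)
# ----------------------------------------------------------------------

def loglik_poisson(y, X, beta) -> float:
    """Poisson log-likelihood with log link: sum_i [y eta - e^eta - log y!]."""
    y = _check_counts(y)
    return float(poisson_logpmf(y, _mu(X, beta)).sum())


def loglik_negbin(y, X, beta, alpha) -> float:
    """NB2 log-likelihood; continuous Poisson limit as alpha -> 0."""
    y = _check_counts(y)
    return float(negbin_logpmf(y, _mu(X, beta), alpha).sum())


def loglik_zip(y, X_count, beta, X_zero, gamma) -> float:
    """Zero-inflated Poisson log-likelihood."""
    y = _check_counts(y)
    if len(X_count) != len(X_zero):
        raise ValueError("count and zero design matrices are not row-aligned")
    return float(zip_logpmf_obs(y, _mu(X_count, beta), X_zero @ gamma).sum())


def loglik_zinb(y, X_count, beta, alpha, X_zero, gamma) -> float:
    """Zero-inflated NB2 log-likelihood."""
    y = _check_counts(y)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if len(X_count) != len(X_zero):
        raise ValueError("count and zero design matrices are not row-aligned")
    return float(zinb_logpmf_obs(y, _mu(X_count, beta), alpha, X_zero @ gamma).sum())


# ----------------------------------------------------------------------
# analytic gradients (score vectors)
# ----------------------------------------------------------------------

def _dnb_dalpha(y, mu, alpha):
    """d/d alpha of the NB2 log-pmf, elementwise."""
    r = 1.0 / alpha
    return (-r * r) * (
        digamma(y + r) - digamma(r) + np.log(r) - np.log(r + mu)
        + 1.0 - (r + y) / (r + mu)
    )


def score_poisson(y, X, beta):
    mu = _mu(X, beta)
    return X.T @ (y - mu)


# fused value-and-gradient kernels (the optimizer hot path shares the
# linear-predictor work between the log-likelihood and its score)

def poisson_vg(y, X, beta):
    mu = _mu(X, beta)
    ll = float(poisson_logpmf(y, mu).sum())
    return ll, X.T @ (y - mu)


def negbin_vg(y, X, beta, alpha):
    mu = _mu(X, beta)
    ll = float(negbin_logpmf(y, mu, alpha).sum())
    gb = X.T @ ((y - mu) / (1.0 + alpha * mu))
    ga = float(_dnb_dalpha(y, mu, alpha).sum())
    return ll, gb, ga


def zip_vg(y, X_count, beta, X_zero, gamma):
    mu = _mu(X_count, beta)
    zeta = X_zero @ gamma
    lp = poisson_logpmf(y, mu)
    ll = float(_zi_logpmf(y, -mu, lp, zeta).sum())
    pi, zero, p0, denom = _zi_pieces(y, mu, -mu, zeta)
    wb = np.where(zero, -(1.0 - pi) * p0 * mu / denom, y - mu)
    wg = np.where(zero, (1.0 - p0) * pi * (1.0 - pi) / denom, -pi)
    return ll, X_count.T @ wb, X_zero.T @ wg


def zinb_vg(y, X_count, beta, alpha, X_zero, gamma):
    mu = _mu(X_count, beta)
    zeta = X_zero @ gamma
    r = 1.0 / alpha
    logp0 = r * np.log(r / (r + mu))
    lp = negbin_logpmf(y, mu, alpha)
    ll = float(_zi_logpmf(y, logp0, lp, zeta).sum())
    pi, zero, p0, denom = _zi_pieces(y, mu, logp0, zeta)
    onem = 1.0 - pi
    wb = np.where(
        zero,
        -onem * p0 * mu / ((1.0 + alpha * mu) * denom),
        (y - mu) / (1.0 + alpha * mu),
    )
    wg = np.where(zero, (1.0 - p0) * pi * onem / denom, -pi)
    dp0 = p0 * (np.log1p(alpha * mu) / alpha**2 - mu / (alpha * (1.0 + alpha * mu)))
    da = np.where(zero, onem * dp0 / denom, _dnb_dalpha(y, mu, alpha))
    return ll, X_count.T @ wb, X_zero.T @ wg, float(da.sum())


def score_negbin(y, X, beta, alpha):
    """Returns (grad_beta, grad_alpha)."""
    mu = _mu(X, beta)
    w = (y - mu) / (1.0 + alpha * mu)
    return X.T @ w, float(_dnb_dalpha(y, mu, alpha).sum())


def _zi_pieces(y, mu, logp0, zeta):
    """Shared zero-inflation quantities: pi, and zero-case mixture weight."""
    pi = expit(zeta)
    zero = y == 0
    p0 = np.exp(logp0)
    denom = pi + (1.0 - pi) * p0  # f(0)
    return pi, zero, p0, denom


def score_zip(y, X_count, beta, X_zero, gamma):
    mu = _mu(X_count, beta)
    zeta = X_zero @ gamma
    pi, zero, p0, denom = _zi_pieces(y, mu, -mu, zeta)

    wb = np.where(zero, -(1.0 - pi) * p0 * mu / denom, y - mu)
    wg = np.where(zero, (1.0 - p0) * pi * (1.0 - pi) / denom, -pi)
    return X_count.T @ wb, X_zero.T @ wg


def score_zinb(y, X_count, beta, alpha, X_zero, gamma):
    """Returns (grad_beta, grad_gamma, grad_alpha)."""
    mu = _mu(X_count, beta)
    zeta = X_zero @ gamma
    r = 1.0 / alpha
    logp0 = r * np.log(r / (r + mu))
    pi, zero, p0, denom = _zi_pieces(y, mu, logp0, zeta)

    onem = 1.0 - pi
    wb = np.where(
        zero,
        -onem * p0 * mu / ((1.0 + alpha * mu) * denom),
        (y - mu) / (1.0 + alpha * mu),
    )
    wg = np.where(zero, (1.0 - p0) * pi * onem / denom, -pi)
    # d p0 / d alpha = p0 * (log(1+alpha mu)/alpha^2 - mu/(alpha(1+alpha mu)))
    dp0 = p0 * (np.log1p(alpha * mu) / alpha**2 - mu / (alpha * (1.0 + alpha * mu)))
    da = np.where(zero, onem * dp0 / denom, _dnb_dalpha(y, mu, alpha))
    return X_count.T @ wb, X_zero.T @ wg, float(da.sum())
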