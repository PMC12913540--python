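"""Log-likelihood kernels: hand-computed values, nesting limits, scores."""

import numpy as np
import pytest
from scipy import stats

from scanprof import likelihoods as lk

ONE = np.ones((1, 1))


def _const_design(n):
    return np.ones((n, 1))


class TestPoisson:
    @pytest.mark.parametrize(
        "y, mu, expected",
        [
            ([0], 1.0, -1.0),  # log P(0; mu=1)
            ([2], 2.0, 2 * np.log(2) - 2 - np.log(2)),  # -1.3068528...
            ([0, 1, 2], 1.0, -3.0 - np.log(2)),  # sum of pmf logs
        ],
    )
    def test_hand_values(self, y, mu, expected):
        X = _const_design(len(y))
        beta = np.array([np.log(mu)])
        assert lk.loglik_poisson(y, X, beta) == pytest.approx(expected, abs=1e-10)

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            lk.loglik_poisson([0.5], ONE, np.array([0.0]))
        with pytest.raises(ValueError, match="non-negative integers"):
            lk.loglik_poisson([-1], ONE, np.array([0.0]))


class TestNegbin:
    def test_geometric_at_zero(self):
        # alpha = 1, mu = 1 is geometric with p = 1/2
        assert lk.loglik_negbin([0], ONE, np.array([0.0]), 1.0) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    def test_poisson_limit(self):
        y = [0, 1, 3, 7, 2]
        X = _const_design(5)
        beta = np.array([np.log(2.3)])
        assert lk.loglik_negbin(y, X, beta, 1e-12) == pytest.approx(
            lk.loglik_poisson(y, X, beta), abs=1e-6
        )

    def test_matches_scipy_nbinom(self):
        # NB2(mu, alpha) == scipy nbinom(n=1/alpha, p=1/(1+alpha*mu))
        alpha, mu, y = 0.5, 2.0, 3
        expected = stats.nbinom.logpmf(y, 1 / alpha, 1 / (1 + alpha * mu))
        got = lk.loglik_negbin([y], ONE, np.array([np.log(mu)]), alpha)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            lk.loglik_negbin([1], ONE, np.array([0.0]), -0.1)


class TestZeroInflated:
    def test_zip_no_inflation_limit(self):
        y = [0, 2, 1, 0, 4]
        X = _const_design(5)
        beta = np.array([np.log(1.7)])
        gamma = np.array([-30.0])  # pi ~ 0
        assert lk.loglik_zip(y, X, beta, X, gamma) == pytest.approx(
            lk.loglik_poisson(y, X, beta), abs=1e-9
        )

    def test_zip_hand_value(self):
        # pi = 0.5, mu = 1, y = 0: log(0.5 + 0.5 e^-1)
        got = lk.loglik_zip([0], ONE, np.array([0.0]), ONE, np.array([0.0]))
        assert got == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1)), abs=1e-10)

    def test_zip_degenerate_mass_at_zero(self):
        y = [0] * 10
        X = _const_design(10)
        ll = lk.loglik_zip(y, X, np.array([0.0]), X, np.array([30.0]))
        assert ll == pytest.approx(0.0, abs=1e-8)

    def test_zinb_limits(self):
        y = [0, 1, 0, 3, 2]
        X = _const_design(5)
        beta = np.array([np.log(1.4)])
        gamma = np.array([-0.4])
        # alpha -> 0: ZINB -> ZIP
        assert lk.loglik_zinb(y, X, beta, 1e-10, X, gamma) == pytest.approx(
            lk.loglik_zip(y, X, beta, X, gamma), abs=1e-6
        )
        # pi -> 0: ZINB -> NB
        assert lk.loglik_zinb(y, X, beta, 0.8, X, np.array([-35.0])) == pytest.approx(
            lk.loglik_negbin(y, X, beta, 0.8), abs=1e-9
        )

    def test_zinb_hand_value(self):
        # pi = 0.3, alpha = 1, mu = 1, y = 0: log(0.3 + 0.7 * 0.5)
        gamma = np.array([np.log(0.3 / 0.7)])
        got = lk.loglik_zinb([0], ONE, np.array([0.0]), 1.0, ONE, gamma)
        assert got == pytest.approx(np.log(0.65), abs=1e-10)

    def test_misaligned_designs_rejected(self):
        with pytest.raises(ValueError, match="row-aligned"):
            lk.loglik_zip([0, 1], _const_design(2), np.array([0.0]),
                          _const_design(3), np.array([0.0]))


@pytest.mark.parametrize("family", ["poisson", "negbin", "zip", "zinb"])
def test_pmf_normalization(family):
    """Each family's pmf sums to 1 over a tail-bounded support."""
    mu, alpha, pi = 2.4, 0.7, 0.35
    ymax = 400
    y = np.arange(ymax + 1)
    muv = np.full(ymax + 1, mu)
    zeta = np.full(ymax + 1, np.log(pi / (1 - pi)))
    if family == "poisson":
        lp = lk.poisson_logpmf(y, muv)
    elif family == "negbin":
        lp = lk.negbin_logpmf(y, muv, alpha)
    elif family == "zip":
        lp = lk.zip_logpmf_obs(y, muv, zeta)
    else:
        lp = lk.zinb_logpmf_obs(y, muv, alpha, zeta)
    assert np.exp(lp).sum() >= 1 - 1e-8
    assert np.exp(lp).sum() <= 1 + 1e-8


@pytest.mark.parametrize("family", ["poisson", "negbin", "zip", "zinb"])
def test_analytic_score_matches_finite_differences(family, rng):
    """The analytic score agrees with central finite differences."""
    n, k = 200, 3
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = np.array([0.3, 0.2, -0.1])
    gamma = np.array([-0.5, 0.4, 0.1])
    alpha = 0.6
    y = rng.poisson(1.5, size=n)

    if family == "poisson":
        f = lambda b: lk.loglik_poisson(y, X, b)
        grads = (lk.score_poisson(y, X, beta),)
        points = (beta,)
    elif family == "negbin":
        f = lambda p: lk.loglik_negbin(y, X, p[:k], p[k])
        gb, ga = lk.score_negbin(y, X, beta, alpha)
        grads = (np.concatenate([gb, [ga]]),)
        points = (np.concatenate([beta, [alpha]]),)
    elif family == "zip":
        f = lambda p: lk.loglik_zip(y, X, p[:k], X, p[k:])
        gb, gg = lk.score_zip(y, X, beta, X, gamma)
        grads = (np.concatenate([gb, gg]),)
        points = (np.concatenate([beta, gamma]),)
    else:
        f = lambda p: lk.loglik_zinb(y, X, p[:k], p[2 * k], X, p[k : 2 * k])
        gb, gg, ga = lk.score_zinb(y, X, beta, alpha, X, gamma)
        grads = (np.concatenate([gb, gg, [ga]]),)
        points = (np.concatenate([beta, gamma, [alpha]]),)

    for point, grad in zip(points, grads):
        num = np.empty_like(point)
        h = 1e-6
        for j in range(len(point)):
            up, dn = point.copy(), point.copy()
            up[j] += h
            dn[j] -= h
            num[j] = (f(up) - f(dn)) / (2 * h)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-5)
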