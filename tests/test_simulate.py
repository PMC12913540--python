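"""Synthetic-cohort generator: moments, determinism, round trips, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from scanprof import (
    CovariateSpec,
    GroupSpec,
    SimTruth,
    default_truth,
    generate_encounters,
    read_encounters,
    write_encounters,
)
from scanprof.design import build_design, design_columns
from scanprof.likelihoods import negbin_logpmf
from scanprof.simulate import DEFAULT_BETA


def _flat_truth(n, seed, *, beta=None, gamma=None, alpha=0.0, **kw):
    """Single-group truth with explicit coefficients (zeros by default)."""
    beta = {"intercept": 0.0, **(beta or {})}
    gamma = {"intercept": -30.0, **(gamma or {})}
    return SimTruth(
        n_encounters=n,
        groups=(GroupSpec("G", 1.0, 1.0),),
        beta=beta,
        gamma=gamma,
        alpha=alpha,
        seed=seed,
        **kw,
    )


class TestInvariants:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="weights"):
            SimTruth(10, (GroupSpec("A", 0.6), GroupSpec("B", 0.5)),
                     {"intercept": 0.0}, {"intercept": 0.0}, 0.1)

    def test_delta_must_be_positive(self):
        with pytest.raises(ValueError, match="delta"):
            SimTruth(10, (GroupSpec("A", 1.0, delta=0.0),),
                     {"intercept": 0.0}, {"intercept": 0.0}, 0.1)

    def test_unknown_coefficient_column_rejected(self):
        with pytest.raises(ValueError, match="unknown design columns"):
            _flat_truth(10, 0, beta={"bogus": 1.0})


class TestCountProcess:
    def test_degenerate_inflation_all_zero(self):
        truth = _flat_truth(2000, 3, gamma={"intercept": 20.0})
        df = generate_encounters(truth)
        assert (df["ct_count"] == 0).all()

    def test_poisson_moments_at_constant_mean(self):
        # pi = 0, alpha = 0, mu = 2: sample mean ~ 2, variance/mean ~ 1
        truth = _flat_truth(100_000, 7, beta={"intercept": np.log(2.0)})
        y = generate_encounters(truth)["ct_count"].to_numpy()
        assert 1.97 <= y.mean() <= 2.03
        assert 0.97 <= y.var(ddof=1) / y.mean() <= 1.03

    def test_study_like_defaults(self):
        """Defaults emulate the target cohort: heavy zeros, overdispersion,
        ten groups with mean scan counts spanning roughly 0.9-3."""
        df = generate_encounters(default_truth(29461, seed=1))
        y = df["ct_count"]
        assert 1.15 <= y.mean() <= 1.45
        assert 0.33 <= (y == 0).mean() <= 0.50
        assert y.var(ddof=1) / y.mean() > 1.5  # overdispersed
        per_group = df.groupby("group")["ct_count"].mean()
        assert len(per_group) == 10
        assert 0.8 <= per_group.min() <= 1.3
        assert 2.0 <= per_group.max() <= 3.6

    @pytest.mark.parametrize("point", range(3))
    def test_zero_fraction_converges_to_mixture_mass(self, point):
        """Empirical P(Y=0 | x) -> pi(x) + (1-pi(x)) NB(0; mu(x), alpha)."""
        n = 50_000
        beta0, gamma0, alpha = [(0.3, -0.5, 0.4), (0.9, 0.5, 0.2), (0.0, -1.5, 0.8)][point]
        spec = CovariateSpec(
            p_male=1.0, age_sd=1e-9, p_admission=(0.0, 0.0, 1.0),
            p_first_time_yes=1.0, p_critical_yes=0.0, p_insured_yes=1.0,
            p_cc=(1.0, 0.0, 0.0), p_emergency=0.0,
            los_log_sigma=1e-9, surgery_rate=0.0, cmi_log_sigma=1e-9,
        )
        truth = _flat_truth(
            n, 100 + point,
            beta={"intercept": beta0}, gamma={"intercept": gamma0},
            alpha=alpha, covariate_spec=spec,
        )
        df = generate_encounters(truth)
        X, cols = build_design(df)
        bvec = np.array([truth.beta.get(c, 0.0) for c in cols])
        gvec = np.array([truth.gamma.get(c, 0.0) for c in cols])
        mu = float(np.exp(X[0] @ bvec))
        pi = float(expit(X[0] @ gvec))
        p0_nb = float(np.exp(negbin_logpmf(np.array([0]), np.array([mu]), alpha)[0]))
        p_zero = pi + (1 - pi) * p0_nb
        se = np.sqrt(p_zero * (1 - p_zero) / n)
        emp = (df["ct_count"] == 0).mean()
        assert abs(emp - p_zero) <= 3 * se + 1e-6

    def test_seed_determinism(self):
        t1 = generate_encounters(default_truth(2000, seed=5))
        t2 = generate_encounters(default_truth(2000, seed=5))
        t3 = generate_encounters(default_truth(2000, seed=6))
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1["ct_count"].equals(t3["ct_count"])

    def test_extreme_covariate_rejected_with_diagnostic(self):
        spec = CovariateSpec(los_log_median=40.0)  # LOS ~ e^40 days
        truth = _flat_truth(200, 1, beta={"los": 0.027}, covariate_spec=spec)
        with pytest.raises(ValueError, match="los"):
            generate_encounters(truth)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        df = generate_encounters(default_truth(1000, seed=2))
        path = tmp_path / "enc.csv"
        write_encounters(df, path)
        back = read_encounters(path)
        pd.testing.assert_frame_equal(df, back)

    def test_negative_count_rejected(self, tmp_path):
        df = generate_encounters(default_truth(50, seed=2))
        df.loc[7, "ct_count"] = -1
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"'ct_count', row 7"):
            read_encounters(path)

    def test_unknown_level_rejected(self, tmp_path):
        df = generate_encounters(default_truth(50, seed=2))
        df.loc[3, "admission_condition"] = "unknown"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="unknown"):
            read_encounters(path)

    def test_missing_column_rejected(self, tmp_path):
        df = generate_encounters(default_truth(50, seed=2)).drop(columns=["cmi"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="cmi"):
            read_encounters(path)

    def test_truth_json_round_trip(self, tmp_path):
        truth = default_truth(500, seed=9)
        path = tmp_path / "truth.json"
        truth.save(path)
        assert SimTruth.load(path) == truth


def test_design_columns_are_stable():
    cols = design_columns()
    assert cols[0] == "intercept"
    assert "gender[male]" in cols and "cc_grade[severe]" in cols
    assert len(cols) == 14
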