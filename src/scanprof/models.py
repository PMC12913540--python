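"""Maximum-likelihood fitting of the four candidate count models.

The risk model predicts, for every encounter, the expected number of CT
scans given the encounter's covariates: ``E[Y|x] = mu(x)`` for Poisson
and negative binomial, ``(1 - pi(x)) * mu(x)`` for the zero-inflated
families.  Fitting maximizes the family's log-likelihood by quasi-Newton
(L-BFGS-B) with analytic gradients; the dispersion is optimized on the
``log(alpha)`` scale so the Poisson limit stays numerically reachable.
Coefficient uncertainty comes from the observed information (negative
Hessian of the log-likelihood at the optimum), which also feeds the
Wald odds-ratio (zero part) and incidence-rate-ratio (count part)
tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from . import likelihoods as lk
from .design import COVARIATES, build_design, check_full_rank, design_columns

__all__ = ["ModelSpec", "ModelFit", "fit", "predict_expected", "coefficient_table"]

FAMILIES = ("poisson", "negbin", "zip", "zinb")

_LOG_ALPHA_MIN = np.log(1e-8)
_LOG_ALPHA_MAX = np.log(1e6)
#: converged when max |mean score| falls below this
_GRAD_TOL = 1e-5


@dataclass(frozen=True)
class ModelSpec:
    """Which family to fit and which covariates enter each part.

    Both parts default to the full risk-factor set; families without a
    zero-inflation part must leave ``zero_covariates`` empty.
    """

    family: str
    count_covariates: tuple[str, ...] = COVARIATES
    zero_covariates: tuple[str, ...] = COVARIATES

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not self.has_zero_part and self.zero_covariates:
            object.__setattr__(self, "zero_covariates", ())

    @property
    def has_zero_part(self) -> bool:
        return self.family in ("zip", "zinb")

    @property
    def has_dispersion(self) -> bool:
        return self.family in ("negbin", "zinb")


@dataclass
class ModelFit:
    """A fitted count model: estimates, uncertainty, fit statistics."""

    spec: ModelSpec
    beta: dict[str, float]
    gamma: dict[str, float]
    alpha: float | None
    loglik: float
    n: int
    converged: bool
    grad_norm: float
    _theta: np.ndarray = field(repr=False)
    _vcov: np.ndarray | None = field(default=None, repr=False)

    # -- parameter bookkeeping ------------------------------------------
    @property
    def count_columns(self) -> list[str]:
        return design_columns(self.spec.count_covariates)

    @property
    def zero_columns(self) -> list[str]:
        return design_columns(self.spec.zero_covariates) if self.spec.has_zero_part else []

    @property
    def param_names(self) -> list[str]:
        names = [f"count:{c}" for c in self.count_columns]
        names += [f"zero:{c}" for c in self.zero_columns]
        if self.spec.has_dispersion:
            names.append("log_alpha")
        return names

    @property
    def k_params(self) -> int:
        return len(self._theta)

    def params_natural(self) -> np.ndarray:
        """Packed estimates with dispersion on the alpha (not log) scale,
        matching the coordinates of :meth:`vcov`."""
        th = self._theta.copy()
        if self.spec.has_dispersion:
            th[-1] = np.exp(th[-1])
        return th

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_params * np.log(self.n)

    # -- prediction ------------------------------------------------------
    def _designs(self, table: pd.DataFrame):
        Xc, _ = build_design(table, self.spec.count_covariates)
        Xz = None
        if self.spec.has_zero_part:
            Xz, _ = build_design(table, self.spec.zero_covariates)
        return Xc, Xz

    def predict_mu(self, table: pd.DataFrame) -> np.ndarray:
        Xc, _ = self._designs(table)
        b = np.array([self.beta[c] for c in self.count_columns])
        return np.exp(Xc @ b)

    def predict_pi(self, table: pd.DataFrame) -> np.ndarray:
        if not self.spec.has_zero_part:
            return np.zeros(len(table))
        Xz, _ = build_design(table, self.spec.zero_covariates)
        g = np.array([self.gamma[c] for c in self.zero_columns])
        return expit(Xz @ g)

    def loglik_obs(self, table: pd.DataFrame) -> np.ndarray:
        """Per-encounter log-likelihood under this fit (Vuong input)."""
        y = np.asarray(table["ct_count"], dtype=int)
        mu = self.predict_mu(table)
        fam = self.spec.family
        if fam == "poisson":
            return lk.poisson_logpmf(y, mu)
        if fam == "negbin":
            return lk.negbin_logpmf(y, mu, self.alpha)
        Xz, _ = build_design(table, self.spec.zero_covariates)
        g = np.array([self.gamma[c] for c in self.zero_columns])
        zeta = Xz @ g
        if fam == "zip":
            return lk.zip_logpmf_obs(y, mu, zeta)
        return lk.zinb_logpmf_obs(y, mu, self.alpha, zeta)

    # -- uncertainty ------------------------------------------------------
    def vcov(self, table: pd.DataFrame) -> np.ndarray:
        """Observed-information covariance matrix of the packed parameters.

        Computed lazily by central finite differences of the analytic
        score at the optimum, then cached.
        """
        if self._vcov is None:
            obj = _Objective(self.spec, table)
            H = obj.hessian(self._theta)
            self._vcov = np.linalg.inv(-H)
        return self._vcov

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "count_covariates": list(self.spec.count_covariates),
            "zero_covariates": list(self.spec.zero_covariates),
            "beta": self.beta,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "k_params": self.k_params,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "theta": self._theta.tolist(),
            "vcov": None if self._vcov is None else self._vcov.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        spec = ModelSpec(
            d["family"],
            tuple(d["count_covariates"]),
            tuple(d["zero_covariates"]),
        )
        return cls(
            spec=spec,
            beta=dict(d["beta"]),
            gamma=dict(d["gamma"]),
            alpha=d["alpha"],
            loglik=d["loglik"],
            n=d["n"],
            converged=d["converged"],
            grad_norm=d["grad_norm"],
            _theta=np.asarray(d["theta"]),
            _vcov=None if d.get("vcov") is None else np.asarray(d["vcov"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------

def _std_block(X: np.ndarray) -> np.ndarray:
    """Map from standardized-design coefficients to natural ones.

    If Z_j = (X_j - m_j)/s_j for non-intercept columns, a linear predictor
    written in Z-coefficients b equals X-coefficients beta = B @ b with
    beta_j = b_j/s_j and beta_0 = b_0 - sum_j b_j m_j/s_j.
    """
    k = X.shape[1]
    m = X.mean(axis=0)
    s = np.maximum(X.std(axis=0), 1e-12)
    B = np.zeros((k, k))
    B[0, 0] = 1.0
    for j in range(1, k):
        B[j, j] = 1.0 / s[j]
        B[0, j] = -m[j] / s[j]
    return B


def _std_map(Xc, Xz, has_dispersion) -> np.ndarray:
    blocks = [_std_block(Xc)]
    if Xz is not None:
        blocks.append(_std_block(Xz))
    if has_dispersion:
        blocks.append(np.eye(1))
    from scipy.linalg import block_diag

    return block_diag(*blocks)


class _Objective:
    """Packed-parameter negative mean log-likelihood with analytic score."""

    def __init__(self, spec: ModelSpec, table: pd.DataFrame):
        self.spec = spec
        self.y = np.asarray(table["ct_count"], dtype=int)
        if np.any(self.y < 0):
            raise ValueError("ct_count must be non-negative")
        self.Xc, self.count_cols = build_design(table, spec.count_covariates)
        check_full_rank(self.Xc, self.count_cols)
        self.kc = self.Xc.shape[1]
        if spec.has_zero_part:
            self.Xz, self.zero_cols = build_design(table, spec.zero_covariates)
            check_full_rank(self.Xz, self.zero_cols)
            self.kz = self.Xz.shape[1]
        else:
            self.Xz, self.zero_cols, self.kz = None, [], 0
        self.n = len(self.y)
        self.k = self.kc + self.kz + (1 if spec.has_dispersion else 0)
        # affine preconditioner: optimize coefficients of the centered and
        # scaled design (raw covariates such as age ~ N(57, 16) otherwise
        # couple badly with the intercept and stall the quasi-Newton steps);
        # theta_natural = M @ phi maps them back
        self.M = _std_map(self.Xc, self.Xz, spec.has_dispersion)

    def unpack(self, theta):
        beta = theta[: self.kc]
        gamma = theta[self.kc : self.kc + self.kz]
        alpha = np.exp(theta[-1]) if self.spec.has_dispersion else None
        return beta, gamma, alpha

    def loglik(self, theta) -> float:
        beta, gamma, alpha = self.unpack(theta)
        fam = self.spec.family
        if fam == "poisson":
            return lk.loglik_poisson(self.y, self.Xc, beta)
        if fam == "negbin":
            return lk.loglik_negbin(self.y, self.Xc, beta, alpha)
        if fam == "zip":
            return lk.loglik_zip(self.y, self.Xc, beta, self.Xz, gamma)
        return lk.loglik_zinb(self.y, self.Xc, beta, alpha, self.Xz, gamma)

    def score(self, theta) -> np.ndarray:
        beta, gamma, alpha = self.unpack(theta)
        fam = self.spec.family
        if fam == "poisson":
            return lk.score_poisson(self.y, self.Xc, beta)
        if fam == "negbin":
            gb, ga = lk.score_negbin(self.y, self.Xc, beta, alpha)
            return np.concatenate([gb, [ga * alpha]])  # chain rule: log-alpha scale
        if fam == "zip":
            gb, gg = lk.score_zip(self.y, self.Xc, beta, self.Xz, gamma)
            return np.concatenate([gb, gg])
        gb, gg, ga = lk.score_zinb(self.y, self.Xc, beta, alpha, self.Xz, gamma)
        return np.concatenate([gb, gg, [ga * alpha]])

    def neg_mean(self, theta):
        beta, gamma, alpha = self.unpack(theta)
        fam = self.spec.family
        try:
            if fam == "poisson":
                ll, gb = lk.poisson_vg(self.y, self.Xc, beta)
                g = gb
            elif fam == "negbin":
                ll, gb, ga = lk.negbin_vg(self.y, self.Xc, beta, alpha)
                g = np.concatenate([gb, [ga * alpha]])
            elif fam == "zip":
                ll, gb, gg = lk.zip_vg(self.y, self.Xc, beta, self.Xz, gamma)
                g = np.concatenate([gb, gg])
            else:
                ll, gb, gg, ga = lk.zinb_vg(
                    self.y, self.Xc, beta, alpha, self.Xz, gamma
                )
                g = np.concatenate([gb, gg, [ga * alpha]])
        except FloatingPointError:
            return np.inf, np.zeros_like(theta)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta)
        return -ll / self.n, -g / self.n

    def hessian(self, theta, rel_step: float = 1e-5) -> np.ndarray:
        """Central-difference Hessian of the log-likelihood via the score.

        Reported on the natural parameter scale: for dispersion families
        the log-alpha coordinate is mapped back to alpha.
        """

        def score_nat(th):
            s = self.score(th)
            if self.spec.has_dispersion:
                s = s.copy()
                s[-1] /= np.exp(th[-1])  # d/d alpha from d/d log-alpha
            return s

        k = len(theta)
        H = np.empty((k, k))
        # differentiate w.r.t. natural parameters: alpha, not log-alpha
        nat = theta.copy()
        if self.spec.has_dispersion:
            nat[-1] = np.exp(theta[-1])

        def to_packed(nat_th):
            th = nat_th.copy()
            if self.spec.has_dispersion:
                th[-1] = np.log(max(nat_th[-1], 1e-12))
            return th

        for j in range(k):
            h = rel_step * max(abs(nat[j]), 1.0)
            up, dn = nat.copy(), nat.copy()
            up[j] += h
            dn[j] -= h
            H[:, j] = (score_nat(to_packed(up)) - score_nat(to_packed(dn))) / (2 * h)
        return (H + H.T) / 2.0


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _start_values(obj: _Objective) -> np.ndarray:
    """Warm start: Poisson fit for the count part, logistic fit of the
    zero indicator for the inflation part, method-of-moments dispersion."""
    y, Xc = obj.y, obj.Xc
    ybar = max(y.mean(), 1e-8)
    b0 = np.zeros(obj.kc)
    b0[0] = np.log(ybar)

    def pois(theta):
        try:
            ll = lk.loglik_poisson(y, Xc, theta)
            g = lk.score_poisson(y, Xc, theta)
        except FloatingPointError:
            return np.inf, np.zeros_like(theta)
        return -ll / obj.n, -g / obj.n

    beta0 = optimize.minimize(pois, b0, jac=True, method="L-BFGS-B").x
    parts = [beta0]
    if obj.spec.has_zero_part:
        z = (y == 0).astype(float)
        zbar = np.clip(z.mean(), 1e-4, 1 - 1e-4)
        g = np.zeros(obj.kz)
        g[0] = np.log(zbar / (1 - zbar))

        def logistic(theta):
            p = expit(obj.Xz @ theta)
            eps = 1e-12
            ll = np.sum(z * np.log(p + eps) + (1 - z) * np.log(1 - p + eps))
            grad = obj.Xz.T @ (z - p)
            return -ll / obj.n, -grad / obj.n

        parts.append(optimize.minimize(logistic, g, jac=True, method="L-BFGS-B").x)
    if obj.spec.has_dispersion:
        s2 = y.var(ddof=1)
        alpha0 = np.clip((s2 - ybar) / ybar**2, 0.01, 10.0)
        parts.append(np.array([np.log(alpha0)]))
    return np.concatenate(parts)


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    start: np.ndarray | None = None,
    maxiter: int = 500,
) -> ModelFit:
    """Fit one family by maximum likelihood.

    ``start`` (a packed parameter vector) enables warm-started refits,
    e.g. during bootstrap resampling.  A fit that fails the gradient
    tolerance is returned with ``converged=False``, never silently.
    """
    obj = _Objective(spec, table)
    if obj.n <= obj.k:
        raise ValueError(f"n={obj.n} must exceed the parameter count {obj.k}")
    theta0 = _start_values(obj) if start is None else np.asarray(start, dtype=float)

    bounds = None
    M = obj.M
    Minv = np.linalg.inv(M)
    if spec.has_dispersion:
        bounds = [(None, None)] * (obj.k - 1) + [(_LOG_ALPHA_MIN, _LOG_ALPHA_MAX)]

    def preconditioned(phi):
        # theta = M @ phi (standardized-design coefficients); grad by M^T
        f, g = obj.neg_mean(M @ phi)
        return f, M.T @ g

    res = optimize.minimize(
        preconditioned,
        Minv @ theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 2e-8},
    )
    theta = M @ res.x
    grad_norm = float(np.max(np.abs(obj.neg_mean(theta)[1])))
    if grad_norm > _GRAD_TOL:  # one polishing pass from where L-BFGS stopped
        res2 = optimize.minimize(
            preconditioned, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-12},
        )
        g2 = float(np.max(np.abs(obj.neg_mean(M @ res2.x)[1])))
        if g2 < grad_norm:
            theta, grad_norm = M @ res2.x, g2

    beta, gamma, alpha = obj.unpack(theta)
    at_bound = spec.has_dispersion and theta[-1] <= _LOG_ALPHA_MIN + 1e-9
    converged = bool(grad_norm < _GRAD_TOL or at_bound)
    return ModelFit(
        spec=spec,
        beta=dict(zip(obj.count_cols, beta.tolist())),
        gamma=dict(zip(obj.zero_cols, gamma.tolist())),
        alpha=None if alpha is None else float(alpha),
        loglik=float(obj.loglik(theta)),
        n=obj.n,
        converged=converged,
        grad_norm=grad_norm,
        _theta=theta,
    )


def predict_expected(fit_: ModelFit, table: pd.DataFrame) -> np.ndarray:
    """Risk-adjusted expected scan count per encounter: E[Y|x].

    ``mu`` for Poisson/NB; ``(1 - pi) * mu`` for the zero-inflated
    families (the structural-zero state contributes no scans).
    """
    if not fit_.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    mu = fit_.predict_mu(table)
    if fit_.spec.has_zero_part:
        mu = (1.0 - fit_.predict_pi(table)) * mu
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise FloatingPointError("non-finite or non-positive expected count")
    return mu


def predict_variance(fit_: ModelFit, table: pd.DataFrame) -> np.ndarray:
    """Model-implied variance of the scan count per encounter.

    Poisson: mu.  NB2: mu + alpha mu^2.  Zero-inflated families mix a
    point mass at zero with the count component:
    Var = (1-pi) mu (1 + pi mu) for ZIP and
    Var = (1-pi) mu (1 + alpha mu + pi mu) for ZINB.
    """
    if not fit_.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    mu = fit_.predict_mu(table)
    fam = fit_.spec.family
    if fam == "poisson":
        return mu
    if fam == "negbin":
        return mu * (1.0 + fit_.alpha * mu)
    pi = fit_.predict_pi(table)
    a = fit_.alpha if fam == "zinb" else 0.0
    return (1.0 - pi) * mu * (1.0 + a * mu + pi * mu)


def coefficient_table(fit_: ModelFit, table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Wald coefficient table: OR (zero part) and IRR (count part).

    One row per coefficient with the point ratio ``exp(estimate)``, its
    Wald CI ``exp(estimate +/- z * SE)``, the Z statistic and two-sided
    normal P value.  SEs come from the observed-information covariance.
    """
    if not fit_.converged:
        raise ValueError("coefficient table requires a converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    V = fit_.vcov(table)
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    z_crit = norm.ppf(0.5 + level / 2)
    names = fit_.param_names
    rows = []
    for name, est, s in zip(names, fit_.params_natural(), se):
        part, _, covname = name.partition(":")
        if name == "log_alpha":
            part, covname, ratio = "dispersion", "alpha", None
        else:
            ratio = float(np.exp(est))
        if s <= 0:
            raise ValueError(f"degenerate (zero) standard error for {name!r}")
        zstat = est / s
        rows.append(
            {
                "part": part,
                "covariate": covname,
                "estimate": est,
                "se": s,
                "ratio": ratio,
                "ci_low": None if ratio is None else float(np.exp(est - z_crit * s)),
                "ci_high": None if ratio is None else float(np.exp(est + z_crit * s)),
                "z": zstat,
                "p": 2.0 * norm.sf(abs(zstat)),
            }
        )
    df = pd.DataFrame(rows)
    df.loc[df["part"] == "zero", "measure"] = "OR"
    df.loc[df["part"] == "count", "measure"] = "IRR"
    df.loc[df["part"] == "dispersion", "measure"] = "alpha"
    return df
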