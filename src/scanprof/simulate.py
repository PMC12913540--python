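"""Synthetic inpatient-encounter generator.

Emulates the statistical structure of encounter-level CT-utilization data
from a large tertiary hospital: eleven risk covariates with realistic
marginals, ten MDC-style patient groups with uneven prevalence, and a
scan count drawn from a zero-inflated negative binomial (ZINB) process
whose count-part mean carries a known per-group distortion factor
``delta``.  ``delta > 1`` plants over-scanning, ``delta < 1``
under-scanning, ``delta = 1`` rational scanning — the ground truth that
downstream observed/expected profiling must recover.

The generative model per encounter, given covariate row ``x`` (count
part) and ``z`` (zero part):

    mu  = exp(x' beta) * delta_g        count-part mean, log link
    pi  = expit(z' gamma)               structural-zero probability
    Y   = 0                with probability pi
        = NB2(mu, alpha)   otherwise    (variance mu + alpha mu^2)

``alpha = 0`` degenerates the count part to Poisson; ``pi = 0`` removes
zero inflation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CATEGORICAL_LEVELS, COVARIATES, build_design, design_columns

__all__ = [
    "GroupSpec",
    "CovariateSpec",
    "SimTruth",
    "default_truth",
    "generate_encounters",
    "write_encounters",
    "read_encounters",
]

#: non-covariate columns every encounter table carries
EXTRA_COLUMNS = ("group", "ct_count", "total_cost")
ENCOUNTER_COLUMNS = ("group", "ct_count") + COVARIATES + ("total_cost",)

# linear-predictor magnitude beyond which the generator refuses to sample
_ETA_LIMIT = 50.0


@dataclass(frozen=True)
class GroupSpec:
    """One patient group: label, sampling weight, planted mean distortion."""

    label: str
    weight: float
    delta: float = 1.0


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distributions of the risk covariates.

    Continuous location parameters accept per-group overrides through
    ``by_group`` (e.g. longer stays and higher case-mix index in the
    pre-grouped and polytrauma categories), which creates realistic
    case-mix differences that a risk model can adjust away.
    """

    p_male: float = 0.5434
    age_mean: float = 57.52
    age_sd: float = 15.85
    age_bounds: tuple[float, float] = (0.0, 110.0)
    # dangerous / urgent / stable
    p_admission: tuple[float, float, float] = (0.0231, 0.2952, 0.6817)
    p_first_time_yes: float = 0.6996
    p_critical_yes: float = 0.1793
    p_insured_yes: float = 0.9081
    # none / mild / severe
    p_cc: tuple[float, float, float] = (0.4555, 0.3417, 0.2038)
    p_emergency: float = 0.2337
    # log-normal LOS matched to median 7.0 d, P75 ~ 11.1 d
    los_log_median: float = 1.947
    los_log_sigma: float = 0.686
    surgery_rate: float = 1.7
    # log-normal CMI matched to median 0.90, P75 ~ 1.89; DRG relative
    # weights are bounded in practice, so the tail is truncated
    cmi_log_median: float = -0.105
    cmi_log_sigma: float = 1.10
    cmi_max: float = 12.0
    # hospitalization cost: log-normal, coupled to LOS; filter support only
    cost_log_median: float = 9.6
    cost_log_sigma: float = 0.55
    cost_los_coef: float = 0.7
    #: per-group overrides of continuous location params,
    #: e.g. {"MDCA": {"los_log_median": 3.05, "cmi_log_median": 2.07}}
    by_group: dict[str, dict[str, float]] = field(default_factory=dict)

    _GROUPABLE = (
        "los_log_median",
        "los_log_sigma",
        "cmi_log_median",
        "cmi_log_sigma",
        "age_mean",
        "surgery_rate",
    )

    def per_group(self, param: str, labels: np.ndarray) -> np.ndarray:
        """Vector of a location parameter, honoring by-group overrides."""
        base = getattr(self, param)
        out = np.full(len(labels), float(base))
        for g, overrides in self.by_group.items():
            if param in overrides:
                out[labels == g] = overrides[param]
        return out


@dataclass(frozen=True)
class SimTruth:
    """Complete ground-truth parameterization of one synthetic cohort."""

    n_encounters: int
    groups: tuple[GroupSpec, ...]
    beta: dict[str, float]  # count part, log link, keyed by design column
    gamma: dict[str, float]  # zero part, logit link
    alpha: float  # NB2 dispersion; 0 -> Poisson
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters <= 0:
            raise ValueError("n_encounters must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        w = sum(g.weight for g in self.groups)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"group prevalence weights sum to {w}, not 1")
        for g in self.groups:
            if g.delta <= 0:
                raise ValueError(f"delta must be > 0 (group {g.label!r})")
        cols = set(design_columns())
        for name, coef in (("beta", self.beta), ("gamma", self.gamma)):
            extra = set(coef) - cols
            if extra:
                raise ValueError(f"{name} has unknown design columns: {sorted(extra)}")
            if "intercept" not in coef:
                raise ValueError(f"{name} must include an 'intercept' entry")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        d["groups"] = tuple(GroupSpec(**g) for g in d["groups"])
        cs = d.get("covariate_spec")
        if isinstance(cs, dict):
            cs = dict(cs)
            for key in ("age_bounds", "p_admission", "p_cc"):
                if key in cs:
                    cs[key] = tuple(cs[key])
            d["covariate_spec"] = CovariateSpec(**cs)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SimTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# study-like defaults
# ----------------------------------------------------------------------

#: ten MDC-style groups; weights are encounter-share marginals of the
#: emulated cohort, deltas plant the qualitative over/under/rational pattern
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("MDCA", 283 / 29461, 0.72),
    GroupSpec("MDCB", 4458 / 29461, 1.15),
    GroupSpec("MDCF", 6136 / 29461, 1.10),
    GroupSpec("MDCG", 5854 / 29461, 0.88),
    GroupSpec("MDCH", 6389 / 29461, 0.90),
    GroupSpec("MDCI", 3940 / 29461, 1.10),
    GroupSpec("MDCK", 1661 / 29461, 1.12),
    GroupSpec("MDCS", 416 / 29461, 1.00),
    GroupSpec("MDCT", 182 / 29461, 1.00),
    GroupSpec("MDCZ", 142 / 29461, 1.48),
)

#: count-part log-IRRs; clinically signed (sicker, longer-stay, higher
#: case-mix encounters accrue more scans)
DEFAULT_BETA: dict[str, float] = {
    "intercept": 0.02,
    "gender[male]": -0.017,
    "age": 0.005,
    "admission_condition[urgent]": -0.383,
    "admission_condition[stable]": -0.405,
    "first_time[yes]": 0.139,
    "critical_serious[yes]": 0.160,
    "insured[no]": 0.117,
    "cc_grade[mild]": 0.013,
    "cc_grade[severe]": 0.056,
    "admission_method[emergency]": -0.017,
    "los": 0.027,
    "surgery_count": 0.024,
    "cmi": 0.048,
}

#: zero-part log-ORs for the structural-zero (never-scanned) state
DEFAULT_GAMMA: dict[str, float] = {
    "intercept": 1.00,
    "gender[male]": -0.60,
    "age": -0.010,
    "admission_condition[urgent]": -0.90,
    "admission_condition[stable]": -0.50,
    "first_time[yes]": -0.30,
    "critical_serious[yes]": 0.20,
    "insured[no]": 0.30,
    "cc_grade[mild]": -0.50,
    "cc_grade[severe]": -0.40,
    "admission_method[emergency]": 0.50,
    "los": -0.050,
    "surgery_count": -0.050,
    "cmi": 0.0,
}

DEFAULT_ALPHA = 0.30

#: case-mix overrides: pre-grouped (MDCA) and polytrauma (MDCZ) encounters
#: run long stays and high case-mix weights
DEFAULT_BY_GROUP = {
    "MDCA": {
        "los_log_median": 3.05,
        "los_log_sigma": 0.48,
        "cmi_log_median": 2.09,
        "cmi_log_sigma": 0.05,
        "surgery_rate": 4.5,
    },
    "MDCZ": {
        "los_log_median": 2.62,
        "los_log_sigma": 0.55,
        "cmi_log_median": 1.36,
        "cmi_log_sigma": 0.64,
        "surgery_rate": 2.5,
    },
}


def default_truth(n_encounters: int = 29461, seed: int = 0, **overrides) -> SimTruth:
    """Study-like defaults: ZINB counts, ten uneven groups, planted deltas."""
    kwargs: dict = dict(
        n_encounters=n_encounters,
        groups=DEFAULT_GROUPS,
        beta=dict(DEFAULT_BETA),
        gamma=dict(DEFAULT_GAMMA),
        alpha=DEFAULT_ALPHA,
        covariate_spec=CovariateSpec(by_group={k: dict(v) for k, v in DEFAULT_BY_GROUP.items()}),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimTruth(**kwargs)


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    mean_b = np.broadcast_to(mean, x.shape)
    sd_b = np.broadcast_to(sd, x.shape)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean_b[bad], sd_b[bad])
        bad = (x < lo) | (x > hi)
    return x


def _coef_vector(coef: dict[str, float], cols: list[str]) -> np.ndarray:
    return np.array([coef.get(c, 0.0) for c in cols])


def generate_encounters(truth: SimTruth) -> pd.DataFrame:
    """Draw one encounter table from a :class:`SimTruth`.

    Deterministic given ``truth.seed``.  Raises if a covariate draw drives
    a linear predictor non-finite, naming the dominant covariate.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_encounters
    cs = truth.covariate_spec

    labels_all = np.array([g.label for g in truth.groups])
    weights = np.array([g.weight for g in truth.groups])
    deltas = np.array([g.delta for g in truth.groups])
    gidx = rng.choice(len(labels_all), size=n, p=weights / weights.sum())
    group = labels_all[gidx]
    delta = deltas[gidx]

    adm_levels = np.array(CATEGORICAL_LEVELS["admission_condition"])
    cc_levels = np.array(CATEGORICAL_LEVELS["cc_grade"])

    df = pd.DataFrame(
        {
            "group": group,
            "gender": np.where(rng.random(n) < cs.p_male, "male", "female"),
            "age": _truncated_normal(
                rng, cs.per_group("age_mean", group), cs.age_sd, *cs.age_bounds, size=n
            ),
            "admission_condition": adm_levels[
                rng.choice(3, size=n, p=np.asarray(cs.p_admission) / sum(cs.p_admission))
            ],
            "first_time": np.where(rng.random(n) < cs.p_first_time_yes, "yes", "no"),
            "critical_serious": np.where(rng.random(n) < cs.p_critical_yes, "yes", "no"),
            "insured": np.where(rng.random(n) < cs.p_insured_yes, "yes", "no"),
            "cc_grade": cc_levels[
                rng.choice(3, size=n, p=np.asarray(cs.p_cc) / sum(cs.p_cc))
            ],
            "admission_method": np.where(
                rng.random(n) < cs.p_emergency, "emergency", "outpatient"
            ),
            "los": np.exp(
                rng.normal(
                    cs.per_group("los_log_median", group),
                    cs.per_group("los_log_sigma", group),
                )
            ),
            "surgery_count": rng.poisson(cs.per_group("surgery_rate", group)),
            "cmi": np.exp(
                _truncated_normal(
                    rng,
                    cs.per_group("cmi_log_median", group),
                    cs.per_group("cmi_log_sigma", group),
                    -np.inf,
                    np.log(cs.cmi_max),
                    size=n,
                )
            ),
        }
    )
    df["total_cost"] = np.exp(
        cs.cost_log_median
        + cs.cost_los_coef * (np.log(df["los"].to_numpy()) - cs.los_log_median)
        + rng.normal(0.0, cs.cost_log_sigma, n)
    )

    X, cols = build_design(df)
    beta = _coef_vector(truth.beta, cols)
    gamma = _coef_vector(truth.gamma, cols)
    eta = X @ beta + np.log(delta)
    zeta = X @ gamma
    for name, lp in (("count", eta), ("zero", zeta)):
        if not np.all(np.abs(lp) < _ETA_LIMIT):
            i = int(np.argmax(np.abs(lp)))
            contrib = np.abs(X[i] * (beta if name == "count" else gamma))
            worst = cols[int(np.argmax(contrib))]
            raise ValueError(
                f"non-finite/extreme {name}-part linear predictor at row {i} "
                f"(value {lp[i]:.3g}); dominant covariate: {worst!r}"
            )

    mu = np.exp(eta)
    pi = 1.0 / (1.0 + np.exp(-zeta))
    structural = rng.random(n) < pi
    if truth.alpha <= 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / truth.alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    counts[structural] = 0
    df.insert(1, "ct_count", counts)
    return df[list(ENCOUNTER_COLUMNS)]


# ----------------------------------------------------------------------
# CSV round trip
# ----------------------------------------------------------------------

def write_encounters(table: pd.DataFrame, path: str | Path) -> None:
    """Write an encounter table as UTF-8 CSV with canonical columns."""
    missing = [c for c in ENCOUNTER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    table[list(ENCOUNTER_COLUMNS)].to_csv(path, index=False)


def read_encounters(path: str | Path) -> pd.DataFrame:
    """Read and validate an encounter CSV.

    Errors name the offending row and column: unknown categorical levels,
    negative or non-integer counts, non-positive LOS/CMI/cost.
    """
    df = pd.read_csv(path)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {missing}")

    def _fail(col, row, msg):
        raise ValueError(f"{path}: column {col!r}, row {row}: {msg}")

    cc = df["ct_count"]
    if not np.issubdtype(cc.dtype, np.integer):
        frac = cc.to_numpy(dtype=float) % 1 != 0
        if frac.any():
            _fail("ct_count", int(np.flatnonzero(frac)[0]), "non-integer count")
        df["ct_count"] = cc.astype(int)
    neg = df["ct_count"] < 0
    if neg.any():
        _fail("ct_count", int(np.flatnonzero(neg)[0]), "negative count")
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            _fail(col, row, f"unknown level {df[col].iloc[row]!r}; allowed {levels}")
    for col, lo in (("age", 0.0), ("surgery_count", 0)):
        bad = df[col] < lo
        if bad.any():
            _fail(col, int(np.flatnonzero(bad)[0]), f"value below {lo}")
    for col in ("los", "cmi", "total_cost"):
        bad = ~(df[col] > 0)
        if bad.any():
            _fail(col, int(np.flatnonzero(bad)[0]), "non-positive value")
    df["group"] = df["group"].astype(str)
    return df[list(ENCOUNTER_COLUMNS)]
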