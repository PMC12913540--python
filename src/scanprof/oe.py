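"""Observed/expected profiling of patient groups.

For each group g the observed scan total ``O_g = sum y_i`` is compared
with the risk-adjusted expectation ``E_g = sum E[Y|x_i]`` from a fitted
count model via the indirect-standardization ratio ``O_g / E_g``.  The
default 95% interval is the log-scale Wald interval with the expected
total treated as fixed, ``exp(log(O/E) +/- z * sqrt(1/O))`` — the
classical SMR-style construction.  Classification:

* CI entirely above 1  -> over_scanning
* CI entirely below 1  -> under_scanning
* CI containing 1      -> rational

A nonparametric bootstrap (resample encounters, refit the model,
recompute every ratio) provides percentile intervals as internal
validation of the whole procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import ModelFit, ModelSpec, fit as fit_model, predict_expected, predict_variance

__all__ = ["GroupEvaluation", "wald_ci", "evaluate_groups", "bootstrap_ci", "classify"]


@dataclass(frozen=True)
class GroupEvaluation:
    group: str
    n_encounters: int
    observed: int
    expected: float
    oe_ratio: float
    ci_wald: tuple[float, float]
    classification: str
    ci_boot: tuple[float, float] | None = None


def classify(lower: float, upper: float) -> str:
    """Three-way rationality verdict from a CI for O/E."""
    if lower > 1.0:
        return "over_scanning"
    if upper < 1.0:
        return "under_scanning"
    return "rational"


def wald_ci(
    observed: float,
    expected: float,
    level: float = 0.95,
    var_log: float | None = None,
) -> tuple[float, float]:
    """Log-scale Wald CI for O/E.

    By default the variance of log(O/E) is the Poisson-count form 1/O
    (expected treated as fixed) — the classical SMR construction.
    ``var_log`` substitutes another variance for log(O/E), e.g. the
    model-implied count variance used by :func:`evaluate_groups`.

    A zero observed total gets lower bound 0 and a continuity-corrected
    upper bound computed at O + 0.5 (the plain formula is undefined at 0).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if observed < 0 or expected <= 0:
        raise ValueError("need observed >= 0 and expected > 0")
    z = norm.ppf(0.5 + level / 2)
    if observed == 0:
        oc = 0.5
        half0 = z * np.sqrt(var_log) if var_log is not None else z / np.sqrt(oc)
        return 0.0, float(np.exp(np.log(oc / expected) + half0))
    log_r = np.log(observed / expected)
    half = z * np.sqrt(var_log) if var_log is not None else z / np.sqrt(observed)
    return float(np.exp(log_r - half)), float(np.exp(log_r + half))


def evaluate_groups(
    table: pd.DataFrame,
    fit_: ModelFit,
    level: float = 0.95,
    variance: str = "model",
) -> list[GroupEvaluation]:
    """Independent O/E evaluation of every group present in the table.

    ``variance`` selects the Wald-interval variance for log(O/E):

    * ``"model"`` (default) — sum of the fitted family's per-encounter
      count variances over the group, divided by O^2.  For a Poisson fit
      this reduces to E/O^2 ~ 1/O; for overdispersed fits it widens the
      interval exactly as much as the selected model says it must.
    * ``"poisson"`` — the classical SMR form 1/O regardless of family.
    """
    if "group" not in table.columns or table["group"].isna().any():
        raise ValueError("every encounter must carry a group label")
    if variance not in ("model", "poisson"):
        raise ValueError("variance must be 'model' or 'poisson'")
    expected = predict_expected(fit_, table)
    var_i = predict_variance(fit_, table) if variance == "model" else None
    out = []
    for g, idx in table.groupby("group", sort=True).indices.items():
        obs = int(table["ct_count"].iloc[idx].sum())
        exp_g = float(expected[idx].sum())
        if exp_g <= 0:
            raise ValueError(f"group {g!r} has non-positive expected total")
        ratio = obs / exp_g
        var_log = None
        if var_i is not None:
            var_log = float(var_i[idx].sum()) / max(obs, 0.5) ** 2
        ci = wald_ci(obs, exp_g, level, var_log=var_log)
        out.append(
            GroupEvaluation(
                group=str(g),
                n_encounters=len(idx),
                observed=obs,
                expected=exp_g,
                oe_ratio=ratio,
                ci_wald=ci,
                classification=classify(*ci),
            )
        )
    return out


def bootstrap_ci(
    table: pd.DataFrame,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    base_fit: ModelFit | None = None,
    max_fail_frac: float = 0.10,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for every group's O/E ratio.

    Each of the ``B`` replicates resamples the whole encounter table with
    replacement, refits the model (warm-started at the full-data optimum)
    and recomputes every group ratio, so the intervals carry model as
    well as sampling uncertainty.  Non-convergent replicates are redrawn;
    more than ``max_fail_frac * B`` failures aborts.  A group absent from
    a resample contributes nothing to its interval for that replicate
    (``n_reps`` records per-group coverage).

    Returns a frame indexed by group with ``boot_lower``, ``boot_upper``,
    ``n_reps``, plus attrs ``n_redrawn``.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if base_fit is None:
        base_fit = fit_model(spec, table)
    groups = sorted(table["group"].unique())
    ratios = np.full((B, len(groups)), np.nan)
    n = len(table)
    failures = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        sample = table.iloc[idx].reset_index(drop=True)
        try:
            refit = fit_model(spec, sample, start=base_fit._theta)
            ok = refit.converged
        except (ValueError, FloatingPointError):
            ok = False
        if not ok:
            failures += 1
            if failures > max_fail_frac * B:
                raise RuntimeError(
                    f"bootstrap aborted: {failures} non-convergent resamples "
                    f"(> {max_fail_frac:.0%} of B={B})"
                )
            continue
        evals = evaluate_groups(sample, refit, level)
        by_g = {e.group: e.oe_ratio for e in evals}
        for j, g in enumerate(groups):
            if g in by_g:
                ratios[b, j] = by_g[g]
        b += 1
    lo_q, hi_q = 100 * (0.5 - level / 2), 100 * (0.5 + level / 2)
    rows = []
    for j, g in enumerate(groups):
        vals = ratios[:, j]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "group": g,
                "boot_lower": float(np.percentile(vals, lo_q)),
                "boot_upper": float(np.percentile(vals, hi_q)),
                "n_reps": int(len(vals)),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["n_redrawn"] = failures
    return out
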