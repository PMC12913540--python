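"""Distribution diagnostics driving model choice.

Two tests, both compared to a 1.96 normal cutoff:

* the overdispersion O test — a standardized dispersion-index statistic,
  ``O = sqrt((n-1)/2) * (s^2/ybar - 1)``, asymptotically N(0,1) under
  Poisson equidispersion, large positive values indicating
  variance > mean;
* the Vuong test for non-nested model comparison, here used to ask
  whether a zero-inflated model is preferred over its plain counterpart
  (positive Z favors the zero-inflated model, signalling excess zeros).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import ModelFit

__all__ = ["DiagnosticResult", "overdispersion_test", "vuong_test"]

THRESHOLD = 1.96


@dataclass(frozen=True)
class DiagnosticResult:
    name: str
    statistic: float
    p_value: float
    decision: str
    threshold: float = THRESHOLD

    @property
    def positive(self) -> bool:
        return self.statistic >= self.threshold

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "threshold": self.threshold,
            "decision": self.decision,
        }


def overdispersion_test(
    y, statistic: Callable[[np.ndarray], float] | None = None
) -> DiagnosticResult:
    """O test for overdispersion of a count vector.

    ``statistic`` is a strategy hook for alternative dispersion
    statistics; the default is the standardized dispersion index above.
    P value is two-sided normal.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("overdispersion test needs n >= 2")
    ybar = y.mean()
    s2 = y.var(ddof=1)
    if ybar <= 0 or s2 == 0:
        raise ValueError("degenerate count vector (zero mean or zero variance)")
    if statistic is None:
        O = np.sqrt((n - 1) / 2.0) * (s2 / ybar - 1.0)
    else:
        O = statistic(y)
    O = float(O)
    p = float(2.0 * norm.sf(abs(O)))
    decision = "overdispersed" if O >= THRESHOLD else "not overdispersed"
    return DiagnosticResult("overdispersion_O", O, p, decision)


def vuong_test(fit_a: ModelFit, fit_b: ModelFit, table: pd.DataFrame,
               correction: str | None = None) -> DiagnosticResult:
    """Vuong closeness test of fit_a against fit_b on the same data.

    ``Z = sqrt(n) * mean(m) / sd(m)`` with ``m_i`` the per-encounter
    log-likelihood difference a minus b.  ``Z >= 1.96`` prefers model a
    (conventionally the zero-inflated candidate).  ``correction`` in
    {None, "aic", "bic"} applies the classical parameter-count penalty
    to the mean difference.
    """
    if fit_a.n != fit_b.n:
        raise ValueError(f"fits are on different sample sizes ({fit_a.n} vs {fit_b.n})")
    la = fit_a.loglik_obs(table)
    lb = fit_b.loglik_obs(table)
    if len(la) != fit_a.n:
        raise ValueError("table does not match the fitted sample size")
    m = la - lb
    n = len(m)
    s = m.std(ddof=1)
    if s == 0:
        raise ValueError("identical likelihoods: Vuong statistic undefined")
    mbar = m.mean()
    if correction == "aic":
        mbar -= (fit_a.k_params - fit_b.k_params) / n
    elif correction == "bic":
        mbar -= (fit_a.k_params - fit_b.k_params) * np.log(n) / (2.0 * n)
    elif correction is not None:
        raise ValueError("correction must be None, 'aic' or 'bic'")
    Z = float(np.sqrt(n) * mbar / s)
    p = float(norm.sf(Z))  # one-sided: preference for model a
    decision = (
        "zero-inflated model preferred" if Z >= THRESHOLD
        else "zero-inflated model not preferred"
    )
    return DiagnosticResult("vuong", Z, p, decision)
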