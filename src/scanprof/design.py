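"""Design-matrix construction for encounter-level risk models.

Categorical risk factors are dummy-encoded against fixed clinical reference
levels (female sex, dangerous admission condition, repeat hospitalization,
no critical/serious condition, insured, no complication/comorbidity,
outpatient admission).  Continuous covariates (age, length of stay, surgery
count, case-mix index) enter linearly and untransformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical covariate columns of an encounter table, in model order
COVARIATES: tuple[str, ...] = (
    "gender",
    "age",
    "admission_condition",
    "first_time",
    "critical_serious",
    "insured",
    "cc_grade",
    "admission_method",
    "los",
    "surgery_count",
    "cmi",
)

#: allowed levels per categorical column; the first level is the reference
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "admission_condition": ("dangerous", "urgent", "stable"),
    "first_time": ("no", "yes"),
    "critical_serious": ("no", "yes"),
    "insured": ("yes", "no"),
    "cc_grade": ("none", "mild", "severe"),
    "admission_method": ("outpatient", "emergency"),
}

CONTINUOUS: tuple[str, ...] = ("age", "los", "surgery_count", "cmi")


def design_columns(covariates: tuple[str, ...] = COVARIATES) -> list[str]:
    """Names of design-matrix columns (intercept first) for a covariate list."""
    cols = ["intercept"]
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            cols.extend(f"{cov}[{lv}]" for lv in CATEGORICAL_LEVELS[cov][1:])
        else:
            cols.append(cov)
    return cols


def build_design(
    table: pd.DataFrame, covariates: tuple[str, ...] = COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Build the (n, k) design matrix with intercept and dummy encoding.

    Raises
    ------
    ValueError
        if a required column is missing or a categorical column contains a
        level outside its declared set (e.g. a level unseen at fit time).
    """
    n = len(table)
    cols = design_columns(covariates)
    X = np.empty((n, len(cols)))
    X[:, 0] = 1.0
    j = 1
    for cov in covariates:
        if cov not in table.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        if cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            values = table[cov].to_numpy()
            known = np.isin(values, levels)
            if not known.all():
                bad = values[~known][0]
                row = int(np.flatnonzero(~known)[0])
                raise ValueError(
                    f"unknown level {bad!r} in column {cov!r} (row {row}); "
                    f"allowed: {levels}"
                )
            for lv in levels[1:]:
                X[:, j] = values == lv
                j += 1
        else:
            vals = np.asarray(table[cov], dtype=float)
            if not np.isfinite(vals).all():
                row = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise ValueError(f"non-finite value in column {cov!r} (row {row})")
            X[:, j] = vals
            j += 1
    return X, cols


def check_full_rank(X: np.ndarray, cols: list[str]) -> None:
    """Raise naming the offending columns if the design is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint columns whose removal restores full column rank
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        suspect = [c for c, d in zip(cols, diag) if d < tol]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {suspect or 'undetermined'}"
        )
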