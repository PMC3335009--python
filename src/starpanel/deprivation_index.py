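"""Socioeconomic deprivation index from county census variables.

A single common factor is extracted from a county-by-variable table of
census percentages (the canonical six items: no high-school education,
unemployment, crowded housing, no car, no telephone, below poverty).
Extraction is iterated principal-axis factoring on the correlation matrix
(a maximum-likelihood one-factor fit is available via ``method``);
loadings are sign-oriented so deprivation-direction variables load
positively, counties are scored by the regression method and standardized
(mean 0, sd 1, higher = more deprived).  Scale reliability is Cronbach's
alpha; index stability across census periods is a Pearson correlation of
the two score vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

__all__ = [
    "FactorModel",
    "DEFAULT_ITEMS",
    "fit_single_factor",
    "cronbach_alpha",
    "score_counties",
    "cross_period_correlation",
]

DEFAULT_ITEMS = (
    "pct_no_highschool",
    "pct_unemployed",
    "pct_crowded_housing",
    "pct_no_car",
    "pct_no_telephone",
    "pct_below_poverty",
)


@dataclass(frozen=True)
class FactorModel:
    """One-factor solution: loadings, communalities, reliability, scoring."""

    variables: tuple[str, ...]
    loadings: np.ndarray
    communalities: np.ndarray
    variance_explained: float
    alpha: float
    scoring_weights: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    if "county_id" in table.columns:
        table = table.set_index("county_id")
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least 2 census variables")
    if num.isna().any().any():
        raise ValueError("census table has missing values")
    return num


def fit_single_factor(table: pd.DataFrame, method: str = "pa") -> FactorModel:
    """Extract one common factor from a county x variable census table.

    ``method`` is ``"pa"`` (iterated principal axis, default) or ``"ml"``.
    Variables are standardized internally; the factor is oriented so the
    average loading is positive (deprivation-direction items load
    positively when they dominate the table).
    """
    num = _validate_table(table)
    n, k = num.shape
    if n <= k:
        raise ValueError(f"need more counties ({n}) than variables ({k})")
    X = num.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        dead = [num.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant variables cannot be factored: {dead}")
    corr = np.corrcoef(X, rowvar=False)
    if np.linalg.matrix_rank(corr, tol=1e-10) < k:
        # name a collinear pair for the error message
        offdiag = np.abs(corr - np.eye(k))
        i, j = np.unravel_index(np.argmax(offdiag), corr.shape)
        raise ValueError(
            "singular correlation matrix; collinear variables include "
            f"{num.columns[i]!r} and {num.columns[j]!r}"
        )
    res = Factor(X, n_factor=1, method=method).fit()
    loadings = np.asarray(res.loadings).ravel()
    if loadings.mean() < 0:
        loadings = -loadings
    communalities = np.clip(loadings**2, 0.0, 1.0)
    # regression-method scoring weights on standardized variables
    weights = np.linalg.solve(corr, loadings)
    return FactorModel(
        variables=tuple(num.columns),
        loadings=loadings,
        communalities=communalities,
        variance_explained=float((loadings**2).sum() / k),
        alpha=cronbach_alpha(num),
        scoring_weights=weights,
        column_means=X.mean(axis=0),
        column_sds=sds,
    )


def cronbach_alpha(table: pd.DataFrame) -> float:
    """Internal-consistency reliability of the item set.

    alpha = (k / (k - 1)) * (1 - sum of item variances / variance of the
    item sum).
    """
    num = _validate_table(table)
    X = num.to_numpy(dtype=float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def score_counties(model: FactorModel, table: pd.DataFrame) -> pd.Series:
    """Standardized per-county factor scores (mean 0, sd 1, higher = more deprived)."""
    num = _validate_table(table)
    if tuple(num.columns) != model.variables:
        raise ValueError(
            f"variable mismatch: model has {list(model.variables)}, table has "
            f"{list(num.columns)}"
        )
    Z = (num.to_numpy(dtype=float) - model.column_means) / model.column_sds
    raw = Z @ model.scoring_weights
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate scores (no county variation)")
    return pd.Series((raw - raw.mean()) / sd, index=num.index, name="deprivation_index")


def cross_period_correlation(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Pearson correlation of two score vectors over the same counties."""
    a, b = pd.Series(scores_a), pd.Series(scores_b)
    if set(a.index) != set(b.index):
        raise ValueError("score vectors cover different county sets")
    b = b.loc[a.index]
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("correlation undefined for constant scores")
    return float(np.corrcoef(a.to_numpy(dtype=float), b.to_numpy(dtype=float))[0, 1])
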