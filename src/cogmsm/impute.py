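"""missForest-style chained imputation of item-level missingness.

Missing covariate cells at *observed* waves (never rows lost to attrition —
those rows simply do not exist in the panel) are filled by iterative chained
imputation: initialise missing cells with the column mean (numeric) or mode
(categorical), then cycle variable by variable fitting a random forest of that
variable on all the others, re-predicting the missing cells, until the change
between successive imputations falls below a tolerance or the iteration cap is
reached. Observed cells are never altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .panel import CohortPanel


class UnimputableError(ValueError):
    """A variable has no observed values to learn from."""


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def _encode_others(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Design matrix from predictor columns; categoricals one-hot encoded."""
    parts = []
    for c in cols:
        s = df[c]
        if _is_numeric(s):
            parts.append(s.to_numpy(dtype=float).reshape(-1, 1))
        else:
            parts.append(pd.get_dummies(s).to_numpy(dtype=float))
    return np.hstack(parts) if parts else np.empty((len(df), 0))


def impute_covariates(panel: CohortPanel, variables: list[str], seed: int,
                      max_iter: int = 10, tol: float = 1e-4,
                      n_estimators: int = 100) -> CohortPanel:
    """Impute missing values in the listed covariates of a panel.

    Deterministic given ``seed``. Variables with no missing values are left
    untouched; a panel with nothing missing is returned unchanged.

    Raises
    ------
    UnimputableError
        If a listed variable is missing in every row.
    """
    df = panel.data.copy()
    for v in variables:
        if v not in df.columns:
            raise KeyError(f"variable {v!r} not in panel")
        if df[v].isna().all():
            raise UnimputableError(f"variable {v!r} has no observed values")

    miss_masks = {v: df[v].isna().to_numpy() for v in variables}
    if not any(m.any() for m in miss_masks.values()):
        return panel

    # initialise with column mean / mode
    work = df.copy()
    for v in variables:
        s = work[v]
        if _is_numeric(s):
            work[v] = s.fillna(s.mean())
        else:
            work[v] = s.fillna(s.mode().iloc[0])

    rng = np.random.default_rng(seed)
    # impute variables in increasing order of missingness, as missForest does
    order = sorted((v for v in variables if miss_masks[v].any()),
                   key=lambda v: miss_masks[v].sum())
    predictors_all = [c for c in panel.covariate_names]

    for _ in range(max_iter):
        delta_num = 0.0
        denom = 0.0
        n_cat_changed = 0
        for v in order:
            mask = miss_masks[v]
            others = [c for c in predictors_all if c != v]
            X = _encode_others(work, others)
            y = work[v]
            est_seed = int(rng.integers(0, 2**31 - 1))
            if _is_numeric(y):
                est = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=est_seed, n_jobs=1)
                est.fit(X[~mask], y[~mask].to_numpy(dtype=float))
                new = est.predict(X[mask])
                old = work.loc[mask, v].to_numpy(dtype=float)
                delta_num += float(np.sum((new - old) ** 2))
                denom += float(np.sum(np.asarray(new, dtype=float) ** 2)) or 1.0
                work.loc[mask, v] = new
            else:
                est = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=est_seed, n_jobs=1)
                est.fit(X[~mask], y[~mask])
                new = est.predict(X[mask])
                n_cat_changed += int(np.sum(new != work.loc[mask, v].to_numpy()))
                work.loc[mask, v] = new
        rel_change = delta_num / denom if denom > 0 else 0.0
        if rel_change < tol and n_cat_changed == 0:
            break

    # observed cells must be bit-identical to the input
    for v in variables:
        df.loc[miss_masks[v], v] = work.loc[miss_masks[v], v]
    return CohortPanel(df)
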