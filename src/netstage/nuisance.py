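"""Ordinary least-squares nuisance removal shared by the pipeline stages.

Both seed definition (age, gender, education, APOE e4 removed from the
voxel data) and the group comparisons (age, gender, education, APOE e4,
ICV, scan site removed from the network scores) residualise a response
matrix against a covariate design before any permutation machinery runs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["build_design", "residualize"]


def build_design(
    covariates: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Covariate table -> numeric design matrix (+ column names).

    Categorical / object columns of a DataFrame are dummy-coded with the
    first level dropped; numeric columns pass through.
    """
    if isinstance(covariates, pd.DataFrame):
        num = pd.get_dummies(covariates, drop_first=True, dtype=float)
        names = list(num.columns)
        X = num.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    return X, names


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns that do not increase the design rank."""
    bad: list[str] = []
    kept = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
            kept = cand
        else:
            bad.append(names[j])
    return bad


def residualize(
    values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    add_intercept: bool = True,
) -> np.ndarray:
    """Per-column OLS residuals of ``values`` on the covariate design.

    With ``covariates=None`` the columns are simply mean-centered (the
    intercept-only model).  Raises ``ValueError`` naming the collinear
    columns when the design is rank deficient.
    """
    Y = np.asarray(values, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if covariates is None:
        resid = Y - Y.mean(axis=0, keepdims=True)
        return resid[:, 0] if squeeze else resid
    X, names = build_design(covariates, add_intercept=add_intercept)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("covariates are not row-aligned with the data")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid
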