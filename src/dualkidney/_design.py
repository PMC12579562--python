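"""Shared design-matrix construction for regression models.

Categorical covariates enter as reference-coded indicator columns; the
reference level is the first level in sorted order (or the first declared
category for pandas Categorical columns). Boolean columns become 0/1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)


def build_design_matrix(
    df: pd.DataFrame,
    covariates: list[str],
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) for ``covariates``.

    ``columns`` fixes the output column set (for prediction on new data);
    unseen indicator columns are filled with 0 and extra levels dropped.
    """
    parts: list[pd.DataFrame] = []
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate not in data: {cov!r}")
        s = df[cov]
        if is_categorical(s):
            levels = (
                list(s.cat.categories)
                if isinstance(s.dtype, pd.CategoricalDtype)
                else sorted(pd.unique(s.dropna()))
            )
            dummies = pd.get_dummies(pd.Categorical(s, categories=levels), dtype=float)
            dummies.columns = [f"{cov}[{lev}]" for lev in levels]
            parts.append(dummies.iloc[:, 1:].set_index(df.index))  # drop reference
        elif s.dtype == bool:
            parts.append(s.astype(float).to_frame(cov))
        else:
            parts.append(s.astype(float).to_frame(cov))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    if columns is not None:
        X = X.reindex(columns=columns, fill_value=0.0)
    return X


def check_full_rank(X: pd.DataFrame, with_intercept: bool = True) -> None:
    """Raise ``np.linalg.LinAlgError`` naming the issue if X is rank-deficient."""
    na_cols = [c for c in X.columns if X[c].isna().any()]
    if na_cols:
        raise ValueError(f"design matrix has missing values in {na_cols}; "
                         "impute before model fitting")
    M = X.to_numpy(dtype=float)
    if with_intercept:
        M = np.column_stack([np.ones(len(M)), M])
    if not len(M):
        return
    # rank via the (small) Gram matrix rather than an n x p SVD
    rank = np.linalg.matrix_rank(M.T @ M, hermitian=True)
    if rank < M.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient ({M.shape[1]} columns, "
            f"rank {rank}); remove collinear covariates"
        )
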