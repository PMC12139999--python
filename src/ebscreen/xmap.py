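"""Cross-dataset cell-type correspondence by reciprocal non-negative regression.

To ask which cell type in one dataset (say, EBs) corresponds to which cell
type in another (say, gastrulating embryos), each target type's pseudobulk
expression profile ``T_a`` is regressed on the full panel of the other
dataset's type profiles ``M_b`` under a non-negativity constraint on the
type coefficients (the intercept is free):

    T_a = beta_0a + beta_1a . M_b,   beta_1a >= 0

restricted to the union of the target type's 1,500 most highly expressed
and 1,500 most specific genes.  Running the regression in both directions
and combining the coefficients,

    beta = 2 (beta_ab + 0.01) (beta_ba + 0.01),

yields a symmetric score that is high only for reciprocally, specifically
predictive type pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["marker_gene_union", "nnls_correspondence"]


def marker_gene_union(
    profiles: pd.DataFrame, target_type: str, n_top: int = 1500
) -> list[str]:
    """Union of the most expressed and most specific genes of one type.

    ``profiles`` is a cell-type x gene matrix of mean log-normalised
    expression.  Specificity of a gene for the target type is its
    expression there minus its mean expression across the other types.
    Ties break by gene id, so the set is deterministic.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two cell types")
    if target_type not in profiles.index:
        raise KeyError(f"unknown cell type {target_type!r}")
    if n_top > profiles.shape[1]:
        warnings.warn(
            f"n_top={n_top} exceeds the {profiles.shape[1]} available genes; using all"
        )
        return sorted(profiles.columns)

    expr = profiles.loc[target_type]
    others = profiles.drop(index=target_type)
    spec = expr - others.mean(axis=0)

    def top(series: pd.Series) -> list[str]:
        order = sorted(series.index, key=lambda g: (-series[g], g))
        return order[:n_top]

    return sorted(set(top(expr)) | set(top(spec)))


def _nnls_with_intercept(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||y - b0 - M w||^2 with w >= 0, intercept unconstrained.

    The intercept is modelled as a +1/-1 column pair so the whole system
    stays a plain NNLS problem.
    """
    n = len(y)
    ones = np.ones((n, 1))
    A = np.hstack([ones, -ones, M])
    coef, _ = nnls(A, y)
    return coef[2:], float(coef[0] - coef[1])


def _fit_direction(
    A: pd.DataFrame, B: pd.DataFrame, n_top: int
) -> pd.DataFrame:
    """Coefficients for predicting each type of A from all types of B."""
    rows = {}
    for a in A.index:
        genes = marker_gene_union(A, a, n_top=n_top)
        y = A.loc[a, genes].to_numpy(float)
        M = B[genes].to_numpy(float).T  # genes x types_b
        if not np.any(y):
            warnings.warn(f"profile of {a!r} is all zero; coefficients set to 0")
            rows[a] = np.zeros(B.shape[0])
            continue
        w, _ = _nnls_with_intercept(M, y)
        rows[a] = w
    return pd.DataFrame.from_dict(rows, orient="index", columns=B.index)


def nnls_correspondence(
    A: pd.DataFrame,
    B: pd.DataFrame,
    n_top: int = 1500,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Reciprocal NNLS correspondence between two pseudobulk profile sets.

    ``A`` and ``B`` are cell-type x gene matrices (mean log-normalised
    expression).  Gene universes are intersected first; each direction
    restricts to the target type's own marker-gene union.  Returns a
    long-format DataFrame with columns ``type_a``, ``type_b``,
    ``beta_ab``, ``beta_ba`` and ``combined`` = ``2(beta_ab+eps)(beta_ba+eps)``.
    The combined score is bounded below by ``2 eps^2`` (2e-4 at the default).
    """
    shared = sorted(set(A.columns) & set(B.columns))
    if not shared:
        raise ValueError("no shared genes between the two datasets")
    dropped = (set(A.columns) | set(B.columns)) - set(shared)
    if dropped:
        warnings.warn(f"{len(dropped)} unmatched genes dropped")
    A = A[shared]
    B = B[shared]

    fwd = _fit_direction(A, B, n_top)  # beta_ab: predicting a from B's types
    rev = _fit_direction(B, A, n_top)  # beta_ba: predicting b from A's types

    records = []
    for a in A.index:
        for b in B.index:
            beta_ab = float(fwd.at[a, b])
            beta_ba = float(rev.at[b, a])
            records.append(
                (a, b, beta_ab, beta_ba, 2.0 * (beta_ab + eps) * (beta_ba + eps))
            )
    return pd.DataFrame(
        records, columns=["type_a", "type_b", "beta_ab", "beta_ba", "combined"]
    )
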