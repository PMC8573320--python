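"""Independent cross-checks for the REML engine.

These routines deliberately avoid the engine's per-tree Cholesky/profiling
path: the marginal covariance of the *entire* response vector is assembled
as one dense N x N matrix and the restricted likelihood is evaluated with
explicit inverses and log-determinants.  They exist to validate the engine
on small instances, not to fit models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from xylemkit.mixed_model import ModelSpec, VarianceParams, build_design


def _ordered_arrays(data: pd.DataFrame, spec: ModelSpec, tree_col, year_col):
    X, terms, Z, _, _, _ = build_design(data, spec)
    tree = data[tree_col].to_numpy()
    year = data[year_col].to_numpy(dtype=float)
    order = np.lexsort((year, tree))
    return (
        data["y"].to_numpy(dtype=float)[order],
        X[order],
        Z[order],
        tree[order],
        year[order],
    )


def dense_covariance(
    data: pd.DataFrame,
    spec: ModelSpec,
    params: VarianceParams,
    *,
    tree_col: str = "tree_id",
    year_col: str = "year",
):
    """Explicit N x N marginal covariance (rows sorted by tree, year)."""
    y, X, Z, tree, year = _ordered_arrays(data, spec, tree_col, year_col)
    n = len(y)
    D = np.diag(np.asarray(params.re_sd, float) ** 2)
    trees = pd.unique(tree)
    wmap = {t: params.weights[i] for i, t in enumerate(trees)}
    V = np.zeros((n, n))
    for t in trees:
        idx = np.flatnonzero(tree == t)
        gaps = np.abs(np.subtract.outer(year[idx], year[idx]))
        R = params.phi ** gaps if params.phi != 0.0 else np.eye(len(idx))
        block = Z[idx] @ D @ Z[idx].T + params.sigma**2 * wmap[t] ** 2 * R
        V[np.ix_(idx, idx)] = block
    return y, X, V


def dense_restricted_loglik(
    data: pd.DataFrame,
    spec: ModelSpec,
    params: VarianceParams,
    *,
    tree_col: str = "tree_id",
    year_col: str = "year",
) -> float:
    """Restricted log-likelihood from the fully assembled covariance matrix.

    lR = -1/2 [ log|V| + log|X'V^-1 X| + r'V^-1 r + (N-p) log 2 pi ]
    with r the dense-GLS residual.
    """
    y, X, V = dense_covariance(
        data, spec, params, tree_col=tree_col, year_col=year_col
    )
    n, p = X.shape
    Vinv = np.linalg.inv(V)
    sign_v, logdet_v = np.linalg.slogdet(V)
    if sign_v <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    A = X.T @ Vinv @ X
    sign_a, logdet_a = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    quad = float(r @ Vinv @ r)
    return -0.5 * (logdet_v + logdet_a + quad + (n - p) * np.log(2.0 * np.pi))


def ols_beta(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Ordinary least squares fixed effects (closed form)."""
    X, _, _, _, _, _ = build_design(data, spec)
    y = data["y"].to_numpy(dtype=float)
    return np.linalg.lstsq(X, y, rcond=None)[0]


def gls_ar1_beta(
    data: pd.DataFrame,
    spec: ModelSpec,
    phi: float,
    *,
    tree_col: str = "tree_id",
    year_col: str = "year",
) -> np.ndarray:
    """Closed-form GLS fixed effects under a pure AR1 error covariance.

    No random effects, equal tree weights: V is block-diagonal with
    phi^|year gap| blocks, inverted densely.
    """
    params = VarianceParams(
        re_sd=np.zeros(0), phi=phi, weights=np.ones(data[tree_col].nunique()),
        sigma=1.0,
    )
    spec0 = ModelSpec(**{**spec.__dict__, "random_terms": ()})
    spec0.climate = spec.climate
    y, X, V = dense_covariance(
        data, spec0, params, tree_col=tree_col, year_col=year_col
    )
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    # rows were re-ordered identically for X and y, so beta is order-free
    return beta
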