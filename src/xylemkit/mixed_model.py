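"""Hierarchical mixed models for trait chronologies.

Each trait x ring-portion chronology is modelled as

    y_ijt = x_ijt' beta + z_ijt' b_i + e_it

with fixed effects for site (reference-coded), standardized tree height h
and h^2, eight seasonal climate predictors, and site x climate
interactions; per-tree random intercept and random slopes for h and h^2
with *diagonal* covariance D; and within-tree errors that are AR1 in time
(continuous-lag: corr = phi^|year gap|) with per-tree relative standard
deviations (heteroscedastic trees, first tree's multiplier fixed at 1).

Estimation is restricted maximum likelihood.  The residual variance and the
fixed effects are profiled out analytically (generalized least squares at
each variance-parameter value), leaving an unconstrained optimization over
log random-effect SDs, Fisher-z of phi, and log weight multipliers.

The restricted log-likelihood, for V = blockdiag_i(Z_i D Z_i' +
sigma^2 w_i^2 R_i(phi)) and r = y - X beta_GLS, is

    lR = -1/2 [ log|V| + log|X' V^-1 X| + r' V^-1 r + (N-p) log 2 pi ].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrs

logger = logging.getLogger(__name__)

#: traits modelled on the natural-log scale
LOG_TRAITS = frozenset({"tb2", "cwt"})

TRAITS = ("la", "tb2", "den", "cwt")
PORTIONS = ("ew", "lw")

STAR_RULES = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_stars(p: float) -> str:
    for cut, mark in STAR_RULES:
        if p < cut:
            return mark
    return ""


# ---------------------------------------------------------------------------
# model specification and standardization
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """What to regress on what, and which covariance structure to use."""

    response: str  # trait column, e.g. "la"
    portion: str = "ew"
    log_transform: bool | None = None  # default: trait in LOG_TRAITS
    climate: tuple[str, ...] = ()  # filled from climate_season if empty
    site_col: str = "site"
    reference_site: str | None = None  # default "W-D" when present
    height_col: str = "height_m"
    random_terms: tuple[str, ...] = ("intercept", "h", "h2")
    ar1: bool = True
    tree_weights: bool = True
    interactions: bool = True

    def __post_init__(self):
        if not self.climate:
            from xylemkit.climate_season import PREDICTOR_COLUMNS

            self.climate = tuple(PREDICTOR_COLUMNS)
        if self.log_transform is None:
            self.log_transform = self.response in LOG_TRAITS
        bad = set(self.random_terms) - {"intercept", "h", "h2"}
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")


@dataclass
class StandardizationRecord:
    """Means/SDs used for z-scoring, enabling exact back-transformation."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_vars: set[str] = field(default_factory=set)

    def transform_value(self, var: str, x):
        x = np.asarray(x, dtype=float)
        if var in self.log_vars:
            x = np.log(x)
        m, s = self.stats[var]
        return (x - m) / s

    def inverse_value(self, var: str, z):
        m, s = self.stats[var]
        x = np.asarray(z, dtype=float) * s + m
        if var in self.log_vars:
            x = np.exp(x)
        return x

    def sd(self, var: str) -> float:
        return self.stats[var][1]


def _zscore(x: pd.Series, name: str, record: StandardizationRecord):
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if not np.isfinite(s) or s <= 0:
        raise ValueError(f"variable {name!r} has zero variance; cannot standardize")
    record.stats[name] = (m, s)
    return (x - m) / s


def standardize(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, StandardizationRecord]:
    """Log-transform (where flagged) and z-score response and predictors.

    Adds columns ``y`` (standardized response), ``h`` and ``h2``
    (standardized height and squared height) and replaces the climate
    columns by their z-scores.  Standardization is global (across sites and
    trees).  Returns the transformed copy plus the record needed to undo it.
    """
    df = data.copy()
    record = StandardizationRecord()

    y = df[spec.response].astype(float)
    if spec.log_transform:
        if (y <= 0).any():
            raise ValueError(
                f"response {spec.response!r} has non-positive values; "
                "cannot log-transform"
            )
        record.log_vars.add(spec.response)
        y = np.log(y)
    df["y"] = _zscore(y, spec.response, record)

    h = df[spec.height_col].astype(float)
    df["h"] = _zscore(h, "h", record)
    df["h2"] = _zscore(h**2, "h2", record)
    for c in spec.climate:
        df[c] = _zscore(df[c].astype(float), c, record)
    return df, record


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def build_design(df: pd.DataFrame, spec: ModelSpec):
    """Fixed- and random-effects design matrices from a standardized dataset.

    Returns ``(X, terms, Z, z_terms, sites, reference)`` where ``terms``
    names the columns of X: intercept, non-reference site indicators, h,
    h^2, the climate predictors, and site x climate interactions.
    """
    sites = sorted(df[spec.site_col].astype(str).unique())
    ref = spec.reference_site
    if ref is None:
        ref = "W-D" if "W-D" in sites else sites[0]
    if ref not in sites:
        raise ValueError(f"reference site {ref!r} not present (sites: {sites})")
    others = [s for s in sites if s != ref]

    cols = [np.ones(len(df))]
    terms = ["(Intercept)"]
    site_ind = {}
    for s in others:
        ind = (df[spec.site_col].astype(str) == s).to_numpy(dtype=float)
        site_ind[s] = ind
        cols.append(ind)
        terms.append(f"site[{s}]")
    cols.append(df["h"].to_numpy())
    terms.append("h")
    cols.append(df["h2"].to_numpy())
    terms.append("h2")
    for c in spec.climate:
        cols.append(df[c].to_numpy(dtype=float))
        terms.append(c)
    if spec.interactions:
        for s in others:
            for c in spec.climate:
                cols.append(site_ind[s] * df[c].to_numpy(dtype=float))
                terms.append(f"site[{s}]:{c}")
    X = np.column_stack(cols)

    z_cols, z_terms = [], []
    if "intercept" in spec.random_terms:
        z_cols.append(np.ones(len(df)))
        z_terms.append("(Intercept)")
    if "h" in spec.random_terms:
        z_cols.append(df["h"].to_numpy())
        z_terms.append("h")
    if "h2" in spec.random_terms:
        z_cols.append(df["h2"].to_numpy())
        z_terms.append("h2")
    Z = np.column_stack(z_cols) if z_cols else np.zeros((len(df), 0))
    return X, terms, Z, z_terms, sites, ref


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------


@dataclass
class VarianceParams:
    """Variance-structure parameters on their natural scale.

    ``re_sd`` are the random-effect SDs (response scale), ``phi`` the AR1
    coefficient, ``weights`` the per-tree relative residual SD multipliers
    (first tree 1), ``sigma`` the residual SD of the first tree.
    """

    re_sd: np.ndarray
    phi: float
    weights: np.ndarray
    sigma: float


class _Problem:
    """Per-tree views of the data for likelihood evaluation."""

    def __init__(self, y, X, Z, tree_ids, years, ar1, use_weights):
        order = np.lexsort((years, tree_ids))
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        self.Z = np.asarray(Z, float)[order]
        self.years = np.asarray(years, float)[order]
        self.tree_ids = np.asarray(tree_ids)[order]
        self.order = order
        self.trees = []
        self.slices = []
        ids = self.tree_ids
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                self.trees.append(ids[start])
                self.slices.append(slice(start, i))
                start = i
        self.n_trees = len(self.trees)
        self.N, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.ar1 = ar1
        self.use_weights = use_weights
        # per-tree absolute year-gap matrices for the continuous-lag AR1;
        # trees sharing a year grid share one correlation matrix, and gaps
        # on integer grids use a power-lookup table
        self.gaps = []
        self._gap_sig = []
        sig_map = {}
        for s in self.slices:
            g = np.abs(np.subtract.outer(self.years[s], self.years[s]))
            key = (g.shape[0], g.tobytes())
            if key not in sig_map:
                sig_map[key] = len(self.gaps)
                gi = np.rint(g).astype(np.int64)
                integer = np.allclose(g, gi)
                self.gaps.append((g, gi if integer else None))
            self._gap_sig.append(sig_map[key])
        self._r_cache_phi = None
        self._r_cache = None
        # batched path when every tree has the same number of years
        sizes = {s.stop - s.start for s in self.slices}
        self._batched = len(sizes) == 1 and self.q > 0
        if self._batched:
            n_i = sizes.pop()
            self._Xs = self.X.reshape(self.n_trees, n_i, self.p)
            self._Zs = self.Z.reshape(self.n_trees, n_i, self.q)
            self._ys = self.y.reshape(self.n_trees, n_i)

    def _corr_matrices(self, phi):
        """AR1 correlation matrix per distinct year grid, cached by phi."""
        if self._r_cache_phi == phi:
            return self._r_cache
        mats = []
        for g, gi in self.gaps:
            if phi == 0.0:
                mats.append(np.eye(g.shape[0]))
            elif gi is not None:
                powers = np.sign(phi) ** np.arange(gi.max() + 1) * (
                    np.abs(phi) ** np.arange(gi.max() + 1)
                )
                mats.append(powers[gi])
            else:
                mats.append(np.abs(phi) ** g * np.sign(phi) ** np.rint(g))
        self._r_cache_phi = phi
        self._r_cache = mats
        return mats

    # -- parameter packing ---------------------------------------------------

    def n_params(self):
        return self.q + int(self.ar1) + (self.n_trees - 1 if self.use_weights else 0)

    def unpack(self, theta):
        q = self.q
        log_sd = theta[:q]
        k = q
        if self.ar1:
            phi = np.tanh(theta[k])
            k += 1
        else:
            phi = 0.0
        if self.use_weights:
            w = np.concatenate([[1.0], np.exp(theta[k:])])
        else:
            w = np.ones(self.n_trees)
        return np.exp(log_sd), phi, w

    # -- likelihood ----------------------------------------------------------

    def _sigma_i(self, k, rel_sd, phi, w):
        """Scaled marginal covariance of tree k: Z D* Z' + w^2 R(phi)."""
        s = self.slices[k]
        Zk = self.Z[s]
        R = self._corr_matrices(phi)[self._gap_sig[k]]
        sig = (Zk * rel_sd**2) @ Zk.T + w[k] ** 2 * R
        return sig

    def _accumulate(self, theta):
        """(X'S^-1 X, X'S^-1 y, y'S^-1 y, log|S|) over all trees, at the
        scaled covariance S = Z D* Z' + w^2 R implied by theta."""
        rel_sd, phi, w = self.unpack(theta)
        if self._batched:
            mats = self._corr_matrices(phi)
            R = np.stack([mats[self._gap_sig[k]] for k in range(self.n_trees)])
            Zd = self._Zs * rel_sd**2
            sig = Zd @ self._Zs.transpose(0, 2, 1) + w[:, None, None] ** 2 * R
            L = np.linalg.cholesky(sig)  # raises LinAlgError if not PD
            logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
            rhs = np.concatenate([self._Xs, self._ys[:, :, None]], axis=2)
            sol = np.empty_like(rhs)
            for k in range(self.n_trees):
                x, info = dpotrs(L[k], rhs[k], lower=1)
                if info != 0:
                    raise np.linalg.LinAlgError("dpotrs failed")
                sol[k] = x
            Xs, ys = sol[:, :, :-1], sol[:, :, -1]
            Xt = self._Xs.transpose(0, 2, 1)
            XtSX = (Xt @ Xs).sum(axis=0)
            XtSy = (Xt @ ys[:, :, None]).sum(axis=0).ravel()
            ytSy = float((self._ys * ys).sum())
            return XtSX, XtSy, ytSy, logdet
        p = self.p
        XtSX = np.zeros((p, p))
        XtSy = np.zeros(p)
        ytSy = 0.0
        logdet = 0.0
        for k, s in enumerate(self.slices):
            sig = self._sigma_i(k, rel_sd, phi, w)
            c = cho_factor(sig, lower=True, check_finite=False)
            logdet += 2.0 * np.log(np.diag(c[0])).sum()
            Xs = cho_solve(c, self.X[s], check_finite=False)
            ys = cho_solve(c, self.y[s], check_finite=False)
            XtSX += self.X[s].T @ Xs
            XtSy += self.X[s].T @ ys
            ytSy += self.y[s] @ ys
        return XtSX, XtSy, ytSy, logdet

    def profiled_neg_loglik(self, theta):
        """Negative profiled restricted log-likelihood (to minimize)."""
        try:
            XtSX, XtSy, ytSy, logdet = self._accumulate(theta)
        except np.linalg.LinAlgError:
            return 1e12
        p = self.p
        sign, logdet_xtx = np.linalg.slogdet(XtSX)
        if sign <= 0:
            return 1e12
        try:
            beta = np.linalg.solve(XtSX, XtSy)
        except np.linalg.LinAlgError:
            return 1e12
        rss = ytSy - beta @ XtSy
        dof = self.N - p
        if rss <= 0:
            return 1e12
        sigma2 = rss / dof
        neg = 0.5 * (
            dof * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet + logdet_xtx
        )
        return neg

    def gls(self, theta):
        """GLS fixed effects and dispersion at variance parameters theta."""
        XtSX, XtSy, ytSy, _ = self._accumulate(theta)
        beta = np.linalg.solve(XtSX, XtSy)
        rss = ytSy - beta @ XtSy
        sigma2 = rss / (self.N - self.p)
        cov_beta = sigma2 * np.linalg.inv(XtSX)
        return beta, sigma2, cov_beta

    def restricted_loglik(self, params: VarianceParams):
        """Unprofiled restricted log-likelihood at explicit parameters.

        Shares the model definition with the fitting path but none of the
        profiling; used to compare against the dense-matrix oracle.
        """
        sigma = params.sigma
        rel_sd = np.asarray(params.re_sd, float) / sigma
        theta = self._pack(rel_sd, params.phi, params.weights)
        rel_sd2, phi, w = self.unpack(theta)
        p = self.p
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        for k, s in enumerate(self.slices):
            V = sigma**2 * self._sigma_i(k, rel_sd2, phi, w)
            c = cho_factor(V, lower=True, check_finite=False)
            logdet += 2.0 * np.log(np.diag(c[0])).sum()
            Xs = cho_solve(c, self.X[s], check_finite=False)
            ys = cho_solve(c, self.y[s], check_finite=False)
            XtVX += self.X[s].T @ Xs
            XtVy += self.X[s].T @ ys
            ytVy += self.y[s] @ ys
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - beta @ XtVy
        _, logdet_xtx = np.linalg.slogdet(XtVX)
        return -0.5 * (
            logdet + logdet_xtx + quad + (self.N - p) * np.log(2.0 * np.pi)
        )

    def _pack(self, rel_sd, phi, weights):
        theta = list(np.log(np.maximum(rel_sd, 1e-300)))
        if self.ar1:
            theta.append(np.arctanh(np.clip(phi, -0.999999, 0.999999)))
        if self.use_weights:
            theta.extend(np.log(np.asarray(weights, float)[1:]))
        return np.asarray(theta)

    def blups(self, theta, beta):
        """Per-tree random-effect predictions b_i = D* Z' Sigma^-1 r."""
        rel_sd, phi, w = self.unpack(theta)
        out = {}
        for k, s in enumerate(self.slices):
            sig = self._sigma_i(k, rel_sd, phi, w)
            r = self.y[s] - self.X[s] @ beta
            c = cho_factor(sig, lower=True, check_finite=False)
            out[self.trees[k]] = (rel_sd**2) * (self.Z[s].T @ cho_solve(c, r))
        return out


@dataclass
class MixedModelFit:
    """A converged REML fit: estimates, tests, and everything needed to
    predict."""

    spec: ModelSpec
    coef_table: pd.DataFrame  # term, estimate, se, df, t, p, stars
    cov_beta: np.ndarray
    params: VarianceParams
    re_sd_terms: tuple[str, ...]
    tree_weights: dict
    loglik: float
    fitted_marginal: np.ndarray  # aligned with `data`
    fitted_conditional: np.ndarray
    random_effects: pd.DataFrame  # tree x random term
    data: pd.DataFrame  # standardized modelling frame (original row order)
    record: StandardizationRecord | None
    sites: list[str]
    reference_site: str
    df_inner: int
    df_outer: int
    converged: bool
    boundary: bool
    n_obs: int
    n_trees: int
    optimizer: dict
    _problem: _Problem = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _Z: np.ndarray = field(repr=False, default=None)
    _terms: list = field(repr=False, default=None)
    _z_terms: list = field(repr=False, default=None)

    @property
    def beta(self) -> pd.Series:
        return self.coef_table.set_index("term")["estimate"]

    def coefficients_original_scale(self) -> pd.Series:
        """Fixed effects rescaled to the (possibly log) response scale.

        Predictors are standardized identically in either scale, so the
        back-transformation is a single multiplication by the response SD
        (the intercept also gains the response mean).
        """
        if self.record is None:
            raise ValueError("fit carries no standardization record")
        m, s = self.record.stats[self.spec.response]
        out = self.beta * s
        out["(Intercept)"] += m
        return out


def fit_reml(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    record: StandardizationRecord | None = None,
    tree_col: str = "tree_id",
    year_col: str = "year",
    n_multistart: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> MixedModelFit:
    """Fit the mixed model by REML.

    ``data`` must already be standardized (column ``y`` present, see
    :func:`standardize`).  Optimization runs on unconstrained transforms
    (log SDs relative to the residual SD, Fisher-z phi, log weight
    multipliers) with the residual variance and fixed effects profiled out;
    jittered multistarts guard against local optima.

    Random-effect variances are allowed to collapse to ~0 (boundary fits
    are flagged, not errors).
    """
    if "y" not in data.columns:
        raise ValueError("data has no 'y' column; run standardize() first")
    tree_ids = data[tree_col].to_numpy()
    if len(np.unique(tree_ids)) < 2:
        raise ValueError("need at least 2 trees")

    X, terms, Z, z_terms, sites, ref = build_design(data, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    y = data["y"].to_numpy(dtype=float)
    years = data[year_col].to_numpy(dtype=float)

    prob = _Problem(y, X, Z, tree_ids, years, spec.ar1, spec.tree_weights)
    if prob.N - prob.p < 1:
        raise ValueError("more fixed effects than observations")

    rng = np.random.default_rng(seed)
    n_par = prob.n_params()
    base = np.zeros(n_par)
    base[: prob.q] = np.log(0.5)
    if spec.ar1:
        base[prob.q] = np.arctanh(0.3)

    if n_par == 0:
        # no variance parameters to estimate (pure (G)LS reduction)
        from types import SimpleNamespace

        theta0 = np.zeros(0)
        best = SimpleNamespace(
            x=theta0,
            fun=prob.profiled_neg_loglik(theta0),
            success=True,
            message="no variance parameters",
        )
        return _finalize_fit(
            prob, best, spec, record, terms, z_terms, sites, ref, X, Z, data, 1
        )

    best = None
    tried = 0
    for attempt in range(n_multistart):
        theta0 = base if attempt == 0 else base + rng.normal(0, 0.7, n_par)
        res = optimize.minimize(
            prob.profiled_neg_loglik,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": tol, "gtol": tol},
        )
        tried += 1
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best is not None and attempt == 0 and res.success:
            break  # first start converged; keep it
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"REML optimization failed after {tried} starts "
            f"(best objective {None if best is None else best.fun})"
        )
    if not best.success:
        logger.warning(
            "REML optimizer reported non-convergence (%s); using best point",
            best.message,
        )
    return _finalize_fit(
        prob, best, spec, record, terms, z_terms, sites, ref, X, Z, data, tried
    )


def _finalize_fit(prob, best, spec, record, terms, z_terms, sites, ref, X, Z,
                  data, tried):
    theta = best.x
    beta, sigma2, cov_beta = prob.gls(theta)
    sigma = float(np.sqrt(sigma2))
    rel_sd, phi, w = prob.unpack(theta)
    params = VarianceParams(
        re_sd=rel_sd * sigma, phi=float(phi), weights=w, sigma=sigma
    )
    boundary = bool(np.any(rel_sd < 1e-4))

    # denominator degrees of freedom, inner-outer convention: terms constant
    # within every tree are tested against the between-tree stratum
    within_var = np.array(
        [
            any(np.ptp(X[s, j]) > 1e-12 for s in prob.slices)
            for j in range(X.shape[1])
        ]
    )
    p_inner = int(within_var.sum())
    p_outer = X.shape[1] - p_inner  # includes intercept
    df_inner = prob.N - prob.n_trees - p_inner
    df_outer = max(prob.n_trees - p_outer, 1)
    term_df = np.where(within_var, df_inner, df_outer)
    term_df[terms.index("(Intercept)")] = df_inner

    se = np.sqrt(np.diag(cov_beta))
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), term_df)
    coef = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "se": se,
            "df": term_df,
            "t": tval,
            "p": pval,
            "stars": [p_stars(p) for p in pval],
        }
    )

    blup = prob.blups(theta, beta)
    re_rows = pd.DataFrame(
        {t: {str(k): v[i] for k, v in blup.items()} for i, t in enumerate(z_terms)}
    )
    re_rows.index.name = "tree_id"

    # fitted values in original row order
    fitted_sorted = prob.X @ beta
    cond_sorted = fitted_sorted.copy()
    for k, s in enumerate(prob.slices):
        cond_sorted[s] += prob.Z[s] @ blup[prob.trees[k]]
    inv = np.empty_like(prob.order)
    inv[prob.order] = np.arange(prob.N)
    fit = MixedModelFit(
        spec=spec,
        coef_table=coef,
        cov_beta=cov_beta,
        params=params,
        re_sd_terms=tuple(z_terms),
        tree_weights={str(t): float(w[k]) for k, t in enumerate(prob.trees)},
        loglik=float(-best.fun),
        fitted_marginal=fitted_sorted[inv],
        fitted_conditional=cond_sorted[inv],
        random_effects=re_rows,
        data=data.reset_index(drop=True),
        record=record,
        sites=sites,
        reference_site=ref,
        df_inner=int(df_inner),
        df_outer=int(df_outer),
        converged=bool(best.success),
        boundary=boundary,
        n_obs=prob.N,
        n_trees=prob.n_trees,
        optimizer={
            "n_starts": tried,
            "final_objective": float(best.fun),
            "message": str(best.message),
        },
        _problem=prob,
        _X=X,
        _Z=Z,
        _terms=terms,
        _z_terms=z_terms,
    )
    return fit


def restricted_loglik(
    data: pd.DataFrame,
    spec: ModelSpec,
    params: VarianceParams,
    *,
    tree_col: str = "tree_id",
    year_col: str = "year",
) -> float:
    """Engine-path restricted log-likelihood at explicit variance parameters."""
    X, terms, Z, _, _, _ = build_design(data, spec)
    prob = _Problem(
        data["y"].to_numpy(float),
        X,
        Z,
        data[tree_col].to_numpy(),
        data[year_col].to_numpy(float),
        spec.ar1,
        spec.tree_weights,
    )
    return prob.restricted_loglik(params)


# ---------------------------------------------------------------------------
# marginal means, Tukey contrasts, compact letter display
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    estimate: float
    se: float
    t: float
    p_adjusted: float


def site_contrasts(fit: MixedModelFit, alpha: float = 0.05):
    """Tukey-adjusted pairwise site comparisons of estimated marginal means.

    Marginal means are evaluated at the mean (zero, after standardization)
    of every covariate, where interaction terms vanish, so each site's mean
    is intercept + its site effect.  Adjusted p-values use the studentized
    range distribution with the fit's between-tree degrees of freedom.

    Returns ``(contrasts, letters)`` -- the pairwise table and a compact
    letter display (sites sharing a letter do not differ at ``alpha``).
    """
    terms = fit._terms
    k = len(fit.sites)
    c_vecs = {}
    for s in fit.sites:
        c = np.zeros(len(terms))
        c[terms.index("(Intercept)")] = 1.0
        t = f"site[{s}]"
        if t in terms:
            c[terms.index(t)] = 1.0
        c_vecs[s] = c

    beta = fit.coef_table["estimate"].to_numpy()
    results = []
    sig_pairs = set()
    for a, b in itertools.combinations(fit.sites, 2):
        c = c_vecs[a] - c_vecs[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        tt = est / se
        p = float(
            stats.studentized_range.sf(abs(tt) * np.sqrt(2.0), k, fit.df_outer)
        )
        p = min(max(p, 0.0), 1.0)
        results.append(ContrastResult((a, b), est, se, tt, p))
        if p < alpha:
            sig_pairs.add(frozenset((a, b)))

    letters = _compact_letters(fit.sites, sig_pairs)
    table = pd.DataFrame(
        {
            "site_a": [r.pair[0] for r in results],
            "site_b": [r.pair[1] for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
    return table, letters


def _compact_letters(groups, sig_pairs):
    """Letters from maximal cliques of the 'not significantly different'
    graph (insert-and-absorb equivalent for small group counts)."""
    groups = list(groups)
    n = len(groups)
    cliques = []
    for r in range(n, 0, -1):
        for subset in itertools.combinations(range(n), r):
            ok = all(
                frozenset((groups[i], groups[j])) not in sig_pairs
                for i, j in itertools.combinations(subset, 2)
            )
            if ok and not any(set(subset) <= c for c in cliques):
                cliques.append(set(subset))
    cliques.sort(key=min)
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[groups[i]] += letter
    return letters


# ---------------------------------------------------------------------------
# predictions and counterfactuals
# ---------------------------------------------------------------------------

#: hold targets -> standardized design columns forced to their mean (zero)
HOLD_COLUMNS = {
    "height": ("h", "h2"),
    "summer_temperature": ("summer_temp",),
}


def predict(fit: MixedModelFit, *, conditional: bool = True) -> np.ndarray:
    """Model predictions for the fitted dataset (tree-conditional by default)."""
    return fit.fitted_conditional if conditional else fit.fitted_marginal


def counterfactual_predict(
    fit: MixedModelFit, hold: str, *, conditional: bool = True
) -> np.ndarray:
    """Predictions with one driver held at its (standardized) mean of zero.

    ``hold='height'`` zeroes h and h^2 in both the fixed and random designs
    (so random slopes contribute nothing); ``hold='summer_temperature'``
    zeroes the summer-temperature column and its site interactions.  Output
    rows align with ``fit.data``.
    """
    if hold not in HOLD_COLUMNS:
        raise ValueError(
            f"unknown hold variable {hold!r}; options: {sorted(HOLD_COLUMNS)}"
        )
    zero_cols = HOLD_COLUMNS[hold]
    df = fit.data.copy()
    for c in zero_cols:
        if c in df.columns:
            df[c] = 0.0
    X, terms, Z, z_terms, _, _ = build_design(df, fit.spec)
    beta = fit.coef_table["estimate"].to_numpy()
    pred = X @ beta
    if conditional and Z.shape[1]:
        re = fit.random_effects
        tree_ids = df["tree_id"].astype(str).to_numpy()
        b = re.loc[tree_ids, list(z_terms)].to_numpy()
        pred = pred + np.einsum("ij,ij->i", Z, b)
    return pred


def prediction_table(fit: MixedModelFit) -> pd.DataFrame:
    """Observed, fitted, and counterfactual predictions per row."""
    out = fit.data[["tree_id", "year", fit.spec.site_col]].copy()
    out["observed"] = fit.data["y"].to_numpy()
    out["fitted"] = fit.fitted_conditional
    out["cf_height"] = counterfactual_predict(fit, "height")
    out["cf_summer_temp"] = counterfactual_predict(fit, "summer_temperature")
    return out
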