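"""Ordinary and phylogenetic generalized least squares (PGLS).

PGLS regresses a trait on covariates with residuals correlated according to
the tree: errors are N(0, sigma2 * C(lambda)) where C(lambda) is the
Brownian covariance with Pagel's lambda scaling the off-diagonal.  lambda
is estimated by maximum likelihood jointly with the regression (profile
likelihood over [0, 1]), so a trait-covariate association that exists only
because both follow the phylogeny is absorbed into the error structure.
With lambda = 0 — or on a star phylogeny — PGLS collapses to ordinary
least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .phylo import Phylogeny, normalize_label, transform_lambda
from .tables import AlignmentError, align_covariates, align_trait

__all__ = ["RegressionFit", "ols_fit", "pgls_fit", "RankDeficiencyError"]

logger = logging.getLogger(__name__)


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient (collinear or constant columns)."""


@dataclass
class RegressionFit:
    """A fitted (possibly phylogenetic) linear model.

    ``coefficients`` has one row per predictor (plus the intercept) with
    columns estimate / std_error / t_value / p_value; ``lambda_used`` is
    the ML Pagel's lambda of the error structure, or the string "none" for
    an ordinary (non-phylogenetic) fit.
    """

    coefficients: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_residual: int
    model_p: float
    residual_se: float
    lambda_used: float | str
    loglik: float | None = None
    degenerate: bool = False

    def summary(self) -> str:
        lines = [self.coefficients.round(4).to_string()]
        lines.append(
            f"Residual S.E. = {self.residual_se:.4g}, "
            f"Multiple R-squared = {self.r_squared:.4g}, "
            f"Adj. R-squared = {self.adj_r_squared:.4g}"
        )
        lines.append(
            f"F-statistic = {self.f_statistic:.4g}, DF = {self.df_residual}, "
            f"p-value = {self.model_p:.4g}, lambda = {self.lambda_used}"
        )
        return "\n".join(lines)


def _check_design(X: pd.DataFrame, n: int) -> None:
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"covariate columns contain missing values: {bad}")
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    M = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(M, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(str(col))
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear or constant columns: {bad}"
        )


def _gls_core(y: np.ndarray, M: np.ndarray, L: np.ndarray | None):
    """GLS via whitening with the Cholesky factor L of the error covariance
    (L = None means identity => OLS).  Returns (beta, rss, XtXinv, wy)."""
    if L is None:
        wy, wM = y, M
    else:
        wy = solve_triangular(L, y, lower=True)
        wM = solve_triangular(L, M, lower=True)
    XtX = wM.T @ wM
    XtXinv = np.linalg.inv(XtX)
    beta = XtXinv @ (wM.T @ wy)
    resid = wy - wM @ beta
    rss = float(resid @ resid)
    return beta, rss, XtXinv, wy, wM


def _fit_tables(
    names, y, M, L, lambda_used, loglik=None
) -> RegressionFit:
    n = len(y)
    p = M.shape[1] - 1  # predictors excluding intercept
    beta, rss, XtXinv, wy, wM = _gls_core(y, M, L)
    df_resid = n - (p + 1)
    s2 = rss / df_resid if df_resid > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(XtXinv), 0.0) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    coef = pd.DataFrame(
        {"estimate": beta, "std_error": se, "t_value": tvals, "p_value": pvals},
        index=names,
    )
    # null (intercept-only) model under the same error structure
    ones = M[:, :1]
    _, tss, _, _, _ = _gls_core(y, ones, L)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    degenerate = False
    if p == 0:
        f_stat, model_p, adj_r2 = np.nan, np.nan, np.nan
        degenerate = True
    elif rss <= 1e-12 * max(tss, 1.0):
        f_stat, model_p = np.inf, 0.0
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
        degenerate = True
    else:
        f_stat = ((tss - rss) / p) / (rss / df_resid)
        model_p = float(stats.f.sf(f_stat, p, df_resid))
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    return RegressionFit(
        coefficients=coef,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        f_statistic=float(f_stat),
        df_model=p,
        df_residual=df_resid,
        model_p=float(model_p) if np.isfinite(model_p) else model_p,
        residual_se=float(np.sqrt(s2)),
        lambda_used=lambda_used,
        loglik=loglik,
        degenerate=degenerate,
    )


def _align_xy(y: pd.Series, X: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    ynorm = {normalize_label(str(k)): float(v) for k, v in y.items()}
    xnorm = {normalize_label(str(k)): k for k in X.index}
    common = [k for k in ynorm if k in xnorm]
    if not common:
        raise AlignmentError("no species shared between trait and covariate tables")
    yv = np.array([ynorm[k] for k in common])
    Xs = X.loc[[xnorm[k] for k in common]].copy()
    Xs.index = common
    return yv, Xs, common


def ols_fit(y: pd.Series, X: pd.DataFrame) -> RegressionFit:
    """Ordinary multiple regression of the trait on covariates (with
    intercept), ignoring the phylogeny; ``lambda_used`` is "none"."""
    yv, Xs, _ = _align_xy(y, X)
    n = len(yv)
    _check_design(Xs, n)
    M = np.column_stack([np.ones(n), Xs.to_numpy(dtype=float)])
    names = ["(Intercept)"] + [str(c) for c in Xs.columns]
    return _fit_tables(names, yv, M, None, "none")


def _pgls_profile_loglik(lam, y, M, C0):
    """Profile ML log-likelihood of lambda: beta and sigma2 concentrated out."""
    C = transform_lambda(C0, float(lam))
    try:
        L = np.linalg.cholesky(C.matrix)
    except np.linalg.LinAlgError:
        return -np.inf, None
    _, rss, _, _, _ = _gls_core(y, M, L)
    n = len(y)
    if rss <= 0:
        return -np.inf, L
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return float(ll), L


def pgls_fit(
    tree: Phylogeny,
    y: pd.Series,
    X: pd.DataFrame,
    lambda_: float | None = None,
) -> RegressionFit:
    """PGLS of the trait on covariates with lambda-scaled BM errors.

    Species present in the tree, the trait table and the covariate table
    are intersected (dropped species are logged); lambda is profiled by ML
    over [0, 1] unless fixed via ``lambda_``.  The model F statistic
    compares against the intercept-only PGLS under the same fitted error
    structure.
    """
    ynorm = {normalize_label(str(k)) for k in y.index}
    xnorm = {normalize_label(str(k)) for k in X.index}
    tipnorm = {normalize_label(t): t for t in tree.tip_labels}
    common_norm = [t for t in tipnorm if t in ynorm and t in xnorm]
    p = X.shape[1]
    if len(common_norm) < p + 2:
        raise ValueError(
            f"only {len(common_norm)} species shared among tree, trait and "
            f"covariates; need at least {p + 2}"
        )
    dropped = sorted(set(tipnorm) - set(common_norm))
    if dropped:
        logger.info("pruning %d species without trait/covariate data: %s", len(dropped), dropped)
        sub = tree.prune_to([tipnorm[t] for t in common_norm])
    else:
        sub = tree

    sub_norm = {normalize_label(t) for t in sub.tip_labels}
    y_sub = y[[k for k in y.index if normalize_label(str(k)) in sub_norm]]
    X_sub = X.loc[[k for k in X.index if normalize_label(str(k)) in sub_norm]]
    yv = align_trait(sub, y_sub)
    Xs = align_covariates(sub, X_sub)
    n = len(yv)
    _check_design(Xs, n)
    M = np.column_stack([np.ones(n), Xs.to_numpy(dtype=float)])
    names = ["(Intercept)"] + [str(c) for c in Xs.columns]
    C0 = sub.vcv()

    if lambda_ is None:
        def neg_ll(lam):
            return -_pgls_profile_loglik(lam[0], yv, M, C0)[0]

        best = None
        for x0 in (0.25, 0.5, 0.75):
            res = optimize.minimize(
                neg_ll, x0=[x0], method="L-BFGS-B", bounds=[(0.0, 1.0)],
                options={"ftol": 1e-12, "gtol": 1e-10, "eps": 1e-7},
            )
            cand = (float(-res.fun), float(res.x[0]))
            if best is None or cand > best:
                best = cand
        for lam in (0.0, 1.0):
            ll, _ = _pgls_profile_loglik(lam, yv, M, C0)
            if (ll, lam) > best:
                best = (ll, lam)
        lam_hat = best[1]
    else:
        if not 0.0 <= lambda_ <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        lam_hat = float(lambda_)

    ll, L = _pgls_profile_loglik(lam_hat, yv, M, C0)
    if L is None:
        raise np.linalg.LinAlgError("transformed covariance is not positive definite")
    return _fit_tables(names, yv, M, L, lam_hat, loglik=ll)
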