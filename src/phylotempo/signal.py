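"""Phylogenetic signal and tempo statistics for a continuous trait.

Implements maximum-likelihood estimation of Pagel's lambda, kappa and delta
under the Brownian-motion (BM) model, with likelihood-ratio tests against the
boundary values 0 and 1, plus three permutation-based statistics:
Blomberg's K, Abouheif's Cmean and Moran's I.

Under BM the tip values are jointly Gaussian,

    y ~ N(mu * 1, sigma2 * C),

where C is the tree's variance-covariance matrix (shared root-to-MRCA path
lengths).  lambda scales the off-diagonal of C, kappa exponentiates branch
lengths, delta exponentiates node depths; each parameter is profiled over
sigma2 and mu analytically and optimized by bounded 1-D search.

Permutation tests shuffle trait values across tips, which destroys any
association between trait similarity and relatedness while preserving the
trait distribution; p-values use the (r + 1) / (n_perm + 1) convention and
so can never be exactly zero (with 999 permutations the floor is 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_solve

from .phylo import (
    PhyloCovariance,
    Phylogeny,
    transform_delta,
    transform_lambda,
)
from .tables import align_trait

__all__ = [
    "BMFit",
    "SignalEstimate",
    "PermutationTest",
    "ZeroVarianceError",
    "bm_loglik",
    "fit_pagel",
    "blomberg_k",
    "abouheif_cmean",
    "abouheif_weights",
    "morans_i",
    "PAGEL_BOUNDS",
]


class ZeroVarianceError(ValueError):
    """The trait is constant across tips; no signal statistic is defined."""


@dataclass(frozen=True)
class BMFit:
    """ML fit of the single-rate Brownian model for a fixed covariance."""

    mu_hat: float
    sigma2_hat: float
    loglik: float


@dataclass(frozen=True)
class SignalEstimate:
    """One Pagel parameter with its boundary likelihood-ratio tests."""

    statistic: str  # "lambda" | "kappa" | "delta"
    estimate: float
    loglik_at_estimate: float
    p_vs_zero: float
    p_vs_one: float
    optimizer_converged: bool


@dataclass(frozen=True)
class PermutationTest:
    """A permutation-based signal statistic and its one-sided p-value."""

    statistic: str  # "blomberg_k" | "abouheif_cmean" | "morans_i"
    observed: float
    n_perm: int
    p_value: float


# parameter bounds for the three Pagel transformations; delta's lower bound
# is strictly positive (delta -> 0 collapses all positive depths to 1)
PAGEL_BOUNDS: dict[str, tuple[float, float]] = {
    "lambda": (0.0, 1.0),
    "kappa": (0.0, 3.0),
    "delta": (1e-6, 3.0),
}


def _check_trait(y: np.ndarray, min_n: int = 2) -> None:
    y = np.asarray(y, dtype=float)
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} tips with trait values, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    if np.ptp(y) == 0:
        raise ZeroVarianceError("trait is constant across tips (zero variance)")


def _coerce_trait(tree: Phylogeny, y) -> np.ndarray:
    if isinstance(y, np.ndarray):
        if y.shape != (tree.n_tips,):
            raise ValueError("trait array length must equal the number of tips")
        return np.asarray(y, dtype=float)
    return align_trait(tree, y)


def bm_loglik(C: PhyloCovariance, y) -> BMFit:
    """ML estimates of the BM mean and rate, and the profile log-likelihood.

    mu_hat is the GLS (phylogenetic) mean (1' C^-1 1)^-1 1' C^-1 y,
    sigma2_hat the ML rate (y - mu 1)' C^-1 (y - mu 1) / n, and the
    log-likelihood the multivariate-normal density at (mu_hat, sigma2_hat C).
    """
    if isinstance(y, np.ndarray):
        yv = np.asarray(y, dtype=float)
        if yv.shape != (C.n,):
            raise ValueError("trait array length must match covariance size")
    else:
        lookup = dict(y.items()) if hasattr(y, "items") else dict(y)
        missing = [lab for lab in C.labels if lab not in lookup]
        if missing:
            raise ValueError(f"trait values missing for: {missing}")
        yv = np.array([float(lookup[lab]) for lab in C.labels])
    _check_trait(yv)
    n = C.n
    L = C.cholesky()
    factor = (L, True)
    ones = np.ones(n)
    Ci1 = cho_solve(factor, ones)
    Ciy = cho_solve(factor, yv)
    s1 = float(ones @ Ci1)
    mu = float(ones @ Ciy) / s1
    r = yv - mu
    q = float(r @ cho_solve(factor, r))
    sigma2 = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        raise ZeroVarianceError("zero residual variance under the BM model")
    loglik = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return BMFit(mu_hat=mu, sigma2_hat=sigma2, loglik=float(loglik))


def _pagel_loglik_fn(tree: Phylogeny, y: np.ndarray, which: str):
    """Profile log-likelihood of one Pagel parameter (others fixed at 1)."""
    if which == "kappa":
        def fn(p: float) -> float:
            try:
                return bm_loglik(tree.vcv(kappa=float(p)), y).loglik
            except (np.linalg.LinAlgError, ValueError):
                return -np.inf
        return fn
    C0 = tree.vcv()
    transform = transform_lambda if which == "lambda" else transform_delta

    def fn(p: float) -> float:
        try:
            return bm_loglik(transform(C0, float(p)), y).loglik
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf

    return fn


def fit_pagel(tree: Phylogeny, y, which: str) -> SignalEstimate:
    """ML estimate of Pagel's lambda, kappa or delta with boundary LR tests.

    The parameter is optimized by bounded scalar search (tolerance 1e-6)
    from three interior starts, keeping the best by likelihood (ties broken
    toward the smaller parameter).  ``p_vs_zero`` and ``p_vs_one`` are
    likelihood-ratio tests of the estimate against the parameter values 0
    (delta: its smallest admissible value) and 1, referred to chi-square
    with 1 df; a test against a bound the estimate already sits on is
    reported as p = 1.
    """
    if which not in PAGEL_BOUNDS:
        raise ValueError(f"unknown Pagel parameter {which!r}")
    yv = _coerce_trait(tree, y)
    if tree.n_tips < 4:
        raise ValueError("Pagel parameter fitting needs at least 4 tips")
    _check_trait(yv, min_n=4)
    lo, hi = PAGEL_BOUNDS[which]
    fn = _pagel_loglik_fn(tree, yv, which)

    candidates: list[tuple[float, float, bool]] = []  # (param, loglik, converged)
    for frac in (0.25, 0.5, 0.75):
        x0 = lo + frac * (hi - lo)
        res = optimize.minimize(
            lambda p: -fn(p[0]),
            x0=[x0],
            method="L-BFGS-B",
            bounds=[(lo, hi)],
            options={"ftol": 1e-12, "gtol": 1e-10, "eps": 1e-7},
        )
        candidates.append((float(res.x[0]), -float(res.fun), bool(res.success)))
    # bounds and the reference value 1 are always candidates: boundary
    # optima are legitimate (and common for lambda)
    for p in (lo, hi, 1.0):
        candidates.append((p, fn(p), True))

    best = max(candidates, key=lambda c: (c[1], -c[0]))
    est, ll_est, converged = best
    est = float(np.clip(est, lo, hi))

    atol = 1e-6 * (hi - lo)
    ll_lo = fn(lo)
    ll_one = fn(1.0)

    def lr_p(ll_bound: float, at_bound: bool) -> float:
        if at_bound:
            return 1.0
        lr = max(0.0, 2.0 * (ll_est - ll_bound))
        return float(stats.chi2.sf(lr, df=1))

    p_vs_zero = lr_p(ll_lo, abs(est - lo) <= atol)
    p_vs_one = lr_p(ll_one, abs(est - 1.0) <= atol)
    return SignalEstimate(
        statistic=which,
        estimate=est,
        loglik_at_estimate=float(ll_est),
        p_vs_zero=p_vs_zero,
        p_vs_one=p_vs_one,
        optimizer_converged=converged,
    )


# ---------------------------------------------------------------------------
# permutation statistics
# ---------------------------------------------------------------------------


def _permutation_matrix(y: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """(n_perm, n) matrix of independent tip-label shuffles of y."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(y, (n_perm, 1)), axis=1)


def _perm_pvalue(count: int, n_perm: int) -> float:
    return (count + 1) / (n_perm + 1)


def blomberg_k(tree: Phylogeny, y, n_perm: int = 999, seed: int = 0) -> PermutationTest:
    """Blomberg's K with a tip-shuffling permutation test.

    K compares the observed ratio of tip variance to phylogenetically
    corrected variance against its BM expectation:

        K = (MSE0 / MSE) / [(tr C - n / (1' C^-1 1)) / (n - 1)]

    with MSE0 the raw mean squared deviation from the phylogenetic mean and
    MSE the C^-1-weighted one.  K = 1 is the BM expectation, K exactly 1 on
    a star tree, K > 1 stronger-than-BM clustering.  Significance shuffles
    the trait across tips and asks how often the permuted phylogenetic MSE
    is as small as observed (small MSE = trait matches the tree).
    """
    yv = _coerce_trait(tree, y)
    _check_trait(yv, min_n=4)
    C = tree.vcv()
    n = C.n
    L = C.cholesky()
    factor = (L, True)
    ones = np.ones(n)
    Ci1 = cho_solve(factor, ones)
    s1 = float(ones @ Ci1)
    expected = (float(np.trace(C.matrix)) - n / s1) / (n - 1)

    def phylo_mse(Y: np.ndarray) -> np.ndarray:
        """Row-wise (y - mu 1)' C^-1 (y - mu 1) / (n - 1) for trait rows Y."""
        CiY = cho_solve(factor, Y.T)  # (n, m)
        mus = (ones @ CiY) / s1
        quad = np.einsum("mn,nm->m", Y, CiY) - mus**2 * s1
        return quad / (n - 1)

    mse_obs = float(phylo_mse(yv[None, :])[0])
    mu = float(ones @ cho_solve(factor, yv)) / s1
    mse0 = float((yv - mu) @ (yv - mu)) / (n - 1)
    k_obs = (mse0 / mse_obs) / expected

    perms = _permutation_matrix(yv, n_perm, seed)
    mse_perm = phylo_mse(perms)
    count = int(np.sum(mse_perm <= mse_obs))
    return PermutationTest("blomberg_k", float(k_obs), n_perm, _perm_pvalue(count, n_perm))


def abouheif_weights(tree: Phylogeny) -> tuple[tuple[str, ...], np.ndarray]:
    """Abouheif's topological proximity matrix A.

    A_ij (i != j) is the product over internal nodes on the path between
    tips i and j (through their MRCA, tips excluded) of one over that
    node's number of direct descendants; A_ii = 0.  Branch lengths play no
    role — this is a purely topological proximity.
    """
    idx = tree._get_index()
    n = len(idx.tip_labels)
    parent = idx.parent
    # number of direct children per node
    n_child = np.zeros(len(parent), dtype=np.int64)
    for i in range(1, len(parent)):
        n_child[parent[i]] += 1
    inv_dd = np.ones(len(parent))
    internal = n_child > 0
    inv_dd[internal] = 1.0 / n_child[internal]

    # ancestor chain (node indices root-ward, excluding the tip itself)
    chains: list[list[int]] = []
    for t in idx.tip_nodes:
        chain = []
        j = parent[t]
        while j != -1:
            chain.append(j)
            j = parent[j]
        chains.append(chain)

    A = np.zeros((n, n))
    for i in range(n):
        anc_i = chains[i]
        for j in range(i + 1, n):
            mrca = idx.mrca[i, j]
            prod = inv_dd[mrca]
            for node in anc_i:
                if node == mrca:
                    break
                prod *= inv_dd[node]
            for node in chains[j]:
                if node == mrca:
                    break
                prod *= inv_dd[node]
            A[i, j] = A[j, i] = prod
    return idx.tip_labels, A


def _autocorr_permutation(
    name: str, W: np.ndarray, z: np.ndarray, denom: float, n_perm: int, seed: int
) -> PermutationTest:
    """One-sided (greater) permutation test of a quadratic autocorrelation
    index z' W z / denom under tip shuffling."""
    obs = float(z @ W @ z) / denom
    perms = _permutation_matrix(z, n_perm, seed)
    stat_perm = np.einsum("mn,nm->m", perms, W @ perms.T) / denom
    count = int(np.sum(stat_perm >= obs))
    return PermutationTest(name, obs, n_perm, _perm_pvalue(count, n_perm))


def abouheif_cmean(tree: Phylogeny, y, n_perm: int = 999, seed: int = 0) -> PermutationTest:
    """Abouheif's Cmean: autocorrelation of the trait under the topological
    proximity matrix, tested by tip-label permutation.

    The proximity matrix is row-normalized and then scaled to total sum 1;
    the statistic is z' W z with z the standardized trait (mean 0, variance
    1 with divisor n).  Alternative standardizations of the proximity shift
    the constant but not the permutation p-value.
    """
    yv = _coerce_trait(tree, y)
    _check_trait(yv, min_n=4)
    _, A = abouheif_weights(tree)
    row_sums = A.sum(axis=1, keepdims=True)
    W = A / row_sums
    W = W / W.sum()
    z = (yv - yv.mean()) / yv.std()  # divisor n
    return _autocorr_permutation("abouheif_cmean", W, z, 1.0, n_perm, seed)


def morans_i(tree: Phylogeny, y, n_perm: int = 999, seed: int = 0) -> PermutationTest:
    """Moran's I with inverse patristic-distance weights, row-standardized.

    I = sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2 with
    w_ii = 0 and rows of w summing to 1.  Under the permutation null its
    expectation is -1/(n - 1); the test counts permutations with I at least
    as large as observed.
    """
    yv = _coerce_trait(tree, y)
    _check_trait(yv, min_n=2)
    labels, D = tree.patristic_matrix()
    off = ~np.eye(len(labels), dtype=bool)
    zero_pairs = np.argwhere((D == 0) & off)
    if zero_pairs.size:
        i, j = zero_pairs[0]
        raise ValueError(
            f"tips at zero patristic distance: {labels[i]!r} and {labels[j]!r}"
        )
    W = np.zeros_like(D)
    W[off] = 1.0 / D[off]
    W /= W.sum(axis=1, keepdims=True)
    z = yv - yv.mean()
    denom = float(z @ z)
    return _autocorr_permutation("morans_i", W, z, denom, n_perm, seed)
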