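"""Treewise phylogenetic signal: Blomberg's K, Pagel's λ, Moran's I and correlograms.

All statistics run on the tree's covariance structure directly, so polytomies
need no prior resolution.  Permutation p-values use (r + 1)/(B + 1) smoothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import Phylogeny, mrca_age_matrix, vcv_matrix
from .traits import aligned_values

__all__ = [
    "SignalResult",
    "Correlogram",
    "DecayFit",
    "blomberg_k",
    "pagel_lambda",
    "moran_i",
    "correlogram",
    "fit_decay",
]


@dataclass
class SignalResult:
    statistic: str
    estimate: float
    p_value: float | None
    null_expectation: float
    n: int
    details: dict = field(default_factory=dict)


def _check_trait(x: np.ndarray) -> None:
    if x.size < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; signal statistics are undefined")


# ----------------------------------------------------------------------
# Blomberg's K
# ----------------------------------------------------------------------

def _k_ratios(X: np.ndarray, cho, w: np.ndarray, sumw: float) -> np.ndarray:
    """MSE0/MSE for each column of X given a Cholesky factor of V."""
    a = (w @ X) / sumw
    Z = X - a
    mse0 = np.einsum("ij,ij->j", Z, Z)
    mse = np.einsum("ij,ij->j", Z, linalg.cho_solve(cho, Z))
    return mse0 / mse


def blomberg_k(
    tree: Phylogeny,
    traits,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg et al.'s K with a tip-shuffling permutation test.

    K is the observed MSE0/MSE ratio (GLS ancestral mean, phylogenetic
    covariance V) divided by its Brownian-motion expectation on the same tree,
    so K ≈ 1 under BM and K > 1 indicates stronger-than-BM conservatism.  The
    one-tailed p-value is the smoothed proportion of tip permutations with
    K at least as large as observed.  ``n_perm=0`` skips the test.
    """
    x = aligned_values(traits, tree)
    _check_trait(x)
    n = x.size
    V = vcv_matrix(tree)
    cho = linalg.cho_factor(V, lower=True)
    w = linalg.cho_solve(cho, np.ones(n))
    sumw = float(w.sum())
    expected = (np.trace(V) - n / sumw) / (n - 1)
    k_obs = float(_k_ratios(x[:, None], cho, w, sumw)[0] / expected)
    p = None
    if n_perm:
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99 (or 0 to skip the test)")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1).T
        k_perm = _k_ratios(perms, cho, w, sumw) / expected
        p = (np.sum(k_perm >= k_obs) + 1) / (n_perm + 1)
    return SignalResult(
        statistic="K",
        estimate=k_obs,
        p_value=p,
        null_expectation=1.0,
        n=n,
        details={"n_perm": n_perm, "bm_expected_ratio": float(expected)},
    )


# ----------------------------------------------------------------------
# Pagel's lambda
# ----------------------------------------------------------------------

def _lambda_loglik_factory(V: np.ndarray, x: np.ndarray):
    """Profile log-likelihood of λ with the GLS mean and σ² concentrated out.

    For ultrametric trees (constant diagonal) V(λ) shares eigenvectors with V,
    so each evaluation is O(n) after one eigendecomposition; otherwise a
    Cholesky factorization is done per evaluation.
    """
    n = x.size
    d = np.diag(V).copy()
    if np.allclose(d, d[0]):
        T = d[0]
        evals, Q = linalg.eigh(V)
        y = Q.T @ x
        u = Q.T @ np.ones(n)

        def loglik(lam: float) -> float:
            w = lam * (evals - T) + T
            if np.any(w <= 0):
                return -np.inf
            ahat = np.sum(u * y / w) / np.sum(u * u / w)
            r = y - ahat * u
            s2 = np.sum(r * r / w) / n
            return -0.5 * (n * (np.log(2 * np.pi * s2) + 1) + np.sum(np.log(w)))

        return loglik

    offdiag = V - np.diag(d)

    def loglik(lam: float) -> float:
        Vl = lam * offdiag + np.diag(d)
        try:
            cho = linalg.cho_factor(Vl, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        ones = np.ones(n)
        Vi1 = linalg.cho_solve(cho, ones)
        Vix = linalg.cho_solve(cho, x)
        ahat = (ones @ Vix) / (ones @ Vi1)
        r = x - ahat
        s2 = (r @ linalg.cho_solve(cho, r)) / n
        logdet = 2 * np.sum(np.log(np.diag(cho[0])))
        return -0.5 * (n * (np.log(2 * np.pi * s2) + 1) + logdet)

    return loglik


def pagel_lambda(
    tree: Phylogeny,
    traits,
    lambda_max: float = 1.0,
    tol: float = 1e-6,
) -> SignalResult:
    """Maximum-likelihood Pagel's λ with LRTs against λ = 0 and λ = 1.

    λ scales the off-diagonal phylogenetic covariance: 0 means evolution
    independent of phylogeny, 1 means a Brownian-motion pattern.  The search
    is bounded in [0, ``lambda_max``]; set ``lambda_max`` above 1 only if
    V(λ) stays positive definite on your tree.
    """
    x = aligned_values(traits, tree)
    _check_trait(x)
    V = vcv_matrix(tree)
    loglik = _lambda_loglik_factory(V, x)
    if not np.isfinite(loglik(0.0)):
        raise ValueError(
            "covariance not positive definite at λ=0; check for duplicate tips "
            "or zero tip ages"
        )
    res = optimize.minimize_scalar(
        lambda lam: -loglik(lam),
        bounds=(0.0, lambda_max),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [(float(res.x), -float(res.fun)), (0.0, loglik(0.0)), (lambda_max, loglik(lambda_max))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll0 = loglik(0.0)
    ll1 = loglik(1.0) if lambda_max >= 1.0 else -np.inf
    lrt0 = 2 * (ll_hat - ll0)
    p0 = float(stats.chi2.sf(lrt0, df=1))
    out = {
        "loglik": ll_hat,
        "lrt_vs_0": lrt0,
        "p_vs_0": p0,
        "lambda_max": lambda_max,
    }
    if np.isfinite(ll1):
        out["lrt_vs_1"] = 2 * (ll_hat - ll1)
        out["p_vs_1"] = float(stats.chi2.sf(out["lrt_vs_1"], df=1))
    return SignalResult(
        statistic="lambda",
        estimate=lam_hat,
        p_value=p0,
        null_expectation=0.0,
        n=x.size,
        details=out,
    )


# ----------------------------------------------------------------------
# Moran's I
# ----------------------------------------------------------------------

def _moran_stat(W: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Moran's I for each centred column of Z, n/S0 · z'Wz / z'z."""
    n = Z.shape[0]
    s0 = W.sum()
    num = np.einsum("ij,ij->j", Z, W @ Z)
    den = np.einsum("ij,ij->j", Z, Z)
    return (n / s0) * num / den


def moran_i(
    dist,
    traits,
    weights: str | np.ndarray = "inverse_time",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> SignalResult:
    """Moran's I on a divergence-time matrix, null expectation −1/(n−1).

    ``weights='inverse_time'`` uses w_ij = 1/d_ij (diagonal 0); alternatively
    pass an explicit symmetric weight matrix (e.g. binary class membership).
    Significance is by tip permutation, one-tailed 'greater' by default
    (positive phylogenetic autocorrelation).
    """
    if isinstance(dist, pd.DataFrame):
        D = dist.to_numpy(dtype=float)
        if isinstance(traits, (pd.Series, dict)) or hasattr(traits, "log_means"):
            series = traits.log_means if hasattr(traits, "log_means") else pd.Series(traits)
            missing = [t for t in dist.index if t not in series.index]
            if missing:
                raise ValueError(f"traits missing for tips: {missing[:10]}")
            x = series.reindex(dist.index).to_numpy(dtype=float)
        else:
            x = np.asarray(traits, dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        x = np.asarray(traits, dtype=float)
    n = x.size
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match trait length")
    _check_trait(x)
    if isinstance(weights, str):
        if weights != "inverse_time":
            raise ValueError(f"unknown weights mode {weights!r}")
        off = ~np.eye(n, dtype=bool)
        if np.any(D[off] <= 0):
            raise ValueError("zero divergence time between distinct tips; weights undefined")
        W = np.zeros_like(D)
        W[off] = 1.0 / D[off]
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    z = x - x.mean()
    i_obs = float(_moran_stat(W, z[:, None])[0])
    expected = -1.0 / (n - 1)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1).T
        Z = perms - perms.mean(axis=0)
        i_perm = _moran_stat(W, Z)
        p_ge = (np.sum(i_perm >= i_obs) + 1) / (n_perm + 1)
        p_le = (np.sum(i_perm <= i_obs) + 1) / (n_perm + 1)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_ge, p_le))
    return SignalResult(
        statistic="moran_I",
        estimate=i_obs,
        p_value=p,
        null_expectation=expected,
        n=n,
        details={"n_perm": n_perm, "alternative": alternative},
    )


# ----------------------------------------------------------------------
# correlogram over divergence-time classes
# ----------------------------------------------------------------------

@dataclass
class Correlogram:
    """Per-divergence-time-class Moran's I (binary class-membership weights)."""

    bins: pd.DataFrame  # lo, hi, midpoint, moran_i, n_pairs, p_value, significant
    n: int
    root_age: float
    null_expectation: float
    alpha: float = 0.05


def _auto_edges(
    d: np.ndarray, n_classes: int, root_age: float, target_min_pairs: int
) -> np.ndarray:
    """Equal-width divergence-time classes, merged right-to-left until every
    class holds at least ``target_min_pairs`` pairs.

    Equal-width bins keep resolution at recent divergences, where similarity
    decays fastest; pair-count quantiles would collapse there because most
    pairs trace back to a handful of deep ancestors.
    """
    edges = list(np.linspace(0.0, root_age, n_classes + 1))
    counts = np.histogram(d, bins=edges)[0]
    # classes are (lo, hi]; put d == 0 ties (none for distinct tips) aside
    i = 0
    while i < len(counts):
        if counts[i] >= target_min_pairs:
            i += 1
            continue
        if i + 1 < len(counts):  # merge into the next class
            counts[i + 1] += counts[i]
            counts = np.delete(counts, i)
            del edges[i + 1]
        elif i > 0:  # last class short: merge into previous
            counts[i - 1] += counts[i]
            counts = np.delete(counts, i)
            del edges[i]
            i -= 1
        else:
            break
    edges = np.asarray(edges)
    if len(edges) - 1 < 2:
        raise ValueError("could not form >= 2 divergence-time classes")
    return edges


def correlogram(
    tree: Phylogeny,
    traits,
    class_edges: Sequence[float] | None = None,
    n_classes: int | None = None,
    target_min_pairs: int = 100,
    n_perm: int = 199,
    seed: int | None = None,
    alpha: float = 0.05,
) -> Correlogram:
    """Moran's I within successive divergence-time classes.

    Classes partition (0, root age]; each unordered tip pair falls in exactly
    one class (d in (lo, hi]).  If no edges are given, equal-width classes are
    built and short ones merged so that every class holds at least
    ``target_min_pairs`` pairs.  Per-class significance is a two-sided
    permutation test at level ``alpha`` (``n_perm=0`` skips it).
    """
    x = aligned_values(traits, tree)
    _check_trait(x)
    n = x.size
    M = mrca_age_matrix(tree)
    root_age = tree.root_age
    iu = np.triu_indices(n, k=1)
    d = M[iu]
    if class_edges is None:
        if n_classes is None:
            n_classes = int(np.clip(d.size // max(target_min_pairs, 1), 2, 12))
        edges = _auto_edges(d, n_classes, root_age, target_min_pairs)
    else:
        edges = np.asarray(class_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 3:
            raise ValueError("need at least 2 classes (3 edge values)")
    # pair -> class, classes are (lo, hi]
    cls = np.searchsorted(edges, d, side="left") - 1
    cls = np.clip(cls, 0, len(edges) - 2)
    n_cls = len(edges) - 1
    counts = np.bincount(cls, minlength=n_cls)
    if np.any(counts < 2):
        raise ValueError(
            f"classes with < 2 pairs (counts {counts.tolist()}); use coarser classes"
        )
    z = x - x.mean()
    zz = float(z @ z)
    prod = z[iu[0]] * z[iu[1]]
    num = np.bincount(cls, weights=prod, minlength=n_cls)
    i_vals = (n / counts) * num / zz  # S0 = 2*count, numerator doubled: factors cancel
    p_vals = np.full(n_cls, np.nan)
    if n_perm:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1).T
        Z = perms - perms.mean(axis=0)
        P = Z[iu[0]] * Z[iu[1]]  # (n_pairs, B)
        zz_perm = np.einsum("ij,ij->j", Z, Z)
        for c in range(n_cls):
            num_c = P[cls == c].sum(axis=0)
            i_perm = (n / counts[c]) * num_c / zz_perm
            p_ge = (np.sum(i_perm >= i_vals[c]) + 1) / (n_perm + 1)
            p_le = (np.sum(i_perm <= i_vals[c]) + 1) / (n_perm + 1)
            p_vals[c] = min(1.0, 2 * min(p_ge, p_le))
    bins = pd.DataFrame(
        {
            "lo": edges[:-1],
            "hi": edges[1:],
            "midpoint": 0.5 * (edges[:-1] + edges[1:]),
            "moran_i": i_vals,
            "n_pairs": counts,
            "p_value": p_vals,
            "significant": p_vals <= alpha if n_perm else pd.NA,
        }
    )
    return Correlogram(
        bins=bins, n=n, root_age=root_age, null_expectation=-1.0 / (n - 1), alpha=alpha
    )


# ----------------------------------------------------------------------
# decay-shape comparison: linear vs exponential
# ----------------------------------------------------------------------

@dataclass
class DecayFit:
    """Linear vs exponential fits to I(t) at correlogram class midpoints.

    A linear decline in similarity with divergence time is the Brownian-motion
    expectation; an exponential decline points to drift plus stabilizing
    selection (an Ornstein-Uhlenbeck pattern).
    """

    linear_params: tuple[float, float]  # intercept, slope
    exponential_params: tuple[float, float, float] | None  # amplitude, rate, offset
    rss_linear: float
    rss_exponential: float | None
    loglik_linear: float
    loglik_exponential: float | None
    statistic: float | None  # 2*(ll_exp - ll_lin)
    df: int
    preferred: str
    exponential_converged: bool


def _gauss_ll(rss: float, m: int) -> float:
    s2 = max(rss / m, 1e-300)
    return -0.5 * m * (np.log(2 * np.pi * s2) + 1)


def fit_decay(corr: Correlogram, alpha: float = 0.05) -> DecayFit:
    """Least-squares linear and exponential fits to the correlogram decay.

    The exponential model I(t) = a·exp(−b·t) + c carries one parameter more
    than the line, so it is preferred only when 2ΔlogLik exceeds the χ²(1)
    threshold at level ``alpha``.  Non-convergence falls back to linear.
    """
    t = corr.bins["midpoint"].to_numpy()
    y = corr.bins["moran_i"].to_numpy()
    m = t.size
    if m < 4:
        raise ValueError("need >= 4 classes to compare decay shapes")
    slope, intercept = np.polyfit(t, y, 1)
    rss_lin = float(np.sum((y - (intercept + slope * t)) ** 2))
    ll_lin = _gauss_ll(rss_lin, m)

    def expdecay(tt, a, b, c):
        return a * np.exp(-b * tt) + c

    converged = True
    try:
        span = max(t[-1] - t[0], 1e-9)
        p0 = (max(y[0] - y[-1], 1e-3), 2.0 / span, y[-1])
        popt, _ = optimize.curve_fit(
            expdecay,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        rss_exp = float(np.sum((y - expdecay(t, *popt)) ** 2))
        ll_exp = _gauss_ll(rss_exp, m)
    except Exception:
        converged = False
        popt, rss_exp, ll_exp = None, None, None

    if not converged:
        return DecayFit(
            linear_params=(float(intercept), float(slope)),
            exponential_params=None,
            rss_linear=rss_lin,
            rss_exponential=None,
            loglik_linear=ll_lin,
            loglik_exponential=None,
            statistic=None,
            df=1,
            preferred="linear",
            exponential_converged=False,
        )
    stat = 2 * (ll_exp - ll_lin)
    threshold = stats.chi2.ppf(1 - alpha, df=1)
    preferred = "exponential" if stat > threshold else "linear"
    return DecayFit(
        linear_params=(float(intercept), float(slope)),
        exponential_params=tuple(float(v) for v in popt),
        rss_linear=rss_lin,
        rss_exponential=rss_exp,
        loglik_linear=ll_lin,
        loglik_exponential=ll_exp,
        statistic=float(stat),
        df=1,
        preferred=preferred,
        exponential_converged=True,
    )
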