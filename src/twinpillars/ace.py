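"""Univariate ACE decomposition for twin traits by maximum likelihood.

The classical twin design contrasts monozygotic (MZ) and dizygotic (DZ)
same-sex pairs to split trait variance into additive-genetic (A), shared
environmental (C), and non-shared environmental (E) components.  On the
latent path scale a twin's trait is

    T_j = mu + a A_j + c C + e E_j,

with corr(A_1, A_2) = 1 for MZ and 0.5 for DZ, C fully shared, and E
independent; the implied cross-twin correlation is ``a^2 rbar + c^2``
(standardized).  Continuous traits use the bivariate-normal likelihood;
ordinal traits use a liability-threshold model in which observed
categories are threshold cuts of a standard-normal latent liability and
pair contributions are bivariate-normal rectangle probabilities.

Missing data are handled by full-information maximum likelihood (FIML):
a pair with one observed member contributes the marginal (univariate)
density of the observed member, so nothing is listwise deleted.

Variance components are optimized as unconstrained path coefficients and
squared, which enforces non-negative shares; estimates on the boundary
(a share pinned at 0) are flagged because their standard errors from the
numerical Hessian are unreliable there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from ._bvn import bvn_rect
from ._data import pair_array, to_pairs

__all__ = [
    "ACEEstimate",
    "pair_loglik_continuous",
    "fit_ace_continuous",
    "pair_loglik_ordinal",
    "fit_ace_ordinal",
]

ZYGOSITY_A_CORR = {"MZ": 1.0, "DZ": 0.5}
_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e10


@dataclass
class ACEEstimate:
    """Standardized ACE decomposition of one trait."""

    a2: float
    c2: float
    e2: float
    total_variance: float
    mean: float | None
    thresholds: np.ndarray | None
    minus2ll: float
    se: dict[str, float]
    n_pairs: dict[str, int]
    converged: bool
    boundary: bool

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2

    def to_dict(self) -> dict:
        d = {
            "a2": self.a2, "c2": self.c2, "e2": self.e2,
            "total_variance": self.total_variance,
            "mean": self.mean,
            "thresholds": None if self.thresholds is None else list(self.thresholds),
            "minus2ll": self.minus2ll, "se": self.se, "n_pairs": self.n_pairs,
            "converged": self.converged, "boundary": self.boundary,
            "r_mz": self.r_mz, "r_dz": self.r_dz,
        }
        return d


# ---------------------------------------------------------------------------
# continuous traits

def pair_loglik_continuous(pair_values, zygosity, mu, total_var, a2, c2):
    """Per-pair FIML log-likelihood of a continuous trait.

    ``pair_values`` is (n, 2) with NaN for unobserved members; pairs with
    neither member observed contribute 0.  The implied pair covariance is
    ``total_var * [[1, r], [r, 1]]`` with ``r = a2 rbar + c2``.  A
    non-positive-definite implied covariance yields a large finite
    penalty rather than an exception.
    """
    x = np.asarray(pair_values, float)
    rbar = ZYGOSITY_A_CORR[zygosity]
    r = a2 * rbar + c2
    out = np.zeros(x.shape[0])
    obs = ~np.isnan(x)
    if total_var <= 0 or abs(r) >= 1 - 1e-12:
        n_any = int(obs.any(axis=1).sum())
        return np.where(obs.any(axis=1), -_PENALTY, 0.0) if n_any else out

    both = obs.all(axis=1)
    one = obs.any(axis=1) & ~both
    if both.any():
        d = x[both] - mu
        det = total_var**2 * (1 - r**2)
        quad = (d[:, 0] ** 2 + d[:, 1] ** 2 - 2 * r * d[:, 0] * d[:, 1]) / (
            total_var * (1 - r**2)
        )
        out[both] = -0.5 * (2 * _LOG2PI + np.log(det) + quad)
    if one.any():
        v = np.where(np.isnan(x[one, 0]), x[one, 1], x[one, 0])
        out[one] = -0.5 * (_LOG2PI + np.log(total_var) + (v - mu) ** 2 / total_var)
    return out


def _continuous_suffstats(values_by_zyg):
    """Sufficient statistics (complete pairs + singletons) per zygosity."""
    stats = {}
    for zyg, x in values_by_zyg.items():
        obs = ~np.isnan(x)
        both = x[obs.all(axis=1)]
        lone_mask = obs.any(axis=1) & ~obs.all(axis=1)
        lone = np.where(np.isnan(x[lone_mask, 0]), x[lone_mask, 1], x[lone_mask, 0])
        stats[zyg] = {
            "n2": both.shape[0],
            "s2": both.sum(axis=0) if both.size else np.zeros(2),
            "S2": both.T @ both if both.size else np.zeros((2, 2)),
            "cross": float((both[:, 0] * both[:, 1]).sum()) if both.size else 0.0,
            "n1": lone.shape[0],
            "s1": float(lone.sum()),
            "ss1": float((lone**2).sum()),
        }
    return stats


def _m2ll_continuous(theta, stats):
    mu, pa, pc, pe = theta
    a2p, c2p, e2p = pa**2, pc**2, pe**2
    total = a2p + c2p + e2p
    if total <= 1e-10 or e2p / total < 1e-10:
        return _PENALTY
    m2 = 0.0
    for zyg, st in stats.items():
        rbar = ZYGOSITY_A_CORR[zyg]
        cov = a2p * rbar + c2p
        det = total**2 - cov**2
        if det <= 0:
            return _PENALTY
        if st["n2"]:
            # sum (x - mu)' Sigma^{-1} (x - mu) via scatter stats
            sxx = st["S2"][0, 0] + st["S2"][1, 1] - 2 * mu * (st["s2"][0] + st["s2"][1]) \
                + 2 * st["n2"] * mu**2
            sxy = st["cross"] - mu * (st["s2"][0] + st["s2"][1]) + st["n2"] * mu**2
            quad = (total * sxx - 2 * cov * sxy) / det
            m2 += st["n2"] * (2 * _LOG2PI + np.log(det)) + quad
        if st["n1"]:
            quad1 = (st["ss1"] - 2 * mu * st["s1"] + st["n1"] * mu**2) / total
            m2 += st["n1"] * (_LOG2PI + np.log(total)) + quad1
    return m2


def _numerical_hessian(f, theta, step=1e-4):
    theta = np.asarray(theta, float)
    k = len(theta)
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _shares_from_paths(theta):
    _, pa, pc, pe = theta
    tot = pa**2 + pc**2 + pe**2
    return np.array([pa**2 / tot, pc**2 / tot, pe**2 / tot, tot, theta[0]])


def _delta_se(theta, vcov, transform):
    k = len(theta)
    base = transform(theta)
    J = np.empty((len(base), k))
    for i in range(k):
        h = 1e-5 * max(1.0, abs(theta[i]))
        up = np.array(theta, float); up[i] += h
        dn = np.array(theta, float); dn[i] -= h
        J[:, i] = (transform(up) - transform(dn)) / (2 * h)
    cov = J @ vcov @ J.T
    var = np.clip(np.diag(cov), 0, None)
    return np.sqrt(var)


def fit_ace_continuous(df: pd.DataFrame | dict, trait: str | None = None) -> ACEEstimate:
    """Fit the continuous ACE model by FIML.

    Accepts either a coded long-format frame plus a trait column name, or
    a ready dict ``{"MZ": (n, 2) array, "DZ": (n, 2) array}``.
    """
    if isinstance(df, dict):
        values = {z: np.asarray(v, float) for z, v in df.items()}
    else:
        pairs = to_pairs(df, [trait])
        values = {
            z: pair_array(pairs[pairs["zygosity"] == z], trait)
            for z in ("MZ", "DZ")
        }
    values = {z: v[~np.isnan(v).all(axis=1)] for z, v in values.items()}
    n_pairs = {z: int(v.shape[0]) for z, v in values.items()}
    for z, n in n_pairs.items():
        if n < 2:
            raise ValueError(f"need at least 2 informative {z} pairs")
    stats = _continuous_suffstats(values)

    allv = np.concatenate([v[~np.isnan(v)] for v in values.values()])
    mu0, var0 = float(allv.mean()), float(allv.var())
    r_hat = {}
    for z, v in values.items():
        both = v[~np.isnan(v).any(axis=1)]
        if both.shape[0] > 2:
            sym = np.concatenate([both, both[:, ::-1]])
            r_hat[z] = float(np.corrcoef(sym[:, 0], sym[:, 1])[0, 1])
        else:
            r_hat[z] = 0.3
    a2_0 = float(np.clip(2 * (r_hat["MZ"] - r_hat["DZ"]), 0.05, 0.9))
    c2_0 = float(np.clip(2 * r_hat["DZ"] - r_hat["MZ"], 0.05, 0.9))
    e2_0 = max(1 - a2_0 - c2_0, 0.05)
    scale = np.sqrt(var0 / (a2_0 + c2_0 + e2_0))
    theta0 = np.array(
        [mu0, np.sqrt(a2_0) * scale, np.sqrt(c2_0) * scale, np.sqrt(e2_0) * scale]
    )

    res = optimize.minimize(
        _m2ll_continuous, theta0, args=(stats,), method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    shares = _shares_from_paths(theta)
    boundary = bool(min(shares[0], shares[1], shares[2]) < 1e-4)

    H = _numerical_hessian(lambda t: _m2ll_continuous(t, stats), theta)
    vcov = 2.0 * np.linalg.pinv(H)
    se_vec = _delta_se(theta, vcov, _shares_from_paths)
    se = dict(zip(["a2", "c2", "e2", "total_variance", "mean"], se_vec))

    return ACEEstimate(
        a2=float(shares[0]), c2=float(shares[1]), e2=float(shares[2]),
        total_variance=float(shares[3]), mean=float(theta[0]), thresholds=None,
        minus2ll=float(res.fun), se=se, n_pairs=n_pairs,
        converged=bool(res.success), boundary=boundary,
    )


# ---------------------------------------------------------------------------
# ordinal traits (liability-threshold model)

def _interval(cats, thresholds):
    """Lower/upper liability limits per observation for integer categories."""
    t = np.concatenate([[-np.inf], thresholds, [np.inf]])
    cats = np.asarray(cats)
    lo = np.where(np.isnan(cats), -np.inf, t[np.nan_to_num(cats, nan=0).astype(int)])
    hi = np.where(np.isnan(cats), np.inf, t[np.nan_to_num(cats, nan=0).astype(int) + 1])
    return lo, hi


def pair_loglik_ordinal(pair_categories, zygosity, thresholds, a2, c2):
    """Per-pair log-likelihood under the liability-threshold ACE model.

    Categories are integers ``0..K-1`` (NaN = missing) cut from a
    standard-normal liability at the ``K-1`` ordered ``thresholds``; the
    latent pair correlation is ``a2 rbar + c2``.  Pair contributions are
    bivariate-normal rectangle probabilities; singletons contribute
    univariate interval probabilities.
    """
    thresholds = np.asarray(thresholds, float)
    if thresholds.ndim != 1 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    x = np.asarray(pair_categories, float)
    rbar = ZYGOSITY_A_CORR[zygosity]
    r = a2 * rbar + c2
    lo1, hi1 = _interval(x[:, 0], thresholds)
    lo2, hi2 = _interval(x[:, 1], thresholds)
    obs = ~np.isnan(x)
    out = np.zeros(x.shape[0])

    both = obs.all(axis=1)
    if both.any():
        p = bvn_rect(lo1[both], hi1[both], lo2[both], hi2[both], r)
        out[both] = np.log(np.clip(p, 1e-300, None))
    one = obs.any(axis=1) & ~both
    if one.any():
        lo = np.where(obs[one, 0], lo1[one], lo2[one])
        hi = np.where(obs[one, 0], hi1[one], hi2[one])
        p = norm.cdf(hi) - norm.cdf(lo)
        out[one] = np.log(np.clip(p, 1e-300, None))
    return out


def _ordinal_crosstab(values_by_zyg, n_categories):
    """Symmetrized pair cross-tabs + singleton margins per zygosity."""
    tabs = {}
    for zyg, x in values_by_zyg.items():
        obs = ~np.isnan(x)
        both = x[obs.all(axis=1)].astype(int)
        tab = np.zeros((n_categories, n_categories))
        for k1, k2 in both:
            tab[k1, k2] += 1
        lone_mask = obs.any(axis=1) & ~obs.all(axis=1)
        lone = np.where(np.isnan(x[lone_mask, 0]), x[lone_mask, 1], x[lone_mask, 0])
        margin = np.bincount(lone.astype(int), minlength=n_categories).astype(float)
        tabs[zyg] = (tab, margin)
    return tabs


def _m2ll_ordinal(theta, tabs, n_categories):
    K = n_categories
    t = np.empty(K - 1)
    t[0] = theta[0]
    if K > 2:
        t[1:] = theta[0] + np.cumsum(np.exp(theta[1 : K - 1]))
    qa, qc, qe = theta[K - 1 :]
    tot = qa**2 + qc**2 + qe**2
    if tot <= 1e-12 or qe**2 / tot < 1e-8:
        return _PENALTY
    a2, c2 = qa**2 / tot, qc**2 / tot
    edges = np.concatenate([[-np.inf], t, [np.inf]])
    lo, hi = edges[:-1], edges[1:]
    m2 = 0.0
    for zyg, (tab, margin) in tabs.items():
        r = a2 * ZYGOSITY_A_CORR[zyg] + c2
        P = bvn_rect(lo[:, None], hi[:, None], lo[None, :], hi[None, :], r)
        logP = np.log(np.clip(P, 1e-300, None))
        m2 -= 2.0 * float((tab * logP).sum())
        if margin.any():
            p1 = np.clip(norm.cdf(hi) - norm.cdf(lo), 1e-300, None)
            m2 -= 2.0 * float((margin * np.log(p1)).sum())
    return m2


def fit_ace_ordinal(
    df: pd.DataFrame | dict, trait: str | None = None, n_categories: int | None = None
) -> ACEEstimate:
    """Liability-threshold ACE fit for an ordinal trait (integer categories)."""
    if isinstance(df, dict):
        values = {z: np.asarray(v, float) for z, v in df.items()}
    else:
        pairs = to_pairs(df, [trait])
        values = {
            z: pair_array(pairs[pairs["zygosity"] == z], trait)
            for z in ("MZ", "DZ")
        }
    values = {z: v[~np.isnan(v).all(axis=1)] for z, v in values.items()}
    n_pairs = {z: int(v.shape[0]) for z, v in values.items()}
    allv = np.concatenate([v[~np.isnan(v)] for v in values.values()])
    if n_categories is None:
        n_categories = int(np.nanmax(allv)) + 1
    K = n_categories
    tabs = _ordinal_crosstab(values, K)

    freq = np.bincount(allv.astype(int), minlength=K) / len(allv)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    t0 = norm.ppf(cum)
    theta0 = np.concatenate(
        [[t0[0]], np.log(np.clip(np.diff(t0), 1e-3, None)),
         [np.sqrt(0.4), np.sqrt(0.2), np.sqrt(0.4)]]
    )
    res = optimize.minimize(
        _m2ll_ordinal, theta0, args=(tabs, K), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    theta = res.x
    t = np.empty(K - 1)
    t[0] = theta[0]
    if K > 2:
        t[1:] = theta[0] + np.cumsum(np.exp(theta[1 : K - 1]))
    qa, qc, qe = theta[K - 1 :]
    tot = qa**2 + qc**2 + qe**2
    a2, c2, e2 = qa**2 / tot, qc**2 / tot, qe**2 / tot
    boundary = bool(min(a2, c2, e2) < 1e-4)

    H = _numerical_hessian(lambda th: _m2ll_ordinal(th, tabs, K), theta, step=1e-3)
    vcov = 2.0 * np.linalg.pinv(H)

    def _trans(th):
        q = th[K - 1 :]
        s = (q**2).sum()
        return np.array([q[0] ** 2 / s, q[1] ** 2 / s, q[2] ** 2 / s])

    se_vec = _delta_se(theta, vcov, _trans)
    se = dict(zip(["a2", "c2", "e2"], se_vec))
    return ACEEstimate(
        a2=float(a2), c2=float(c2), e2=float(e2), total_variance=1.0,
        mean=None, thresholds=t, minus2ll=float(res.fun), se=se,
        n_pairs=n_pairs, converged=bool(res.success), boundary=boundary,
    )
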