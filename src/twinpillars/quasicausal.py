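"""Bivariate quasi-causal co-twin models for pillar count vs. outcome.

The co-twin control design asks whether a phenotypic association between
the number of lifestyle pillars met (X) and an outcome (Y, log-BMI or
square-root PHQ-2) survives control for *between-family* confounding.
Structural equations for twin ``j`` of pair ``i``::

    X_ij = mu_x + a_x A_xij + c_x C_xi + e_x E_xij
    Y_ij = mu_y + b_p (X_ij - mu_x) + b_a A_xij + b_c C_xi
           + a_u A_uij + c_u C_ui + e_u E_uij + Z_ij' beta

with additive-genetic latents correlated 1 (MZ) / 0.5 (DZ) across twins
and shared-environment latents fully shared.  ``b_p`` is the within-
person (phenotypic / quasi-causal) path; ``b_a`` and ``b_c`` route the
predictor's own familial latents into the outcome and so absorb
between-family confounding.

Model sequence (per outcome and pillar subset):

* **Model 1** -- phenotypic: ``b_a = b_c = 0``, ``b_p`` free per sex group.
* **Model 2** -- quasi-causal: ``b_a = b_c = b_f`` estimated (the two
  confound paths are poorly separated in practice, so their equality is
  imposed a priori); ``b_p`` free per group.
* **Model 3** -- Model 2 with ``b_p`` additionally equated across the
  male and female groups (testable by a Wald test on the Model 2 fits).

Two predictor treatments are available: ``observed_count`` fits the
integer count as a continuous variable (fast, slopes per count unit),
while ``liability_ordinal`` (the default) treats the count as threshold
cuts of a standard-normal latent liability and integrates the ordinal
pair over bivariate-normal rectangles conditionally on the observed
outcomes.  Estimation is FIML over partially observed (X1, Y1, X2, Y2)
vectors; covariates enter the outcome mean only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from ._bvn import bvn_rect
from ._data import pair_array, to_pairs
from .pillars import PILLAR_ORDER

__all__ = [
    "PRESETS",
    "QuasiCausalSpec",
    "QuasiCausalFit",
    "StructuralParams",
    "implied_pair_moments",
    "fit_model",
    "wald_test",
    "wald_equal",
    "percent_change_per_pillar",
    "liability_predictor_loglik",
]

ZYGOSITY_A_CORR = {"MZ": 1.0, "DZ": 0.5}
_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e10

#: named pillar subsets: all five, and the top-2 subsets identified per outcome
PRESETS = {
    "all": PILLAR_ORDER,
    "bmi_top2": ("mvpa", "sedentary"),
    "phq_top2": ("sedentary", "nonsmoking"),
}


@dataclass(frozen=True)
class QuasiCausalSpec:
    """What to fit: outcome, pillar subset, model level, and options."""

    outcome: str = "log_bmi"
    pillars: tuple[str, ...] | str = "all"
    model_level: int = 2
    predictor_mode: str = "liability_ordinal"  # or "observed_count"
    covariates: tuple[str, ...] = ()
    groups: tuple[str, ...] | None = ("female", "male")  # None = pooled

    def pillar_subset(self) -> tuple[str, ...]:
        subset = PRESETS[self.pillars] if isinstance(self.pillars, str) else self.pillars
        if not subset:
            raise ValueError("pillar subset must be non-empty")
        return tuple(subset)

    def __post_init__(self):
        if self.model_level not in (1, 2, 3):
            raise ValueError("model_level must be 1, 2 or 3")
        if self.predictor_mode not in ("observed_count", "liability_ordinal"):
            raise ValueError("unknown predictor_mode")
        if self.model_level == 3 and (self.groups is None or len(self.groups) < 2):
            raise ValueError("Model 3 requires both sex groups")


@dataclass
class StructuralParams:
    """Structural paths for one group (continuous-predictor scale)."""

    mu_x: float
    p_xa: float
    p_xc: float
    p_xe: float
    b_p: float
    b_a: float
    b_c: float
    mu_y: float
    p_ua: float
    p_uc: float
    p_ue: float
    betas: np.ndarray = field(default_factory=lambda: np.zeros(0))


def implied_pair_moments(params: StructuralParams, zygosity: str):
    """Implied mean (4,) and covariance (4, 4) of (X1, Y1, X2, Y2).

    Exact moment algebra on the structural equations; covariate terms are
    row-specific mean shifts and are not included here.
    """
    rbar = ZYGOSITY_A_CORR[zygosity]
    pa, pc, pe = params.p_xa, params.p_xc, params.p_xe
    bp, ba, bc = params.b_p, params.b_a, params.b_c
    qa, qc, qe = params.p_ua, params.p_uc, params.p_ue

    var_x = pa**2 + pc**2 + pe**2
    cov_x = pa**2 * rbar + pc**2
    cxy_w = bp * var_x + ba * pa + bc * pc
    cxy_x = bp * cov_x + ba * rbar * pa + bc * pc
    var_y = (
        bp**2 * var_x + 2 * bp * (ba * pa + bc * pc)
        + ba**2 + bc**2 + qa**2 + qc**2 + qe**2
    )
    cov_yy = (
        bp**2 * cov_x + 2 * bp * (ba * rbar * pa + bc * pc)
        + ba**2 * rbar + bc**2 + qa**2 * rbar + qc**2
    )
    mu = np.array([params.mu_x, params.mu_y, params.mu_x, params.mu_y])
    sigma = np.array(
        [
            [var_x, cxy_w, cov_x, cxy_x],
            [cxy_w, var_y, cxy_x, cov_yy],
            [cov_x, cxy_x, var_x, cxy_w],
            [cxy_x, cov_yy, cxy_w, var_y],
        ]
    )
    return mu, sigma


# ---------------------------------------------------------------------------
# data containers

def _subset_count(df: pd.DataFrame, subset: tuple[str, ...]) -> np.ndarray:
    cols = [f"{p}_met" for p in subset]
    arr = df[cols].to_numpy(float)
    count = arr.sum(axis=1)
    count[np.isnan(arr).any(axis=1)] = np.nan
    return count


class _GroupData:
    """Paired arrays for one sex group, organized by zygosity and
    missingness pattern over the (X1, Y1, X2, Y2) vector."""

    def __init__(self, pairs: pd.DataFrame, outcome: str, covariates):
        self.covariates = tuple(covariates)
        self.by_zyg = {}
        self.n_pairs = {}
        for zyg in ("MZ", "DZ"):
            sub = pairs[pairs["zygosity"] == zyg]
            X = pair_array(sub, "x_count")
            Y = pair_array(sub, outcome)
            if self.covariates:
                Z = np.stack(
                    [
                        np.column_stack(
                            [sub[f"{c}_1"].to_numpy(float) for c in self.covariates]
                        ),
                        np.column_stack(
                            [sub[f"{c}_2"].to_numpy(float) for c in self.covariates]
                        ),
                    ],
                    axis=1,
                )  # (n, 2, q)
                keep = ~np.isnan(Z).any(axis=(1, 2))
                X, Y, Z = X[keep], Y[keep], Z[keep]
                Z = Z - np.nanmean(Z, axis=(0, 1), keepdims=True)
            else:
                Z = None
            informative = ~(np.isnan(X).all(axis=1) & np.isnan(Y).all(axis=1))
            X, Y = X[informative], Y[informative]
            if Z is not None:
                Z = Z[informative]
            self.n_pairs[zyg] = int(X.shape[0])
            V = np.column_stack([X[:, 0], Y[:, 0], X[:, 1], Y[:, 1]])
            obs = ~np.isnan(V)
            pattern_id = obs @ (1 << np.arange(4))
            patterns = {}
            for pid in np.unique(pattern_id):
                if pid == 0:
                    continue
                rows = pattern_id == pid
                idx = np.flatnonzero([(pid >> b) & 1 for b in range(4)])
                vals = V[rows][:, idx]
                entry = {"idx": idx, "vals": vals, "n": int(rows.sum())}
                entry["sum"] = vals.sum(axis=0)
                entry["scatter"] = vals.T @ vals
                if Z is not None:
                    entry["Z"] = Z[rows]
                patterns[int(pid)] = entry
            self.by_zyg[zyg] = patterns

    def m2ll(self, params: StructuralParams) -> float:
        total = 0.0
        for zyg, patterns in self.by_zyg.items():
            mu, sigma = implied_pair_moments(params, zyg)
            for p in patterns.values():
                idx = p["idx"]
                s_o = sigma[np.ix_(idx, idx)]
                try:
                    L = np.linalg.cholesky(s_o)
                except np.linalg.LinAlgError:
                    return _PENALTY
                logdet = 2.0 * np.log(np.diag(L)).sum()
                m = mu[idx]
                if "Z" in p:
                    shift = np.zeros((p["n"], len(idx)))
                    for col, j in enumerate(idx):
                        if j == 1:
                            shift[:, col] = p["Z"][:, 0, :] @ params.betas
                        elif j == 3:
                            shift[:, col] = p["Z"][:, 1, :] @ params.betas
                    resid = p["vals"] - m - shift
                    w = np.linalg.solve(L, resid.T)
                    quad = float((w * w).sum())
                else:
                    S = p["scatter"] - np.outer(p["sum"], m) - np.outer(m, p["sum"]) \
                        + p["n"] * np.outer(m, m)
                    w = np.linalg.solve(s_o, S)
                    quad = float(np.trace(w))
                total += p["n"] * (len(idx) * _LOG2PI + logdet) + quad
        return total


# ---------------------------------------------------------------------------
# observed-count likelihood and fitting

def _obs_param_names(free_bf: bool, covariates, with_bp: bool = True):
    names = ["mu_x", "p_xa", "p_xc", "p_xe"]
    if with_bp:
        names.append("b_p")
    if free_bf:
        names.append("b_f")
    names += ["mu_y", "p_ua", "p_uc", "p_ue"]
    names += [f"beta_{c}" for c in covariates]
    return names


def _obs_unpack(theta, free_bf, covariates, b_p=None):
    i = 0
    mu_x, p_xa, p_xc, p_xe = theta[i : i + 4]; i += 4
    if b_p is None:
        b_p = theta[i]; i += 1
    if free_bf:
        b_f = theta[i]; i += 1
    else:
        b_f = 0.0
    mu_y, p_ua, p_uc, p_ue = theta[i : i + 4]; i += 4
    betas = np.asarray(theta[i:], float)
    return StructuralParams(
        mu_x=mu_x, p_xa=p_xa, p_xc=p_xc, p_xe=p_xe, b_p=b_p, b_a=b_f, b_c=b_f,
        mu_y=mu_y, p_ua=p_ua, p_uc=p_uc, p_ue=p_ue, betas=betas,
    )


def _obs_start(data: _GroupData, free_bf: bool, covariates):
    xs, ys, xy = [], [], []
    rx, ry = {}, {}
    for zyg, patterns in data.by_zyg.items():
        full = patterns.get(15)
        if full is None:
            continue
        v = full["vals"]
        xs.append(np.concatenate([v[:, 0], v[:, 2]]))
        ys.append(np.concatenate([v[:, 1], v[:, 3]]))
        xy.append(v)
        sym_x = np.concatenate([v[:, [0, 2]], v[:, [2, 0]]])
        sym_y = np.concatenate([v[:, [1, 3]], v[:, [3, 1]]])
        rx[zyg] = float(np.corrcoef(sym_x.T)[0, 1]) if len(v) > 3 else 0.3
        ry[zyg] = float(np.corrcoef(sym_y.T)[0, 1]) if len(v) > 3 else 0.3
    x = np.concatenate(xs) if xs else np.array([0.0, 1.0])
    y = np.concatenate(ys) if ys else np.array([0.0, 1.0])
    mu_x, var_x = float(x.mean()), max(float(x.var()), 1e-3)
    mu_y, var_y = float(y.mean()), max(float(y.var()), 1e-3)
    bp0 = float(np.cov(x, y)[0, 1] / var_x) if len(x) > 3 else 0.0

    def shares(rmz, rdz):
        a2 = float(np.clip(2 * (rmz - rdz), 0.05, 0.85))
        c2 = float(np.clip(2 * rdz - rmz, 0.05, 0.85))
        e2 = max(1.0 - a2 - c2, 0.1)
        s = a2 + c2 + e2
        return a2 / s, c2 / s, e2 / s

    ax2, cx2, ex2 = shares(rx.get("MZ", 0.4), rx.get("DZ", 0.25))
    ay2, cy2, ey2 = shares(ry.get("MZ", 0.4), ry.get("DZ", 0.25))
    resid_var = max(var_y - bp0**2 * var_x, 0.2 * var_y)
    theta = [mu_x, np.sqrt(ax2 * var_x), np.sqrt(cx2 * var_x), np.sqrt(ex2 * var_x),
             bp0]
    if free_bf:
        theta.append(0.0)
    theta += [mu_y, np.sqrt(ay2 * resid_var), np.sqrt(cy2 * resid_var),
              np.sqrt(ey2 * resid_var)]
    theta += [0.0] * len(covariates)
    return np.array(theta), bp0


# ---------------------------------------------------------------------------
# liability-ordinal likelihood

def _liab_param_names(n_thresh, free_bf, covariates, with_bp=True):
    names = [f"t{j+1}" for j in range(n_thresh)]
    names += ["q_xa", "q_xc", "q_xe"]
    if with_bp:
        names.append("b_p")
    if free_bf:
        names.append("b_f")
    names += ["mu_y", "p_ua", "p_uc", "p_ue"]
    names += [f"beta_{c}" for c in covariates]
    return names


def _liab_thresholds(raw):
    t = np.empty(len(raw))
    t[0] = raw[0]
    if len(raw) > 1:
        t[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    return t


def _liab_unpack(theta, n_thresh, free_bf, covariates, b_p=None):
    i = n_thresh
    raw_t = np.asarray(theta[:i], float)
    q = np.asarray(theta[i : i + 3], float); i += 3
    tot = float((q**2).sum())
    if tot <= 1e-12:
        return None, None
    ax, cx, ex = np.sqrt(q**2 / tot)
    if b_p is None:
        b_p = theta[i]; i += 1
    b_f = theta[i] if free_bf else 0.0
    if free_bf:
        i += 1
    mu_y, p_ua, p_uc, p_ue = theta[i : i + 4]; i += 4
    betas = np.asarray(theta[i:], float)
    params = StructuralParams(
        mu_x=0.0, p_xa=ax, p_xc=cx, p_xe=ex, b_p=b_p, b_a=b_f, b_c=b_f,
        mu_y=mu_y, p_ua=p_ua, p_uc=p_uc, p_ue=p_ue, betas=betas,
    )
    return params, _liab_thresholds(raw_t)


def liability_predictor_loglik(pair_counts, pair_outcomes, zygosity, params,
                               thresholds):
    """Per-pair log-likelihood with an ordinal (liability) predictor.

    ``pair_counts`` (n, 2) integer categories (NaN missing), cut from a
    standard-normal liability at ``thresholds``; ``pair_outcomes`` (n, 2)
    continuous (NaN missing).  The joint of (L1, L2, Y1, Y2) is Gaussian,
    so each contribution factorizes exactly as

        N(Y_obs) * P(liability rectangle | Y_obs),

    the rectangle probability being a conditional bivariate-normal CDF
    difference.  This is deterministic (no simulation): the conditioning
    is closed-form Gaussian algebra and the rectangle uses quadrature on
    the tetrachoric integral.
    """
    X = np.asarray(pair_counts, float)
    Y = np.asarray(pair_outcomes, float)
    n = X.shape[0]
    thresholds = np.asarray(thresholds, float)
    edges = np.concatenate([[-np.inf], thresholds, [np.inf]])
    _, sigma = implied_pair_moments(params, zygosity)
    # reorder to (L1, L2, Y1, Y2)
    order = [0, 2, 1, 3]
    sig = sigma[np.ix_(order, order)]
    s_ll, s_ly, s_yy = sig[:2, :2], sig[:2, 2:], sig[2:, 2:]

    out = np.zeros(n)
    obs_x = ~np.isnan(X)
    obs_y = ~np.isnan(Y)
    pattern = (
        obs_x[:, 0].astype(int)
        | (obs_x[:, 1].astype(int) << 1)
        | (obs_y[:, 0].astype(int) << 2)
        | (obs_y[:, 1].astype(int) << 3)
    )
    for pid in np.unique(pattern):
        rows = pattern == pid
        xo = [b for b in range(2) if (pid >> b) & 1]
        yo = [b for b in range(2) if (pid >> (b + 2)) & 1]
        ll = np.zeros(int(rows.sum()))
        if yo:
            syy = s_yy[np.ix_(yo, yo)]
            L = np.linalg.cholesky(syy)
            resid = Y[rows][:, yo] - params.mu_y
            w = np.linalg.solve(L, resid.T)
            ll += -0.5 * (
                len(yo) * _LOG2PI + 2 * np.log(np.diag(L)).sum() + (w * w).sum(axis=0)
            )
            gain = np.linalg.solve(syy, s_ly[:, yo].T).T  # (2, |yo|)
            cond_mean = (gain @ resid.T).T
            cond_cov = s_ll - gain @ s_ly[:, yo].T
        else:
            cond_mean = np.zeros((int(rows.sum()), 2))
            cond_cov = s_ll
        if xo:
            sd = np.sqrt(np.clip(np.diag(cond_cov), 1e-12, None))
            k = X[rows].astype(float)
            if len(xo) == 2:
                rho = float(np.clip(cond_cov[0, 1] / (sd[0] * sd[1]), -1, 1))
                lo1 = (edges[k[:, 0].astype(int)] - cond_mean[:, 0]) / sd[0]
                hi1 = (edges[k[:, 0].astype(int) + 1] - cond_mean[:, 0]) / sd[0]
                lo2 = (edges[k[:, 1].astype(int)] - cond_mean[:, 1]) / sd[1]
                hi2 = (edges[k[:, 1].astype(int) + 1] - cond_mean[:, 1]) / sd[1]
                p = bvn_rect(lo1, hi1, lo2, hi2, rho)
            else:
                j = xo[0]
                lo = (edges[k[:, j].astype(int)] - cond_mean[:, j]) / sd[j]
                hi = (edges[k[:, j].astype(int) + 1] - cond_mean[:, j]) / sd[j]
                p = norm.cdf(hi) - norm.cdf(lo)
            ll += np.log(np.clip(p, 1e-300, None))
        out[rows] = ll
    return out


class _LiabGroupData:
    """Raw paired arrays for the liability-ordinal likelihood."""

    def __init__(self, pairs: pd.DataFrame, outcome: str, covariates, n_cats: int):
        self.covariates = tuple(covariates)
        self.n_cats = n_cats
        self.by_zyg = {}
        self.n_pairs = {}
        for zyg in ("MZ", "DZ"):
            sub = pairs[pairs["zygosity"] == zyg]
            X = pair_array(sub, "x_count")
            Y = pair_array(sub, outcome)
            Z = None
            if self.covariates:
                Z = np.stack(
                    [np.column_stack([sub[f"{c}_{t}"].to_numpy(float)
                                      for c in self.covariates]) for t in (1, 2)],
                    axis=1,
                )
                keep = ~np.isnan(Z).any(axis=(1, 2))
                X, Y, Z = X[keep], Y[keep], Z[keep]
                Z = Z - np.nanmean(Z, axis=(0, 1), keepdims=True)
            informative = ~(np.isnan(X).all(axis=1) & np.isnan(Y).all(axis=1))
            X, Y = X[informative], Y[informative]
            if Z is not None:
                Z = Z[informative]
            self.by_zyg[zyg] = (X, Y, Z)
            self.n_pairs[zyg] = int(X.shape[0])

    def m2ll(self, params: StructuralParams, thresholds) -> float:
        if params is None or np.any(np.diff(thresholds) <= 0):
            return _PENALTY
        total = 0.0
        for zyg, (X, Y, Z) in self.by_zyg.items():
            Yadj = Y
            if Z is not None and params.betas.size:
                Yadj = Y - np.einsum("ntq,q->nt", Z, params.betas)
            try:
                ll = liability_predictor_loglik(X, Yadj, zyg, params, thresholds)
            except np.linalg.LinAlgError:
                return _PENALTY
            total -= 2.0 * float(ll.sum())
        return total


def _liab_start(data: _LiabGroupData, free_bf, covariates):
    counts, ys = [], []
    for X, Y, _ in data.by_zyg.values():
        counts.append(X[~np.isnan(X)])
        ys.append(Y[~np.isnan(Y)])
    c = np.concatenate(counts)
    y = np.concatenate(ys)
    K = data.n_cats
    freq = np.bincount(c.astype(int), minlength=K) / max(len(c), 1)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    t0 = norm.ppf(cum)
    raw = np.concatenate([[t0[0]], np.log(np.clip(np.diff(t0), 1e-3, None))])
    mu_y, var_y = float(y.mean()), max(float(y.var()), 1e-4)
    theta = list(raw) + [np.sqrt(0.4), np.sqrt(0.2), np.sqrt(0.4), 0.0]
    if free_bf:
        theta.append(0.0)
    rv = np.sqrt(var_y / 3.0)
    theta += [mu_y, rv, rv, rv]
    theta += [0.0] * len(covariates)
    return np.array(theta)


# ---------------------------------------------------------------------------
# fit results

@dataclass
class QuasiCausalFit:
    """Estimates, covariance and fit statistics for one model level."""

    spec: QuasiCausalSpec
    param_names: list[str]
    estimates: np.ndarray
    vcov: np.ndarray
    minus2ll: float
    n_pairs: dict
    converged: bool
    boundary: bool
    wald: tuple[float, int, float] | None = None

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.estimates)))

    @property
    def se(self) -> dict[str, float]:
        return dict(
            zip(self.param_names, np.sqrt(np.clip(np.diag(self.vcov), 0, None)))
        )

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def z_and_p(self, name: str):
        est, se = self.params[name], self.se[name]
        z = est / se if se > 0 else np.nan
        return z, 2 * norm.sf(abs(z))

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "pillars": list(self.spec.pillar_subset()),
            "model_level": self.spec.model_level,
            "predictor_mode": self.spec.predictor_mode,
            "params": self.params,
            "se": {k: float(v) for k, v in self.se.items()},
            "minus2ll": self.minus2ll,
            "n_pairs": self.n_pairs,
            "converged": self.converged,
            "boundary": self.boundary,
            "wald": None if self.wald is None else {
                "statistic": self.wald[0], "df": self.wald[1], "p": self.wald[2]
            },
        }


def _minimize(fun, theta0):
    res = optimize.minimize(
        fun, theta0, method="L-BFGS-B",
        options={"maxiter": 800, "ftol": 1e-11, "gtol": 1e-7},
    )
    return res


def _hessian(fun, theta, step=5e-4):
    theta = np.asarray(theta, float)
    k = len(theta)
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        H = np.where(np.isfinite(H), H, 0.0)
    return H, f0


def _prepare_groups(spec: QuasiCausalSpec, coded: pd.DataFrame):
    subset = spec.pillar_subset()
    df = coded.copy()
    df["x_count"] = _subset_count(df, subset)
    cols = ["x_count", spec.outcome, *spec.covariates]
    pairs = to_pairs(df, cols)
    if spec.groups is None:
        return {"all": pairs}, len(subset) + 1
    out = {}
    for g in spec.groups:
        sub = pairs[pairs["sex"] == g]
        if not len(sub):
            raise ValueError(f"no pairs for group {g!r}")
        out[g] = sub
    return out, len(subset) + 1


def fit_model(spec: QuasiCausalSpec, coded: pd.DataFrame,
              compute_vcov: bool = True) -> QuasiCausalFit:
    """Fit the requested model level by FIML.

    Models 1 and 2 are fitted per sex group (groups are independent, so
    the joint covariance is block-diagonal and cross-group Wald tests are
    available); Model 3 is a joint fit with ``b_p`` shared.
    Parameter names are prefixed ``group:name`` when more than one group
    is present.
    """
    group_pairs, n_cats = _prepare_groups(spec, coded)
    liab = spec.predictor_mode == "liability_ordinal"
    free_bf = spec.model_level >= 2

    datas = {}
    for g, pairs in group_pairs.items():
        if liab:
            datas[g] = _LiabGroupData(pairs, spec.outcome, spec.covariates, n_cats)
        else:
            datas[g] = _GroupData(pairs, spec.outcome, spec.covariates)

    def group_fun(g):
        data = datas[g]
        if liab:
            nt = n_cats - 1

            def fun(theta, b_p=None):
                params, t = _liab_unpack(theta, nt, free_bf, spec.covariates, b_p=b_p)
                return data.m2ll(params, t) if params is not None else _PENALTY

            theta0 = _liab_start(data, free_bf, spec.covariates)
            names = _liab_param_names(nt, free_bf, spec.covariates)
        else:

            def fun(theta, b_p=None):
                return data.m2ll(
                    _obs_unpack(theta, free_bf, spec.covariates, b_p=b_p)
                )

            theta0, _ = _obs_start(data, free_bf, spec.covariates)
            names = _obs_param_names(free_bf, spec.covariates)
        return fun, theta0, names

    n_pairs = {g: d.n_pairs for g, d in datas.items()}

    if spec.model_level in (1, 2):
        all_names, all_est, blocks = [], [], []
        m2ll = 0.0
        converged = True
        for g in datas:
            fun, theta0, names = group_fun(g)
            res = _minimize(fun, theta0)
            converged &= bool(res.success)
            m2ll += float(res.fun)
            prefix = f"{g}:" if len(datas) > 1 else ""
            all_names += [prefix + n for n in names]
            all_est.append(res.x)
            if compute_vcov:
                H, _ = _hessian(fun, res.x)
                blocks.append(2.0 * np.linalg.pinv(H))
            else:
                blocks.append(np.full((len(names), len(names)), np.nan))
        est = np.concatenate(all_est)
        k = len(est)
        vcov = np.zeros((k, k))
        i = 0
        for b in blocks:
            vcov[i : i + b.shape[0], i : i + b.shape[0]] = b
            i += b.shape[0]
        boundary = _boundary_flag(all_names, est)
        return QuasiCausalFit(spec, all_names, est, vcov, m2ll, n_pairs,
                              converged, boundary)

    # Model 3: joint fit, shared b_p
    funs, starts, names_g = {}, {}, {}
    for g in datas:
        funs[g], starts[g], names_g[g] = group_fun(g)
    bp_idx = {g: names_g[g].index("b_p") for g in datas}
    groups = list(datas)
    sizes = {g: len(starts[g]) - 1 for g in groups}
    theta0 = np.concatenate(
        [[np.mean([starts[g][bp_idx[g]] for g in groups])]]
        + [np.delete(starts[g], bp_idx[g]) for g in groups]
    )

    def joint(theta):
        bp = theta[0]
        tot = 0.0
        i = 1
        for g in groups:
            tot += funs[g](theta[i : i + sizes[g]], b_p=bp)
            i += sizes[g]
        return tot

    res = _minimize(joint, theta0)
    all_names = ["b_p"] + [
        f"{g}:{n}" for g in groups for n in names_g[g] if n != "b_p"
    ]
    if compute_vcov:
        H, _ = _hessian(joint, res.x)
        vcov = 2.0 * np.linalg.pinv(H)
    else:
        vcov = np.full((len(res.x), len(res.x)), np.nan)
    boundary = _boundary_flag(all_names, res.x)
    return QuasiCausalFit(spec, all_names, res.x, vcov, float(res.fun),
                          n_pairs, bool(res.success), boundary)


def _boundary_flag(names, est) -> bool:
    for n, v in zip(names, est):
        base = n.split(":")[-1]
        if base in ("p_xa", "p_xc", "p_xe", "p_ua", "p_uc", "p_ue", "q_xa",
                    "q_xc", "q_xe") and abs(v) < 1e-4:
            return True
    return False


# ---------------------------------------------------------------------------
# tests and conversions

def wald_test(fit: QuasiCausalFit, R, r=None):
    """Wald chi-square test of the linear restriction R theta = r.

    ``R`` may be a matrix over ``fit.param_names`` or a list of parameter
    names (each tested against 0).  Returns (statistic, df, p).
    """
    if isinstance(R, (list, tuple)) and all(isinstance(x, str) for x in R):
        mat = np.zeros((len(R), len(fit.param_names)))
        for i, name in enumerate(R):
            mat[i, fit.param_names.index(name)] = 1.0
        R = mat
    R = np.atleast_2d(np.asarray(R, float))
    r = np.zeros(R.shape[0]) if r is None else np.asarray(r, float)
    diff = R @ fit.estimates - r
    mid = R @ fit.vcov @ R.T
    if np.linalg.matrix_rank(mid) < mid.shape[0]:
        raise np.linalg.LinAlgError("singular restricted covariance")
    stat = float(diff @ np.linalg.solve(mid, diff))
    df = R.shape[0]
    return stat, df, float(chi2.sf(stat, df))


def wald_equal(fit: QuasiCausalFit, name_a: str, name_b: str):
    """Wald test of equality of two parameters (e.g. b_p across sexes)."""
    R = np.zeros((1, len(fit.param_names)))
    R[0, fit.param_names.index(name_a)] = 1.0
    R[0, fit.param_names.index(name_b)] = -1.0
    return wald_test(fit, R)


def percent_change_per_pillar(b_p: float) -> float:
    """Percent decrease in the raw outcome per additional pillar met.

    For an outcome modeled on the natural-log scale, a slope ``b_p``
    multiplies the raw outcome by ``exp(b_p)`` per pillar; the percent
    decrease is ``100 (1 - exp(b_p))`` (negative slope -> positive
    percent decrease).
    """
    return 100.0 * (1.0 - np.exp(b_p))


def multiplicative_factor(b_p: float) -> float:
    """Multiplicative change in the raw outcome per additional pillar met."""
    return float(np.exp(b_p))
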