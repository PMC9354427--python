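"""Regression trees over binary pillar indicators with surrogate splits.

A small, transparent CART implementation specialized to this analysis:
continuous outcome, binary (met / not-met / missing) predictors,
ANOVA-style splitting (reduction in within-node sum of squared errors),
surrogate splits for routing cases missing the primary splitter,
cost-complexity pruning tuned by seeded k-fold cross-validation, and the
summed-improvement variable-importance measure scaled to total 100.

Conventions follow the classic recursive-partitioning method: a node is
split only when it holds at least ``minsplit`` cases and the best split
improves the fit by at least ``cp`` times the root sum of squares; each
child must receive at least ``minbucket`` cases.  Cases missing the
primary splitter are routed by the first applicable surrogate (ordered
by agreement with the primary split, keeping only surrogates that beat
the go-with-the-majority baseline) and otherwise to the majority side.
Variable importance credits each split's improvement to its primary
variable and, weighted by adjusted agreement, to its surrogates.

Ties on equal improvement are broken by the canonical pillar order, so
results are invariant to row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pillars import PILLAR_COLUMNS

__all__ = [
    "TreeNode",
    "RegressionTree",
    "best_split",
    "find_surrogates",
    "grow_tree",
    "cv_prune",
    "variable_importance",
    "fit_regression_tree",
]


@dataclass
class Surrogate:
    variable: str
    left_value: float  # predictor value sent left (1.0 or 0.0)
    agreement: float
    adjusted: float


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    node_mean: float
    sse: float
    fraction_of_root: float
    split_var: str | None = None
    improvement: float = 0.0
    surrogates: list[Surrogate] = field(default_factory=list)
    majority_left: bool = True
    left: int | None = None
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class RegressionTree:
    nodes: dict[int, TreeNode]
    variables: list[str]
    outcome: str
    minsplit: int
    minbucket: int
    cp: float
    cp_table: pd.DataFrame | None = None

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    def leaves(self):
        return [nd for nd in self.nodes.values() if nd.is_leaf]

    def n_splits(self) -> int:
        return sum(1 for nd in self.nodes.values() if not nd.is_leaf)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[self.variables].to_numpy(float)
        out = np.empty(arr.shape[0])
        for i in range(arr.shape[0]):
            out[i] = self.nodes[self._route(arr[i])].node_mean
        return out

    def _route(self, row) -> int:
        nid = 0
        while not self.nodes[nid].is_leaf:
            nd = self.nodes[nid]
            go_left = None
            v = row[self.variables.index(nd.split_var)]
            if not np.isnan(v):
                go_left = v == 1.0
            else:
                for s in nd.surrogates:
                    sv = row[self.variables.index(s.variable)]
                    if not np.isnan(sv):
                        go_left = sv == s.left_value
                        break
                if go_left is None:
                    go_left = nd.majority_left
            nid = nd.left if go_left else nd.right
        return nid

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "variables": self.variables,
            "minsplit": self.minsplit,
            "minbucket": self.minbucket,
            "cp": self.cp,
            "nodes": {
                str(i): {
                    "depth": nd.depth, "n": nd.n, "mean": nd.node_mean,
                    "sse": nd.sse, "fraction_of_root": nd.fraction_of_root,
                    "split_var": nd.split_var, "improvement": nd.improvement,
                    "surrogates": [
                        {"variable": s.variable, "left_value": s.left_value,
                         "agreement": s.agreement, "adjusted": s.adjusted}
                        for s in nd.surrogates
                    ],
                    "left": nd.left, "right": nd.right,
                }
                for i, nd in self.nodes.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def render(self) -> str:
        """Text rendering: node mean and share of the sample, per node."""
        lines = []

        def rec(nid, indent, label):
            nd = self.nodes[nid]
            lines.append(
                f"{'  ' * indent}{label}mean={nd.node_mean:.2f} "
                f"({100 * nd.fraction_of_root:.0f}%, n={nd.n})"
                + ("" if nd.is_leaf else f" split on {nd.split_var}")
            )
            if not nd.is_leaf:
                rec(nd.left, indent + 1, f"{nd.split_var}=met: ")
                rec(nd.right, indent + 1, f"{nd.split_var}=not met: ")

        rec(0, 0, "")
        return "\n".join(lines)


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def best_split(y, X, variables, minbucket=1):
    """Best binary split by SSE reduction.

    For each candidate, the improvement is computed over cases
    non-missing on that candidate: SSE(parent) - SSE(left) - SSE(right).
    Returns ``(variable, improvement)`` or ``None`` when no candidate
    yields positive improvement with at least ``minbucket`` cases per
    side.  Ties go to the earliest variable in ``variables``.
    """
    best = None
    for j, var in enumerate(variables):
        x = X[:, j]
        ok = ~np.isnan(x)
        if not ok.any():
            continue
        yv, xv = y[ok], x[ok]
        left = xv == 1.0
        n_l, n_r = int(left.sum()), int((~left).sum())
        if n_l < minbucket or n_r < minbucket:
            continue
        imp = _sse(yv) - _sse(yv[left]) - _sse(yv[~left])
        if imp > 0 and (best is None or imp > best[1] + 1e-12):
            best = (var, imp)
    return best


def find_surrogates(primary_left, X, variables, primary_var):
    """Ordered surrogates for a primary split.

    ``primary_left`` is the boolean routing of cases non-missing on the
    primary (aligned with rows of ``X``; NaN-primary rows are excluded
    by the caller).  For each other variable, the better of its two
    orientations is scored by agreement with the primary routing among
    cases observed on both; surrogates must beat the go-with-majority
    baseline.  Returned sorted by agreement (descending), ties in
    canonical variable order.
    """
    out = []
    for j, var in enumerate(variables):
        if var == primary_var:
            continue
        x = X[:, j]
        ok = ~np.isnan(x)
        if not ok.any():
            continue
        n_both = int(ok.sum())
        maj = max(primary_left[ok].mean(), 1 - primary_left[ok].mean())
        agree1 = float((primary_left[ok] == (x[ok] == 1.0)).mean())
        agree0 = float((primary_left[ok] == (x[ok] == 0.0)).mean())
        left_value, agree = (1.0, agree1) if agree1 >= agree0 else (0.0, agree0)
        if agree > maj + 1e-12:
            adj = (agree - maj) / (1.0 - maj) if maj < 1 else 0.0
            out.append(Surrogate(var, left_value, agree, adj))
    out.sort(key=lambda s: (-s.agreement, variables.index(s.variable)))
    return out


def _route_cases(nd_rows_X, variables, split_var, surrogates, majority_left):
    """Boolean go-left for every case at a node, with surrogate routing."""
    x = nd_rows_X[:, variables.index(split_var)]
    go_left = np.where(np.isnan(x), np.nan, x == 1.0)
    for s in surrogates:
        sv = nd_rows_X[:, variables.index(s.variable)]
        fill = np.isnan(go_left) & ~np.isnan(sv)
        go_left = np.where(fill, sv == s.left_value, go_left)
    go_left = np.where(np.isnan(go_left), majority_left, go_left)
    return go_left.astype(bool)


def grow_tree(
    data: pd.DataFrame,
    outcome: str,
    variables: list[str] | None = None,
    minsplit: int = 20,
    minbucket: int | None = None,
    cp: float = 0.01,
    max_depth: int = 30,
) -> RegressionTree:
    """Grow a regression tree by recursive SSE partitioning.

    Rows with a missing outcome are dropped; predictors may be missing
    and are handled by surrogate routing.  Splitting stops when a node
    has fewer than ``minsplit`` cases, or when no split achieves an
    improvement of at least ``cp`` times the root SSE.
    """
    variables = list(variables or PILLAR_COLUMNS)
    if minbucket is None:
        minbucket = max(minsplit // 3, 1)
    keep = data[outcome].notna()
    y = data.loc[keep, outcome].to_numpy(float)
    X = data.loc[keep, variables].to_numpy(float)
    if y.size == 0:
        raise ValueError("no cases with observed outcome")

    nodes: dict[int, TreeNode] = {}
    root_sse = _sse(y)
    threshold = cp * root_sse
    counter = [0]

    def build(rows: np.ndarray, depth: int) -> int:
        nid = counter[0]
        counter[0] += 1
        yv = y[rows]
        nd = TreeNode(
            node_id=nid, depth=depth, n=int(rows.size),
            node_mean=float(yv.mean()), sse=_sse(yv),
            fraction_of_root=rows.size / y.size,
        )
        nodes[nid] = nd
        if rows.size < minsplit or depth >= max_depth:
            return nid
        found = best_split(yv, X[rows], variables, minbucket)
        if found is None or found[1] < threshold:
            return nid
        var, imp = found
        xv = X[rows][:, variables.index(var)]
        primary_ok = ~np.isnan(xv)
        surrogates = find_surrogates(
            (xv == 1.0)[primary_ok], X[rows][primary_ok], variables, var
        )
        majority_left = bool((xv[primary_ok] == 1.0).mean() >= 0.5)
        nd.split_var = var
        nd.improvement = imp
        nd.surrogates = surrogates
        nd.majority_left = majority_left
        go_left = _route_cases(X[rows], variables, var, surrogates, majority_left)
        nd.left = build(rows[go_left], depth + 1)
        nd.right = build(rows[~go_left], depth + 1)
        return nid

    build(np.arange(y.size), 0)
    tree = RegressionTree(
        nodes=nodes, variables=variables, outcome=outcome,
        minsplit=minsplit, minbucket=minbucket, cp=cp,
    )
    return tree


# ---------------------------------------------------------------------------
# cost-complexity pruning

def _subtree_stats(tree: RegressionTree, nid: int):
    nd = tree.nodes[nid]
    if nd.is_leaf:
        return nd.sse, 1
    sl, ll = _subtree_stats(tree, nd.left)
    sr, lr = _subtree_stats(tree, nd.right)
    return sl + sr, ll + lr


def _prune_to_alpha(tree: RegressionTree, alpha: float) -> RegressionTree:
    """Collapse every internal node whose weakest-link value <= alpha."""
    import copy

    pruned = copy.deepcopy(tree)
    changed = True
    while changed:
        changed = False
        for nid in sorted(pruned.nodes, reverse=True):
            nd = pruned.nodes.get(nid)
            if nd is None or nd.is_leaf:
                continue
            sse_sub, n_leaves = _subtree_stats(pruned, nid)
            g = (nd.sse - sse_sub) / (n_leaves - 1)
            if g <= alpha + 1e-12:
                _collapse(pruned, nid)
                changed = True
    return pruned


def _collapse(tree: RegressionTree, nid: int) -> None:
    nd = tree.nodes[nid]

    def drop(child):
        if child is None:
            return
        c = tree.nodes.pop(child)
        drop(c.left)
        drop(c.right)

    drop(nd.left)
    drop(nd.right)
    nd.split_var = None
    nd.improvement = 0.0
    nd.surrogates = []
    nd.left = nd.right = None


def _alpha_sequence(tree: RegressionTree):
    """Weakest-link alpha sequence (increasing) for the nested subtrees."""
    import copy

    alphas = [0.0]
    work = copy.deepcopy(tree)
    while work.n_splits() > 0:
        best = None
        for nid, nd in work.nodes.items():
            if nd.is_leaf:
                continue
            sse_sub, n_leaves = _subtree_stats(work, nid)
            g = (nd.sse - sse_sub) / (n_leaves - 1)
            if best is None or g < best[0] - 1e-12:
                best = (g, [nid])
            elif abs(g - best[0]) <= 1e-12:
                best[1].append(nid)
        alphas.append(best[0])
        for nid in best[1]:
            if nid in work.nodes and not work.nodes[nid].is_leaf:
                _collapse(work, nid)
    return alphas


def cv_prune(
    tree: RegressionTree,
    data: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    rule: str = "min",
):
    """Cost-complexity pruning with seeded k-fold cross-validation.

    Candidate complexities are the geometric means of successive
    weakest-link alphas of the grown tree.  For each fold a tree is
    grown on the training part with the same settings, pruned to each
    candidate alpha, and scored on the held-out part; ``rule`` selects
    the subtree with minimal CV error (``"min"``) or the smallest
    subtree within one SE of the minimum (``"1se"``).

    Returns ``(pruned_tree, cp_table)``.
    """
    keep = data[tree.outcome].notna()
    data = data.loc[keep].reset_index(drop=True)
    n = len(data)
    if n < folds:
        raise ValueError("fewer cases than folds")
    alphas = _alpha_sequence(tree)
    cand = [0.0]
    for a, b in zip(alphas[1:], alphas[2:]):
        cand.append(float(np.sqrt(a * b)) if a > 0 else b / 2)
    if len(alphas) > 1:
        cand.append(alphas[-1] * 1.0000001)
    cand = sorted(set(cand))

    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(np.arange(n) % folds)
    y = data[tree.outcome].to_numpy(float)
    cv_sse = np.zeros(len(cand))
    cv_sq = np.zeros(len(cand))
    per_fold = np.zeros((folds, len(cand)))
    for f in range(folds):
        train = data[fold_id != f]
        test = data[fold_id == f]
        ft = grow_tree(
            train, tree.outcome, tree.variables, tree.minsplit,
            tree.minbucket, tree.cp,
        )
        for ai, a in enumerate(cand):
            pt = _prune_to_alpha(ft, a)
            pred = pt.predict(test)
            per_fold[f, ai] = float(
                ((test[tree.outcome].to_numpy(float) - pred) ** 2).sum()
            )
    xerror = per_fold.sum(axis=0)
    xstd = per_fold.std(axis=0, ddof=1) * np.sqrt(folds)

    sizes, rel_err = [], []
    for a in cand:
        pt = _prune_to_alpha(tree, a)
        sizes.append(pt.n_splits())
        sse_sub, _ = _subtree_stats(pt, 0)
        rel_err.append(sse_sub / tree.root.sse if tree.root.sse > 0 else 0.0)
    root_sse = tree.root.sse if tree.root.sse > 0 else 1.0
    table = pd.DataFrame(
        {
            "alpha": cand,
            "cp": [a / root_sse for a in cand],
            "nsplit": sizes,
            "rel_error": rel_err,
            "xerror": xerror / root_sse,
            "xstd": xstd / root_sse,
        }
    )
    if rule == "min":
        best_i = int(np.argmin(xerror))
        # among ties within numerical noise, prefer the smallest subtree
        ties = np.flatnonzero(xerror <= xerror[best_i] * (1 + 1e-10))
        best_i = int(ties[np.argmin(np.array(sizes)[ties])])
    elif rule == "1se":
        i_min = int(np.argmin(xerror))
        limit = xerror[i_min] + xstd[i_min]
        ok = np.flatnonzero(xerror <= limit)
        best_i = int(ok[np.argmin(np.array(sizes)[ok])])
    else:
        raise ValueError("rule must be 'min' or '1se'")
    pruned = _prune_to_alpha(tree, cand[best_i])
    pruned.cp_table = table
    return pruned, table


def variable_importance(tree: RegressionTree) -> pd.Series:
    """Summed-improvement variable importance, scaled to total 100.

    Each split's SSE improvement is credited to its primary variable
    and, multiplied by the adjusted agreement, to each retained
    surrogate; variables never appearing score 0.
    """
    imp = {v: 0.0 for v in tree.variables}
    for nd in tree.nodes.values():
        if nd.is_leaf:
            continue
        imp[nd.split_var] += nd.improvement
        for s in nd.surrogates:
            imp[s.variable] += nd.improvement * s.adjusted
    total = sum(imp.values())
    if total > 0:
        imp = {k: 100.0 * v / total for k, v in imp.items()}
    return pd.Series(imp).sort_values(ascending=False)


def fit_regression_tree(
    data: pd.DataFrame,
    outcome: str,
    variables: list[str] | None = None,
    minsplit: int = 20,
    minbucket: int | None = None,
    cp: float = 0.01,
    folds: int = 10,
    seed: int = 0,
    prune_rule: str = "min",
) -> RegressionTree:
    """Grow, cross-validate, and prune a tree; attach the importance table."""
    tree = grow_tree(data, outcome, variables, minsplit, minbucket, cp)
    if tree.n_splits() > 0:
        tree, _ = cv_prune(tree, data, folds=folds, seed=seed, rule=prune_rule)
    return tree
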