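"""Classification trees (CART) for parity-mode discrimination.

Binary recursive partitioning with the Gini impurity, grown unpruned
(complexity parameter 0), with surrogate splits (up to n_covariates - 1 per
node) for missing-value routing and variable-importance credit.  Pruning
follows weakest-link cost-complexity with a stratified 10-fold
cross-validation profile and the 1-SE rule.  Importance credits each split's
primary variable with its n-weighted impurity decrease and every retained
surrogate with the agreement-weighted share of the same decrease.

The implementation is self-contained (no scikit-learn) because surrogate
splits, the rpart-style relative-error CV profile and per-split importance
are the quantities of interest and are not exposed by the usual libraries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitSpec",
    "TreeNode",
    "ClassificationTree",
    "CvProfile",
    "ConfusionSummary",
    "best_split",
    "grow_tree",
    "predict",
    "cost_complexity_sequence",
    "prune_at",
    "cross_validate",
    "prune_1se",
    "variable_importance",
    "classification_summary",
]

_EPS = 1e-12


@dataclass
class SplitSpec:
    """One primary or surrogate split: go left when value < threshold
    (or >= threshold for a reversed surrogate)."""

    variable: str
    var_index: int
    threshold: float
    decrease: float  # Gini decrease at the node (per-case scale)
    role: str = "primary"  # "primary" | "surrogate"
    agreement: float = 1.0  # fraction of primary-known cases matched
    adj_agreement: float = 1.0  # excess agreement over the majority rule
    left_if_less: bool = True

    def goes_left(self, value: float) -> bool | None:
        if np.isnan(value):
            return None
        less = value < self.threshold
        return less if self.left_if_less else not less


@dataclass
class TreeNode:
    counts: np.ndarray  # per-class training counts
    depth: int
    indices: np.ndarray  # training-row indices reaching this node
    split: SplitSpec | None = None
    surrogates: list[SplitSpec] = field(default_factory=list)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    majority_side: str = "left"  # routing fallback when all splits missing
    split_number: int = 0  # 1-based, breadth-first over internal nodes

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def prediction(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def risk(self) -> int:
        """Misclassification count if this node were a leaf."""
        return int(self.counts.sum() - self.counts.max())

    def gini(self) -> float:
        p = self.counts / self.counts.sum()
        return float(1.0 - np.sum(p**2))


@dataclass
class CvProfile:
    """rpart-style complexity table: one row per pruning step."""

    cp: np.ndarray  # relative complexity parameter (alpha / R(root))
    n_leaves: np.ndarray
    rel_error: np.ndarray  # training risk / root risk
    xerror: np.ndarray  # cross-validated risk / root risk
    xstd: np.ndarray
    n_folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cp": self.cp,
                "n_leaves": self.n_leaves,
                "rel_error": self.rel_error,
                "xerror": self.xerror,
                "xstd": self.xstd,
            }
        )


@dataclass
class ClassificationTree:
    root: TreeNode
    variables: list[str]
    classes: list
    params: dict
    X: np.ndarray  # training covariates (kept for importance directions)
    y: np.ndarray  # training class indices
    cv_profile: CvProfile | None = None
    pruned: bool = False

    def n_leaves(self) -> int:
        return _count_leaves(self.root)

    def internal_nodes(self) -> list[TreeNode]:
        """Internal nodes in breadth-first order (split 1 = root split)."""
        out: list[TreeNode] = []
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            if not node.is_leaf:
                out.append(node)
                queue.extend([node.left, node.right])
        return out

    def to_text(self) -> str:
        lines: list[str] = []
        _dump(self.root, self.classes, lines, indent=0)
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(_node_dict(self.root, self.classes), indent=2)


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------


def _gini_from_counts(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
    return 1.0 - np.nansum(p**2, axis=-1)


def _best_split_one_var(
    x: np.ndarray, y: np.ndarray, n_classes: int, minbucket: int
) -> tuple[float, float] | None:
    """Best (threshold, weighted Gini decrease) for one covariate.

    The decrease is on the per-case scale of the node's *full* n, i.e.
    splits searched on a missing subset are down-weighted by the observed
    fraction.  Ties resolve to the smallest threshold (first index of the
    ascending candidate scan).
    """
    obs = ~np.isnan(x)
    n_node = len(x)
    x_o, y_o = x[obs], y[obs]
    n = len(x_o)
    if n < 2 * minbucket:
        return None
    order = np.argsort(x_o, kind="stable")
    xs, ys = x_o[order], y_o[order]
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    left_counts = np.cumsum(onehot, axis=0)[:-1]  # prefix of size i+1
    total = left_counts[-1] + onehot[-1]
    right_counts = total - left_counts
    sizes_l = np.arange(1, n)
    sizes_r = n - sizes_l
    valid = (xs[1:] > xs[:-1]) & (sizes_l >= minbucket) & (sizes_r >= minbucket)
    if not valid.any():
        return None
    g_parent = _gini_from_counts(total)
    g_l = _gini_from_counts(left_counts)
    g_r = _gini_from_counts(right_counts)
    decrease = g_parent - (sizes_l / n) * g_l - (sizes_r / n) * g_r
    decrease = np.where(valid, decrease, -np.inf)
    i = int(np.argmax(decrease))
    if decrease[i] <= _EPS:
        return None
    thr = (xs[i] + xs[i + 1]) / 2.0
    return thr, float(decrease[i]) * (n / n_node)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    variables: Sequence[str],
    var: str | int | None = None,
    minbucket: int = 1,
    n_classes: int | None = None,
) -> SplitSpec | None:
    """Exhaustive Gini split search over midpoints of consecutive values.

    With ``var`` given, only that covariate is searched; otherwise the best
    split over all covariates is returned (ties to the lower variable
    index).  Returns None when no split strictly reduces impurity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n_classes = n_classes or int(y.max()) + 1
    if var is not None:
        j_list = [var if isinstance(var, int) else list(variables).index(var)]
    else:
        j_list = list(range(X.shape[1]))
    best: SplitSpec | None = None
    for j in j_list:
        res = _best_split_one_var(X[:, j], y, n_classes, minbucket)
        if res is None:
            continue
        thr, dec = res
        if best is None or dec > best.decrease + _EPS:
            best = SplitSpec(
                variable=variables[j], var_index=j, threshold=thr, decrease=dec
            )
    return best


def _find_surrogates(
    X: np.ndarray,
    primary: SplitSpec,
    variables: Sequence[str],
    max_surrogates: int,
) -> list[SplitSpec]:
    """Surrogate splits mimicking the primary left/right assignment.

    A surrogate is retained only if it matches more primary-known cases
    than the blind majority-direction rule; candidates are ranked by
    agreement (fraction matched).
    """
    xp = X[:, primary.var_index]
    known = ~np.isnan(xp)
    go_left = xp[known] < primary.threshold
    n_known = int(known.sum())
    if n_known == 0:
        return []
    n_left = int(go_left.sum())
    baseline = max(n_left, n_known - n_left)
    out: list[SplitSpec] = []
    for j in range(X.shape[1]):
        if j == primary.var_index:
            continue
        xj = X[known, j]
        obs = ~np.isnan(xj)
        if obs.sum() < 2:
            continue
        xs_idx = np.argsort(xj[obs], kind="stable")
        xs = xj[obs][xs_idx]
        ls = go_left[obs][xs_idx].astype(int)
        n = len(xs)
        left_prefix = np.cumsum(ls)[:-1]
        total_left = ls.sum()
        sizes = np.arange(1, n)
        # rule "xj < t -> left" agrees on lefts in prefix + rights in suffix
        agree_lt = left_prefix + ((n - sizes) - (total_left - left_prefix))
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            continue
        agree_lt = np.where(valid, agree_lt, -1)
        agree_ge = np.where(valid, n - agree_lt, -1)
        i_lt, i_ge = int(np.argmax(agree_lt)), int(np.argmax(agree_ge))
        if agree_lt[i_lt] >= agree_ge[i_ge]:
            i, left_if_less, agree = i_lt, True, int(agree_lt[i_lt])
        else:
            i, left_if_less, agree = i_ge, False, int(agree_ge[i_ge])
        # agree is counted on the doubly-observed cases only, so cases with
        # the surrogate missing implicitly count as mismatches vs the baseline
        if agree <= baseline:
            continue
        out.append(
            SplitSpec(
                variable=variables[j],
                var_index=j,
                threshold=(xs[i] + xs[i + 1]) / 2.0,
                decrease=primary.decrease,
                role="surrogate",
                agreement=agree / n_known,
                adj_agreement=(agree - baseline) / (n_known - baseline),
                left_if_less=left_if_less,
            )
        )
    out.sort(key=lambda s: (-s.agreement, s.var_index))
    return out[:max_surrogates]


# ---------------------------------------------------------------------------
# growing and prediction
# ---------------------------------------------------------------------------


def grow_tree(
    X: np.ndarray,
    y,
    variables: Sequence[str],
    classes: Sequence | None = None,
    cp: float = 0.0,
    minsplit: int = 20,
    minbucket: int | None = None,
    max_surrogates: int | None = None,
    max_depth: int = 30,
) -> ClassificationTree:
    """Grow the full CART (cp = 0 grows until pure / minsplit / minbucket).

    ``y`` may hold arbitrary labels; ``classes`` fixes their order (default:
    sorted unique).  ``minsplit``/``minbucket`` default to the classic 20/7.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if classes is None:
        classes = sorted(pd.unique(y).tolist())
    classes = list(classes)
    class_index = {c: k for k, c in enumerate(classes)}
    yi = np.asarray([class_index[v] for v in y], dtype=int)
    n_classes = len(classes)
    minbucket = minbucket if minbucket is not None else max(1, round(minsplit / 3))
    max_surrogates = (
        max_surrogates if max_surrogates is not None else X.shape[1] - 1
    )
    if len(np.unique(yi)) < 2:
        warnings.warn("only one class present; returning a single-leaf tree")
    root_risk = len(yi) - np.bincount(yi, minlength=n_classes).max()

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(yi[idx], minlength=n_classes)
        node = TreeNode(counts=counts.astype(float), depth=depth, indices=idx)
        if (
            counts.max() == counts.sum()
            or len(idx) < minsplit
            or depth >= max_depth
        ):
            return node
        spec = best_split(X[idx], yi[idx], variables, minbucket=minbucket,
                          n_classes=n_classes)
        if spec is None:
            return node
        if cp > 0 and spec.decrease * len(idx) < cp * root_risk:
            return node
        node.split = spec
        node.surrogates = _find_surrogates(X[idx], spec, variables, max_surrogates)
        xj = X[idx, spec.var_index]
        known = ~np.isnan(xj)
        go_left = np.zeros(len(idx), dtype=bool)
        go_left[known] = xj[known] < spec.threshold
        node.majority_side = "left" if go_left[known].sum() * 2 >= known.sum() else "right"
        # route missing-primary cases through surrogates, then majority
        for i in np.flatnonzero(~known):
            go_left[i] = _route_left(node, X[idx[i]])
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(len(yi)), 0)
    tree = ClassificationTree(
        root=root,
        variables=list(variables),
        classes=classes,
        params={
            "cp": cp,
            "minsplit": minsplit,
            "minbucket": minbucket,
            "max_surrogates": max_surrogates,
        },
        X=X,
        y=yi,
    )
    _number_splits(tree)
    return tree


def _route_left(node: TreeNode, row: np.ndarray) -> bool:
    d = node.split.goes_left(row[node.split.var_index])
    if d is not None:
        return d
    for s in node.surrogates:
        d = s.goes_left(row[s.var_index])
        if d is not None:
            return d
    return node.majority_side == "left"


def predict(tree: ClassificationTree, X: np.ndarray) -> np.ndarray:
    """Predicted class labels, with surrogate/majority routing of NaNs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = []
    for row in X:
        node = tree.root
        while not node.is_leaf:
            node = node.left if _route_left(node, row) else node.right
        out.append(tree.classes[node.prediction])
    return np.asarray(out)


def _count_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


def _branch_risk(node: TreeNode) -> float:
    if node.is_leaf:
        return node.risk
    return _branch_risk(node.left) + _branch_risk(node.right)


def _number_splits(tree: ClassificationTree) -> None:
    for k, node in enumerate(tree.internal_nodes(), start=1):
        node.split_number = k


# ---------------------------------------------------------------------------
# cost-complexity pruning
# ---------------------------------------------------------------------------


def _copy_tree(node: TreeNode) -> TreeNode:
    new = TreeNode(
        counts=node.counts.copy(),
        depth=node.depth,
        indices=node.indices,
        split=node.split,
        surrogates=node.surrogates,
        majority_side=node.majority_side,
        split_number=node.split_number,
    )
    if not node.is_leaf:
        new.left = _copy_tree(node.left)
        new.right = _copy_tree(node.right)
    return new


def _weakest_g(node: TreeNode, out: list[tuple[float, TreeNode]]) -> None:
    if node.is_leaf:
        return
    leaves = _count_leaves(node)
    g = (node.risk - _branch_risk(node)) / (leaves - 1)
    out.append((g, node))
    _weakest_g(node.left, out)
    _weakest_g(node.right, out)


def _collapse_upto(root: TreeNode, alpha_abs: float) -> None:
    """Iteratively collapse every weakest link with g <= alpha (absolute
    risk scale), yielding the *smallest* optimal subtree for that alpha."""
    while not root.is_leaf:
        glist: list[tuple[float, TreeNode]] = []
        _weakest_g(root, glist)
        g_min = min(g for g, _ in glist)
        if g_min > alpha_abs + _EPS:
            break
        for g, node in glist:
            if g <= g_min + _EPS and not node.is_leaf:
                node.split = None
                node.left = node.right = None


def cost_complexity_sequence(tree: ClassificationTree) -> list[tuple[float, int]]:
    """Weakest-link pruning sequence as (cp, n_leaves) pairs.

    cp is the per-leaf misclassification saving normalized by the root
    risk (the relative-error scale).  Each row is the smallest optimal
    subtree at that cp: row 0 (cp = 0) already collapses branches that do
    not change the training misclassification count, and the sequence ends
    at the root-only tree.
    """
    root_risk = max(tree.root.risk, 1)
    work = _copy_tree(tree.root)
    _collapse_upto(work, 0.0)
    seq: list[tuple[float, int]] = [(0.0, _count_leaves(work))]
    while not work.is_leaf:
        glist: list[tuple[float, TreeNode]] = []
        _weakest_g(work, glist)
        g_min = min(g for g, _ in glist)
        for g, node in glist:
            if g <= g_min + _EPS and not node.is_leaf:
                node.split = None
                node.left = node.right = None
        seq.append((g_min / root_risk, _count_leaves(work)))
    # merge steps that share a cp or a size (multiple equal weakest links)
    dedup: list[tuple[float, int]] = []
    for cp, size in seq:
        if dedup and (abs(cp - dedup[-1][0]) <= _EPS or dedup[-1][1] == size):
            dedup[-1] = (cp, size)
        else:
            dedup.append((cp, size))
    return dedup


def prune_at(tree: ClassificationTree, cp: float) -> ClassificationTree:
    """Smallest optimal subtree for relative complexity parameter cp."""
    root_risk = max(tree.root.risk, 1)
    work = _copy_tree(tree.root)
    _collapse_upto(work, cp * root_risk)
    pruned = ClassificationTree(
        root=work,
        variables=tree.variables,
        classes=tree.classes,
        params=dict(tree.params, pruned_cp=cp),
        X=tree.X,
        y=tree.y,
        cv_profile=tree.cv_profile,
        pruned=True,
    )
    _number_splits(pruned)
    return pruned


# ---------------------------------------------------------------------------
# cross-validation and the 1-SE rule
# ---------------------------------------------------------------------------


def _stratified_folds(
    yi: np.ndarray, n_folds: int, seed: int, max_retries: int = 10
) -> np.ndarray:
    n = len(yi)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 1000 * attempt)
        fold = np.empty(n, dtype=int)
        for c in np.unique(yi):
            idx = np.flatnonzero(yi == c)
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % n_folds
        ok = all(
            len(np.unique(yi[fold != f])) == len(np.unique(yi))
            for f in range(n_folds)
        )
        if ok:
            return fold
    raise RuntimeError("could not build folds with every class in each training set")


def cross_validate(
    X: np.ndarray,
    y,
    variables: Sequence[str],
    n_folds: int = 10,
    seed: int = 0,
    **params,
) -> tuple[ClassificationTree, CvProfile]:
    """Grow the full tree and attach its 10-fold CV complexity profile.

    Folds are stratified by class.  For every cp in the full tree's pruning
    sequence, each fold's tree is pruned at the geometric mean of adjacent
    cp values (the standard evaluation point) and the held-out
    misclassification count is accumulated; xerror/xstd are on the
    relative-to-root-risk scale.
    """
    tree = grow_tree(X, y, variables, **params)
    yi = tree.y
    n = len(yi)
    if n < n_folds:
        raise ValueError(f"n = {n} < n_folds = {n_folds}")
    seq = cost_complexity_sequence(tree)
    cps = np.array([cp for cp, _ in seq])
    sizes = np.array([s for _, s in seq])
    eval_cps = np.sqrt(cps * np.append(cps[1:], cps[-1] if len(cps) > 1 else 0.0))
    eval_cps[-1] = cps[-1]

    root_risk = max(tree.root.risk, 1)
    rel_error = np.array(
        [_branch_risk(prune_at(tree, c).root) / root_risk for c in cps]
    )

    fold = _stratified_folds(yi, n_folds, seed)
    errs = np.zeros(len(cps))
    for f in range(n_folds):
        train, test = fold != f, fold == f
        sub = grow_tree(
            X[train],
            [tree.classes[i] for i in yi[train]],
            variables,
            classes=tree.classes,
            **tree.params,
        )
        for k, c in enumerate(eval_cps):
            pred = predict(prune_at(sub, c), X[test])
            truth = np.asarray([tree.classes[i] for i in yi[test]])
            errs[k] += np.sum(pred != truth)
    xerror = errs / root_risk
    xstd = np.sqrt(errs * np.clip(1 - errs / n, 0, None)) / root_risk
    profile = CvProfile(
        cp=cps,
        n_leaves=sizes,
        rel_error=rel_error,
        xerror=xerror,
        xstd=xstd,
        n_folds=n_folds,
        seed=seed,
    )
    tree.cv_profile = profile
    return tree, profile


def prune_1se(tree: ClassificationTree, profile: CvProfile | None = None) -> ClassificationTree:
    """Prune to the smallest subtree with xerror within one SE of the best."""
    profile = profile or tree.cv_profile
    if profile is None:
        raise ValueError("tree has no CV profile; run cross_validate first")
    k_min = int(np.argmin(profile.xerror))
    threshold = profile.xerror[k_min] + profile.xstd[k_min]
    eligible = np.flatnonzero(profile.xerror <= threshold + _EPS)
    k_sel = int(eligible[np.argmin(profile.n_leaves[eligible])])
    return prune_at(tree, float(profile.cp[k_sel]))


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------


def variable_importance(
    tree: ClassificationTree,
    scope: str | int = "global",
    positive_class=None,
) -> pd.DataFrame:
    """Importance as percent of total impurity improvement.

    Each split credits its primary variable with (Gini decrease x node n)
    and each retained surrogate with its *adjusted* agreement (the excess
    over the blind majority-direction rule, the rpart convention) times
    the same improvement, so a surrogate that barely beats the trivial
    rule earns almost nothing.
    ``scope`` is "global" or a 1-based split number.  A variable is flagged
    significant when its share exceeds 100 / n_covariates.  The direction
    column gives each variable's association with ``positive_class``
    (default: last class): -1 when low values of the variable go with that
    class, +1 when high values do, judged per split from the primary
    variable's side and the Spearman sign between covariate and primary
    variable over the node's cases.
    """
    nodes = tree.internal_nodes()
    if scope != "global":
        nodes = [n for n in nodes if n.split_number == int(scope)]
        if not nodes:
            raise ValueError(f"no split number {scope} in this tree")
    pos = (
        len(tree.classes) - 1
        if positive_class is None
        else tree.classes.index(positive_class)
    )
    credit = dict.fromkeys(tree.variables, 0.0)
    direction_vote = dict.fromkeys(tree.variables, 0.0)
    for node in nodes:
        improvement = node.split.decrease * node.n
        # does the low side of the primary variable lean to the positive class?
        left_pos = node.left.counts[pos] / max(node.left.n, 1)
        right_pos = node.right.counts[pos] / max(node.right.n, 1)
        main_sign = -1.0 if left_pos >= right_pos else 1.0
        specs = [node.split] + node.surrogates
        for s in specs:
            w = 1.0 if s.role == "primary" else s.adj_agreement
            credit[s.variable] += w * improvement
            if s.variable == node.split.variable:
                rho_sign = 1.0
            else:
                xv = tree.X[node.indices, s.var_index]
                xm = tree.X[node.indices, node.split.var_index]
                ok = ~(np.isnan(xv) | np.isnan(xm))
                if ok.sum() < 3:
                    rho_sign = 0.0
                else:
                    rho = stats.spearmanr(xv[ok], xm[ok]).statistic
                    rho_sign = float(np.sign(rho)) if np.isfinite(rho) else 0.0
            direction_vote[s.variable] += w * improvement * main_sign * rho_sign
    total = sum(credit.values())
    if total <= 0:
        return pd.DataFrame(
            columns=["variable", "importance_pct", "significant", "direction"]
        )
    n_vars = len(tree.variables)
    rows = []
    for v in tree.variables:
        pct = 100.0 * credit[v] / total
        rows.append(
            {
                "variable": v,
                "importance_pct": pct,
                "significant": pct > 100.0 / n_vars,
                "direction": int(np.sign(direction_vote[v])),
            }
        )
    df = pd.DataFrame(rows).sort_values("importance_pct", ascending=False)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# confusion summaries
# ---------------------------------------------------------------------------


def _pct(correct: int, total: int) -> float:
    return round(100.0 * correct / total, 1) if total else float("nan")


@dataclass
class ConfusionSummary:
    """Correct-classification counts per parity mode, per clade, overall."""

    per_parity: dict  # name -> (n_correct, n_total)
    per_clade: dict
    overall: tuple[int, int]

    def percent(self, group: str | None = None) -> float:
        """1-decimal percent correct for a parity mode, clade or overall."""
        if group is None:
            return _pct(*self.overall)
        if group in self.per_parity:
            return _pct(*self.per_parity[group])
        return _pct(*self.per_clade[group])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "n_correct": c, "n_total": t, "percent": _pct(c, t)}
            for g, (c, t) in [
                ("overall", self.overall),
                *self.per_parity.items(),
                *self.per_clade.items(),
            ]
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_counts(
        cls, per_parity: dict, per_clade: dict
    ) -> "ConfusionSummary":
        overall = (
            sum(c for c, _ in per_parity.values()),
            sum(t for _, t in per_parity.values()),
        )
        return cls(per_parity=dict(per_parity), per_clade=dict(per_clade), overall=overall)


def classification_summary(
    tree: ClassificationTree,
    X: np.ndarray,
    labels,
    clades,
) -> ConfusionSummary:
    """Resubstitution confusion summary by parity mode and by clade."""
    pred = predict(tree, X)
    labels = np.asarray(labels)
    clades = np.asarray(clades)
    correct = pred == labels
    per_parity = {
        p: (int(correct[labels == p].sum()), int((labels == p).sum()))
        for p in sorted(pd.unique(labels).tolist())
    }
    per_clade = {
        c: (int(correct[clades == c].sum()), int((clades == c).sum()))
        for c in sorted(pd.unique(clades).tolist())
    }
    return ConfusionSummary(
        per_parity=per_parity,
        per_clade=per_clade,
        overall=(int(correct.sum()), len(labels)),
    )


# ---------------------------------------------------------------------------
# dumps
# ---------------------------------------------------------------------------


def _dump(node: TreeNode, classes, lines: list[str], indent: int) -> None:
    pad = "  " * indent
    counts = "/".join(str(int(c)) for c in node.counts)
    if node.is_leaf:
        lines.append(f"{pad}leaf: predict {classes[node.prediction]} [{counts}]")
        return
    s = node.split
    lines.append(
        f"{pad}split {node.split_number}: {s.variable} < {s.threshold:.4g} "
        f"[{counts}] (decrease {s.decrease:.4f}, "
        f"{len(node.surrogates)} surrogate(s))"
    )
    _dump(node.left, classes, lines, indent + 1)
    _dump(node.right, classes, lines, indent + 1)


def _node_dict(node: TreeNode, classes) -> dict:
    d: dict = {
        "counts": {str(classes[k]): int(c) for k, c in enumerate(node.counts)},
        "prediction": str(classes[node.prediction]),
    }
    if not node.is_leaf:
        s = node.split
        d["split"] = {
            "number": node.split_number,
            "variable": s.variable,
            "threshold": s.threshold,
            "decrease": s.decrease,
        }
        d["surrogates"] = [
            {
                "variable": t.variable,
                "threshold": t.threshold,
                "agreement": t.agreement,
                "left_if_less": t.left_if_less,
            }
            for t in node.surrogates
        ]
        d["left"] = _node_dict(node.left, classes)
        d["right"] = _node_dict(node.right, classes)
    return d
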