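"""Regression trees with least-squared-deviation (LSD) splitting.

A from-scratch CART regression tree for a continuous outcome (here the
CD-RISC resilience score, or a change-score target).  Splits are chosen by
exhaustive search over every variable and every midpoint between consecutive
distinct values, maximizing the reduction in within-node sum of squared
deviations; growth stops on a minimum parent size, minimum terminal size,
maximum depth, and a minimum risk improvement.  The tree's *risk estimate*
is the event-weighted within-terminal-node variance, R = (1/N) sum over
terminal nodes of SSE(node), reported raw and normalized by the (population,
1/N denominator) variance of the outcome so a root-only tree has normalized
risk exactly 1.

Ties in improvement are broken deterministically: lowest variable index in
the supplied column order, then smallest threshold.  Row order never affects
the fitted tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: relative tolerance under which two split improvements are considered tied
_TIE_RTOL = 1e-9


@dataclass
class CartConfig:
    """Stopping rules: defaults mirror a 20-subject design (5 = 25% of N
    in a terminal node, 10 observations before splitting, depth 3)."""

    min_terminal: int = 5
    min_parent: int = 10
    max_depth: int = 3
    min_improvement: float = 1e-4  # in normalized-risk units

    def __post_init__(self) -> None:
        if not (self.min_parent > self.min_terminal >= 1):
            raise ValueError("require min_parent > min_terminal >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")


@dataclass
class SplitCandidate:
    var: str
    var_index: int
    threshold: float
    improvement: float  # SSE reduction / N_root, >= 0


@dataclass
class Node:
    node_id: int
    depth: int
    indices: np.ndarray        # row indices of the training data in this node
    mean: float
    sse: float                 # within-node sum of squared deviations
    split_var: str | None = None
    threshold: float | None = None
    improvement: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def n(self) -> int:
        return int(self.indices.size)

    @property
    def is_terminal(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"node_id": self.node_id, "depth": self.depth, "n": self.n,
             "mean": self.mean, "sse": self.sse}
        if not self.is_terminal:
            d.update(split_var=self.split_var, threshold=self.threshold,
                     improvement=self.improvement,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


def _sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def _pop_var(y: np.ndarray) -> float:
    return float(np.var(y))  # 1/N denominator


def _best_split_column(y: np.ndarray, x: np.ndarray, min_terminal: int
                       ) -> tuple[float, float] | None:
    """Best (threshold, SSE reduction) for one variable, or None.

    Uses prefix sums over the value-sorted order; candidate thresholds are
    midpoints between consecutive distinct values.  Ties within a column are
    broken toward the smallest threshold.
    """
    n = y.size
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cs = np.cumsum(ys)
    cs2 = np.cumsum(ys ** 2)
    total, total2 = cs[-1], cs2[-1]
    k = np.arange(1, n)  # left-child sizes
    valid = (xs[1:] != xs[:-1]) & (k >= min_terminal) & (n - k >= min_terminal)
    if not valid.any():
        return None
    left_sum = cs[:-1]
    # SSE reduction = parent SSE - (left SSE + right SSE); the y^2 terms cancel
    red = left_sum ** 2 / k + (total - left_sum) ** 2 / (n - k) - total ** 2 / n
    red = np.where(valid, red, -np.inf)
    best = red.max()
    parent_sse = total2 - total ** 2 / n
    ties = np.flatnonzero(red >= best - _TIE_RTOL * max(abs(best), parent_sse, 1.0))
    i = ties[0]  # smallest threshold among tied candidates (sorted order)
    threshold = float((xs[i] + xs[i + 1]) / 2)
    return threshold, float(max(red[i], 0.0))


def best_split(y, X, cfg: CartConfig, var_names=None, *,
               n_root: int | None = None, var_ref: float | None = None
               ) -> SplitCandidate | None:
    """Exhaustive LSD search for the best admissible split of one node.

    ``X`` is an (n, p) matrix (or DataFrame) restricted to the node's rows.
    Improvement is the SSE reduction divided by ``n_root`` (the size of the
    whole training sample; defaults to this node's n), and the split is
    admissible only if both children have at least ``min_terminal`` rows and
    the improvement reaches ``min_improvement * var_ref`` where ``var_ref``
    defaults to the population variance of this node's y.  Returns None when
    no admissible split exists.
    """
    y = np.asarray(y, dtype=float)
    if hasattr(X, "columns"):  # DataFrame
        var_names = list(X.columns) if var_names is None else var_names
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if var_names is None:
            var_names = [f"x{j}" for j in range(X.shape[1])]
    n = y.size
    if n < cfg.min_parent:
        return None
    n_root = n if n_root is None else n_root
    var_ref = _pop_var(y) if var_ref is None else var_ref
    scale = max(var_ref * n, 1.0)

    best: tuple[float, int, float] | None = None  # (reduction, col, threshold)
    for j in range(X.shape[1]):
        res = _best_split_column(y, X[:, j], cfg.min_terminal)
        if res is None:
            continue
        thr, red = res
        if best is None or red > best[0] + _TIE_RTOL * scale:
            best = (red, j, thr)
        # ties across columns: keep the earlier column (manifest order)
    if best is None:
        return None
    red, j, thr = best
    if red <= 0:  # no split reduces the deviance (e.g. constant outcome)
        return None
    improvement = red / n_root
    if improvement < cfg.min_improvement * var_ref:
        return None
    return SplitCandidate(var=var_names[j], var_index=j, threshold=thr,
                          improvement=improvement)


class RegressionTree:
    """A fitted LSD regression tree (see :func:`fit_tree`)."""

    def __init__(self, root: Node, var_names: list[str], n: int, y_var: float,
                 cfg: CartConfig):
        self.root = root
        self.var_names = var_names
        self.n = n
        self.y_var = y_var  # population variance of the outcome
        self.cfg = cfg

    # -- traversal ----------------------------------------------------------
    def nodes(self) -> list[Node]:
        """Breadth-first node list."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            if not node.is_terminal:
                queue.extend([node.left, node.right])
        return out

    def terminal_nodes(self) -> list[Node]:
        return [nd for nd in self.nodes() if nd.is_terminal]

    def depth(self) -> int:
        return max(nd.depth for nd in self.nodes())

    # -- risk ---------------------------------------------------------------
    @property
    def risk(self) -> float:
        return sum(nd.sse for nd in self.terminal_nodes()) / self.n

    @property
    def normalized_risk(self) -> float | None:
        """risk / Var(y); None (flagged) when the outcome is constant."""
        if self.y_var == 0:
            return None
        return self.risk / self.y_var

    # -- reporting ----------------------------------------------------------
    def splitter_variables(self) -> list[str]:
        """Distinct split variables in breadth-first first-use order."""
        seen: list[str] = []
        for nd in self.nodes():
            if not nd.is_terminal and nd.split_var not in seen:
                seen.append(nd.split_var)
        return seen

    def to_dict(self) -> dict:
        return {"n": self.n, "y_var": self.y_var, "risk": self.risk,
                "normalized_risk": self.normalized_risk,
                "splitters": self.splitter_variables(),
                "root": self.root.to_dict()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def fit_tree(y, X, cfg: CartConfig | None = None, var_names=None) -> RegressionTree:
    """Grow an LSD regression tree under the configured stopping rules.

    Deterministic for a fixed column order; row order is irrelevant.  Raises
    on non-finite outcome values.
    """
    cfg = cfg or CartConfig()
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite values in the outcome")
    if hasattr(X, "columns"):
        var_names = list(X.columns) if var_names is None else var_names
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if var_names is None:
            var_names = [f"x{j}" for j in range(X.shape[1])]
    if len(set(var_names)) != len(var_names):
        raise ValueError("variable names must be unique")
    n = y.size
    if n < 1:
        raise ValueError("empty outcome")
    y_var = _pop_var(y)

    counter = [0]

    def new_node(indices: np.ndarray, depth: int) -> Node:
        node = Node(node_id=counter[0], depth=depth, indices=indices,
                    mean=float(y[indices].mean()), sse=_sse(y[indices]))
        counter[0] += 1
        return node

    root = new_node(np.arange(n), 0)
    queue = [root]
    while queue:
        node = queue.pop(0)
        if node.depth >= cfg.max_depth or node.n < cfg.min_parent or node.sse == 0:
            continue
        cand = best_split(y[node.indices], X[node.indices], cfg,
                          var_names=var_names, n_root=n, var_ref=y_var)
        if cand is None:
            continue
        x = X[node.indices, cand.var_index]
        left_idx = node.indices[x <= cand.threshold]
        right_idx = node.indices[x > cand.threshold]
        node.split_var = cand.var
        node.threshold = cand.threshold
        node.improvement = cand.improvement
        node.left = new_node(left_idx, node.depth + 1)
        node.right = new_node(right_idx, node.depth + 1)
        queue.extend([node.left, node.right])
    return RegressionTree(root, list(var_names), n, y_var, cfg)


def tree_risk(tree: RegressionTree, y=None) -> tuple[float, float | None]:
    """(risk, normalized risk) of a fitted tree.

    When ``y`` is given, the risk is recomputed from the stored node index
    sets against that outcome vector; otherwise the fit-time node SSEs are
    used.  Normalized risk is None when the outcome variance is zero.
    """
    if y is None:
        return tree.risk, tree.normalized_risk
    y = np.asarray(y, dtype=float)
    risk = sum(_sse(y[nd.indices]) for nd in tree.terminal_nodes()) / y.size
    var = _pop_var(y)
    return risk, (None if var == 0 else risk / var)


def splitter_variables(tree: RegressionTree) -> list[str]:
    """Distinct split variables of a fitted tree in breadth-first order."""
    return tree.splitter_variables()
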