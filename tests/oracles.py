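"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit loops, full enumeration)
and shares no code with the package implementation paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np

TIE_RTOL = 1e-9  # same tie convention as the implementation, naive arithmetic


def sse(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    m = sum(y) / len(y)
    return float(sum((v - m) ** 2 for v in y))


def oracle_best_split(y: np.ndarray, X: np.ndarray, min_terminal: int,
                      cross_tol: float) -> tuple[int, float, float] | None:
    """(column, threshold, sse_reduction) by naive exhaustive search.

    Per column the best reduction is found and near-ties resolved toward the
    smallest threshold; across columns a later column wins only if strictly
    better beyond ``cross_tol`` (the implementation's conventions).
    """
    parent = sse(y)
    best = None  # (reduction, col, threshold)
    for j in range(X.shape[1]):
        xs = np.unique(X[:, j])
        col_candidates = []
        for a, b in zip(xs[:-1], xs[1:]):
            thr = (a + b) / 2
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            if len(left) < min_terminal or len(right) < min_terminal:
                continue
            col_candidates.append((thr, parent - sse(left) - sse(right)))
        if not col_candidates:
            continue
        col_best = max(r for _, r in col_candidates)
        tol = TIE_RTOL * max(abs(col_best), parent, 1.0)
        thr, red = min((t, r) for t, r in col_candidates if r >= col_best - tol)
        if best is None or red > best[0] + cross_tol:
            best = (red, j, thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


def oracle_fit_tree(y: np.ndarray, X: np.ndarray, min_terminal: int,
                    min_parent: int, max_depth: int,
                    min_improvement: float) -> dict:
    """Greedy exhaustive-search regression tree as a nested dict."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_root = len(y)
    var_root = float(np.var(y))
    cross_tol = TIE_RTOL * max(var_root * n_root, 1.0)

    def grow(idx: np.ndarray, depth: int) -> dict:
        node = {"n": len(idx), "mean": float(y[idx].mean()),
                "sse": sse(y[idx])}
        if depth >= max_depth or len(idx) < min_parent or node["sse"] == 0:
            return node
        res = oracle_best_split(y[idx], X[idx], min_terminal, cross_tol)
        if res is None:
            return node
        j, thr, red = res
        if red / n_root < min_improvement * var_root:
            return node
        node["split"] = (j, thr)
        left = idx[X[idx, j] <= thr]
        right = idx[X[idx, j] > thr]
        node["left"] = grow(left, depth + 1)
        node["right"] = grow(right, depth + 1)
        return node

    return grow(np.arange(n_root), 0)


def oracle_tree_risk(node: dict) -> float:
    """Sum of terminal SSEs of an oracle tree."""
    if "split" not in node:
        return node["sse"]
    return oracle_tree_risk(node["left"]) + oracle_tree_risk(node["right"])


def trees_equal(impl_node, oracle_node, atol=1e-8) -> bool:
    """Structural equality of an implementation Node vs an oracle dict."""
    if impl_node.n != oracle_node["n"]:
        return False
    impl_split = impl_node.split_var is not None
    oracle_split = "split" in oracle_node
    if impl_split != oracle_split:
        return False
    if not impl_split:
        return True
    j, thr = oracle_node["split"]
    if impl_node.split_var != f"x{j}" or abs(impl_node.threshold - thr) > atol:
        return False
    return (trees_equal(impl_node.left, oracle_node["left"], atol)
            and trees_equal(impl_node.right, oracle_node["right"], atol))


def enumerate_mwu_p(x1, x2) -> float:
    """Two-sided Mann-Whitney p by full enumeration of all labelings."""
    x1, x2 = list(map(float, x1)), list(map(float, x2))
    pooled = x1 + x2
    n1, n = len(x1), len(pooled)

    def u_of(group1):
        u = 0.0
        group2 = [i for i in range(n) if i not in group1]
        for i in group1:
            for k in group2:
                if pooled[i] > pooled[k]:
                    u += 1.0
                elif pooled[i] == pooled[k]:
                    u += 0.5
        return u

    u_obs = u_of(set(range(n1)))
    us = [u_of(set(c)) for c in combinations(range(n), n1)]
    p_le = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2 * min(p_le, p_ge))


def enumerate_signed_rank_p(d) -> float:
    """Two-sided exact Wilcoxon signed-rank p by 2^m sign enumeration."""
    from scipy.stats import rankdata
    d = np.asarray([v for v in d if v != 0], dtype=float)
    m = d.size
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in product([0, 1], repeat=m):
        ws.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    p_le = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
    p_ge = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_summaries(table, manifest):
    """Row-scan recomputation of per-sample summary variables.

    Returns a dict variable_id -> value computed with plain python loops
    over events (no vectorized paths shared with the implementation).
    """
    import statistics

    areas = table["Area_BF"].tolist()

    def stratum_of(a):
        if a < manifest.cutoff_small:
            return "small"
        if a > manifest.cutoff_large:
            return "large"
        return "medium"

    out = {}
    for feat in manifest.active_features:
        for ch in manifest.channels:
            col = feat.column_for(ch)
            vals = table[col].tolist()
            for stratum in ("small", "medium", "large", "total"):
                sub = [v for v, a in zip(vals, areas)
                       if stratum == "total" or stratum_of(a) == stratum]
                key = f"{feat.name}|{ch}|{stratum}|"
                out[key + "AVG"] = statistics.fmean(sub) if sub else math.nan
                out[key + "MED"] = statistics.median(sub) if sub else math.nan
                out[key + "SD"] = statistics.stdev(sub) if len(sub) >= 2 else math.nan
    return out
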