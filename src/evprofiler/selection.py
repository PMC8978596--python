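"""Two-level regression-tree feature selection.

For each summary statistic (AVG, MED, SD) the per-sample variables are split
by feature category (size, shape, texture, signal strength); one regression
tree per category is fitted with the CD-RISC score (or its change-score
analogue) as the continuous outcome; the splitter variables collected from
the four category trees feed a final tree for that statistic; the splitters
of the three final trees, pooled across statistics, form the candidate set
handed to the group-comparison stage.

``level1_scope`` controls what "identified at the first level" means: by
default every splitter of a category tree is forwarded (``all_splitters``);
``root_only`` forwards only each category tree's root split variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import CartConfig, RegressionTree, fit_tree
from .manifest import CATEGORIES, FeatureManifest, parse_variable_id

LEVEL1_SCOPES = ("all_splitters", "root_only")


@dataclass
class SelectionResult:
    """Per-statistic trees and the pooled candidate set."""

    level1: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # statistic -> category -> splitter ids
    final: dict[str, list[str]] = field(default_factory=dict)
    # statistic -> final-tree splitter ids
    candidates: list[str] = field(default_factory=list)
    normalized_risks: dict[str, float | None] = field(default_factory=dict)
    # "<statistic>/<category>" or "<statistic>/final" -> normalized risk
    trees: dict[str, RegressionTree] = field(default_factory=dict)
    n_excluded_missing: int = 0

    def to_dict(self, include_trees: bool = True) -> dict:
        d = {
            "level1": self.level1,
            "final": self.final,
            "candidates": self.candidates,
            "normalized_risks": self.normalized_risks,
            "n_excluded_missing": self.n_excluded_missing,
        }
        if include_trees:
            d["trees"] = {k: t.to_dict() for k, t in self.trees.items()}
        return d


def _ordered_union(lists) -> list[str]:
    seen: list[str] = []
    for lst in lists:
        for v in lst:
            if v not in seen:
                seen.append(v)
    return seen


def select_features(variables: pd.DataFrame, y, cfg: CartConfig | None = None,
                    manifest: FeatureManifest | None = None,
                    level1_scope: str = "all_splitters") -> SelectionResult:
    """Run the two-level selection workflow.

    ``variables`` is a subjects x variable-id frame (baseline values or
    change scores, one row per subject, aligned with ``y``).  Variables
    missing for any subject are excluded listwise (the trees have no
    surrogate splits).  Deterministic for a fixed column order.
    """
    if level1_scope not in LEVEL1_SCOPES:
        raise ValueError(f"level1_scope must be one of {LEVEL1_SCOPES}")
    cfg = cfg or CartConfig()
    manifest = manifest or FeatureManifest()
    y = np.asarray(y, dtype=float)
    if len(variables) != y.size:
        raise ValueError("variables and outcome are misaligned")

    complete = variables.loc[:, variables.notna().all(axis=0)]
    n_excluded = variables.shape[1] - complete.shape[1]
    if complete.shape[1] == 0:
        raise ValueError("no variables remain after missingness exclusion")

    parsed = {vid: parse_variable_id(vid) for vid in complete.columns}
    result = SelectionResult(n_excluded_missing=n_excluded)

    for stat in manifest.statistics:
        stat_cols = [v for v in complete.columns if parsed[v][3] == stat]
        level1_sel: dict[str, list[str]] = {}
        for category in CATEGORIES:
            cols = [v for v in stat_cols
                    if manifest.category_of(parsed[v][0]) == category]
            if not cols:
                level1_sel[category] = []
                continue
            tree = fit_tree(y, complete[cols], cfg)
            key = f"{stat}/{category}"
            result.trees[key] = tree
            result.normalized_risks[key] = tree.normalized_risk
            splitters = tree.splitter_variables()
            if level1_scope == "root_only":
                splitters = splitters[:1] if splitters else []
            level1_sel[category] = splitters
        result.level1[stat] = level1_sel

        pooled = _ordered_union(level1_sel.values())
        if pooled:
            final_tree = fit_tree(y, complete[pooled], cfg)
            key = f"{stat}/final"
            result.trees[key] = final_tree
            result.normalized_risks[key] = final_tree.normalized_risk
            result.final[stat] = final_tree.splitter_variables()
        else:
            result.final[stat] = []

    result.candidates = _ordered_union(result.final.values())
    return result
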