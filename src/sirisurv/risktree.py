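"""Clinic-facing risk tree on discretized variables.

After distillation, every continuous model variable is converted to a
small ordinal category (its interval between consecutive cutoffs, boundary
values going to the upper interval).  A shallow decision tree is then
grown on the categorical covariates by greedy two-sample log-rank
splitting over category subsets (exhaustive for the clinical cardinalities
involved), with a depth cap (default 3) and a minimum node size (default
40).  Finally, leaves are ordered by their mean forest mortality score and
adjacent leaves whose survival curves are statistically indistinguishable
are merged into ordered risk groups — Group 1 is the lowest risk.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distill import CutoffSet
from .errors import DomainError, InvalidConfigError
from .stats import SurvivalCurve, kaplan_meier, logrank_test

__all__ = [
    "RiskTreeConfig",
    "TreeNode",
    "RiskTree",
    "RiskGroupModel",
    "discretize",
    "grow_risk_tree",
    "merge_leaves",
    "assign_risk_group",
    "threshold_high_risk",
]


@dataclass(frozen=True)
class RiskTreeConfig:
    max_depth: int = 3
    min_node_size: int = 40
    merge_alpha: float = 0.05
    target_groups: int | None = None

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise InvalidConfigError("max_depth must be >= 1")
        if self.min_node_size < 2:
            raise InvalidConfigError("min_node_size must be >= 2")
        if not (0 < self.merge_alpha < 1):
            raise InvalidConfigError("merge_alpha must be in (0, 1)")


def discretize(cohort: pd.DataFrame, cutoffsets: list[CutoffSet],
               extra_categorical: list[str] = ()) -> pd.DataFrame:
    """Convert continuous variables to interval categories.

    Each value maps to the index of its interval among the variable's
    cutoffs; a value equal to a cutoff goes to the upper interval
    (left-closed convention).  Variables with an empty cutoff set pass
    through as a single category, with a warning.  Categorical columns in
    ``extra_categorical`` are copied unchanged.
    """
    out = pd.DataFrame(index=cohort.index)
    for cs in cutoffsets:
        if cs.variable not in cohort.columns:
            raise DomainError(f"cutoff set refers to missing variable {cs.variable!r}")
        values = cohort[cs.variable].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise DomainError(f"missing/non-finite value in variable {cs.variable!r}")
        if cs.is_empty:
            warnings.warn(f"variable {cs.variable!r} has no cutoffs; "
                          "it collapses to a single category")
            out[cs.variable] = 0
        else:
            out[cs.variable] = np.searchsorted(np.sort(cs.cutoffs), values, side="right")
    for col in extra_categorical:
        out[col] = cohort[col].to_numpy()
    return out


@dataclass
class TreeNode:
    depth: int
    indices: np.ndarray
    variable: str | None = None
    left_categories: frozenset | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    leaf_id: int | None = None
    statistic: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.leaf_id, "n": int(len(self.indices))}
        return {
            "variable": self.variable,
            "left_categories": sorted(map(str, self.left_categories)),
            "statistic": self.statistic,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_left: np.ndarray) -> float:
    """Two-sample log-rank chi-square, vectorized over event times."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], in_left[order]
    # risk sets just before each distinct event time
    uniq = np.unique(t[e == 1])
    n = len(t)
    # counts at risk: subjects with time >= u
    at_risk_total = n - np.searchsorted(t, uniq, side="left")
    csum_left = np.concatenate([[0], np.cumsum(g)])
    at_risk_left = g.sum() - csum_left[np.searchsorted(t, uniq, side="left")]
    # event counts at each distinct time
    ev_idx = np.searchsorted(uniq, t[e == 1])
    d_total = np.bincount(ev_idx, minlength=len(uniq)).astype(float)
    d_left = np.bincount(ev_idx, weights=g[e == 1], minlength=len(uniq)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = d_total * at_risk_left / at_risk_total
        var = (d_total * (at_risk_left / at_risk_total)
               * (1 - at_risk_left / at_risk_total)
               * (at_risk_total - d_total) / np.maximum(at_risk_total - 1, 1))
    o_minus_e = np.nansum(d_left - expected)
    v = np.nansum(var)
    if v <= 0:
        return 0.0
    return float(o_minus_e**2 / v)


def _candidate_subsets(categories: list) -> list[frozenset]:
    """Binary partitions of a category list: all subsets containing the
    first category, excluding the full set (2^(k-1) - 1 candidates)."""
    rest = categories[1:]
    subsets = []
    for r in range(len(rest)):
        for combo in itertools.combinations(rest, r):
            subsets.append(frozenset((categories[0],) + combo))
    return subsets


def grow_risk_tree(categorical: pd.DataFrame, times, events,
                   config: RiskTreeConfig | None = None) -> "RiskTree":
    """Greedy log-rank survival tree over categorical covariates."""
    config = config or RiskTreeConfig()
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() == 0:
        raise DomainError("cannot grow a risk tree with no events")
    for col in categorical.columns:
        if categorical[col].nunique() > 6:
            raise DomainError(f"variable {col!r} has more than 6 categories")
    data = {col: categorical[col].to_numpy() for col in categorical.columns}
    variables = list(categorical.columns)
    leaf_counter = itertools.count()

    def build(indices: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(depth=depth, indices=indices)
        if depth >= config.max_depth or len(indices) < 2 * config.min_node_size:
            node.leaf_id = next(leaf_counter)
            return node
        t, e = times[indices], events[indices]
        best = None  # (chi2, var, left_set, mask)
        for var in variables:
            vals = data[var][indices]
            cats = sorted(pd.unique(vals).tolist())
            if len(cats) < 2:
                continue
            for left_set in _candidate_subsets(cats):
                mask = np.isin(vals, list(left_set))
                n_left = int(mask.sum())
                if n_left < config.min_node_size or len(indices) - n_left < config.min_node_size:
                    continue
                chi2 = _logrank_chi2(t, e, mask.astype(float))
                key = (chi2, var, tuple(sorted(map(str, left_set))))
                if best is None or chi2 > best[0][0] + 1e-12:
                    best = (key, var, left_set, mask)
        if best is None or best[0][0] <= 0:
            node.leaf_id = next(leaf_counter)
            return node
        _, var, left_set, mask = best
        node.variable = var
        node.left_categories = left_set
        node.statistic = best[0][0]
        node.left = build(indices[mask], depth + 1)
        node.right = build(indices[~mask], depth + 1)
        return node

    root = build(np.arange(len(times)), 0)
    return RiskTree(root=root, variables=variables, config=config)


@dataclass
class RiskTree:
    root: TreeNode
    variables: list[str]
    config: RiskTreeConfig

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def route(self, row: pd.Series | dict) -> int:
        """Return the leaf id a subject routes to."""
        node = self.root
        while not node.is_leaf:
            if node.variable not in row:
                raise DomainError(f"missing tree variable {node.variable!r}")
            value = row[node.variable]
            node = node.left if value in node.left_categories else node.right
        return node.leaf_id

    def route_frame(self, categorical: pd.DataFrame) -> np.ndarray:
        return np.asarray([self.route(row) for _, row in categorical.iterrows()])

    def rules(self) -> dict[int, str]:
        """One human-readable rule string per leaf."""
        out: dict[int, str] = {}

        def walk(node: TreeNode, path: list[str]) -> None:
            if node.is_leaf:
                out[node.leaf_id] = " and ".join(path) if path else "(all subjects)"
                return
            cats = "{" + ", ".join(sorted(map(str, node.left_categories))) + "}"
            walk(node.left, path + [f"{node.variable} in {cats}"])
            walk(node.right, path + [f"{node.variable} not in {cats}"])

        walk(self.root, [])
        return out


@dataclass
class RiskGroupModel:
    """The final ordered risk grouping: tree + leaf -> group mapping."""

    tree: RiskTree
    leaf_to_group: dict[int, int]          # group indices 1..G, 1 = lowest risk
    group_mean_scores: dict[int, float]
    group_curves: dict[int, SurvivalCurve] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.leaf_to_group.values()))

    def rules(self) -> list[str]:
        leaf_rules = self.tree.rules()
        return [f"{leaf_rules[leaf]} -> Group {group}"
                for leaf, group in sorted(self.leaf_to_group.items())]

    def to_json(self) -> str:
        return json.dumps({
            "tree": self.tree.root.to_dict(),
            "variables": self.tree.variables,
            "leaf_to_group": {str(k): v for k, v in self.leaf_to_group.items()},
            "group_mean_scores": {str(k): v for k, v in self.group_mean_scores.items()},
            "rules": self.rules(),
        }, indent=2)


def merge_leaves(tree: RiskTree, times, events, mortality_scores,
                 alpha: float = 0.05, target_groups: int | None = None) -> RiskGroupModel:
    """Merge statistically indistinguishable leaves into ordered groups.

    Leaves are ordered by their training-set mean mortality score; the
    adjacent pair with the largest pairwise log-rank p-value is merged
    while that p-value exceeds ``alpha`` (or until ``target_groups``
    remain).  Requires at least 2 leaves to do anything useful.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    scores = np.asarray(mortality_scores, dtype=float)
    leaves = tree.leaves()
    order = np.argsort([scores[leaf.indices].mean() for leaf in leaves], kind="stable")
    groups: list[list[TreeNode]] = [[leaves[i]] for i in order]

    def group_members(group: list[TreeNode]) -> np.ndarray:
        return np.concatenate([leaf.indices for leaf in group])

    def adjacent_p(a: list[TreeNode], b: list[TreeNode]) -> float:
        ia, ib = group_members(a), group_members(b)
        idx = np.concatenate([ia, ib])
        labels = np.concatenate([np.zeros(len(ia)), np.ones(len(ib))])
        ev = events[idx]
        if ev.sum() == 0:
            return 1.0
        return logrank_test(times[idx], ev, labels).p_value

    while len(groups) > 1:
        pvals = [adjacent_p(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]
        i_max = int(np.argmax(pvals))
        if target_groups is not None:
            if len(groups) <= target_groups:
                break
        elif pvals[i_max] <= alpha:
            break
        groups[i_max] = groups[i_max] + groups.pop(i_max + 1)

    leaf_to_group: dict[int, int] = {}
    group_mean_scores: dict[int, float] = {}
    group_curves: dict[int, SurvivalCurve] = {}
    for g, group in enumerate(groups, start=1):
        idx = group_members(group)
        for leaf in group:
            leaf_to_group[leaf.leaf_id] = g
        group_mean_scores[g] = float(scores[idx].mean())
        group_curves[g] = kaplan_meier(times[idx], events[idx])
    return RiskGroupModel(tree=tree, leaf_to_group=leaf_to_group,
                          group_mean_scores=group_mean_scores, group_curves=group_curves)


def assign_risk_group(model: RiskGroupModel, categorical: pd.DataFrame | pd.Series | dict
                      ) -> np.ndarray | int:
    """Deterministic leaf routing followed by the leaf -> group mapping."""
    if isinstance(categorical, (pd.Series, dict)):
        return model.leaf_to_group[model.tree.route(categorical)]
    leaf_ids = model.tree.route_frame(categorical)
    return np.asarray([model.leaf_to_group[l] for l in leaf_ids])


def threshold_high_risk(scores, quantile: float = 0.75,
                        reference_scores=None) -> np.ndarray:
    """Binary high/low risk labels from a quantile of the training scores.

    The cutoff is the linear-interpolation empirical quantile of the
    reference (training) scores; a subject is high-risk iff its score is
    strictly greater than the cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    ref = scores if reference_scores is None else np.asarray(reference_scores, dtype=float)
    if len(ref) < 4:
        raise DomainError("need at least 4 reference scores")
    if np.ptp(ref) == 0:
        raise DomainError("all scores tied; no stratification possible")
    cutoff = float(np.quantile(ref, quantile, method="linear"))
    return scores > cutoff
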