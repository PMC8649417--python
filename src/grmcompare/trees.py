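"""Shallow regression trees over expanded summary tables.

Binary recursive partitioning on categorical design features minimizing
mean squared error, with a depth cap of four splits, a zero complexity
threshold (any strictly improving split is accepted), and conventional
minimum node sizes.  Every node is annotated with its outcome mean so
the rendered tree doubles as a condensed results table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .simulate import CONDITION_LEVELS

#: Default predictor declaration order: the seven design features, then
#: the analysis method, then the prescreening flag.
DEFAULT_FEATURES = [
    (name, levels)
    for name, levels in CONDITION_LEVELS.items()
    if name != "true_focal_mean"
] + [
    ("true_focal_mean", (0.0, 0.5)),
    ("method", ("sum_score", "irt_model", "irt_eap")),
    ("prescreened", (False, True)),
]

MAX_DEPTH = 4
MIN_SPLIT = 20
MIN_LEAF = 7


@dataclass
class TreeNode:
    """A split (or leaf) with its outcome mean and case count."""

    mean: float
    n: int
    depth: int
    feature: str | None = None
    left_levels: tuple = ()
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"mean": self.mean, "n": self.n, "depth": self.depth}
        if not self.is_leaf:
            d["feature"] = self.feature
            d["left_levels"] = list(self.left_levels)
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


def _sse(y) -> float:
    return float(((y - y.mean()) ** 2).sum()) if len(y) else 0.0


def _best_split(df, outcome, features, min_leaf):
    """Exhaustive best binary partition; deterministic tie-breaking by
    feature declaration order then level-subset enumeration order."""
    y = df[outcome]
    best = None  # (sse, feature, left_levels, mask)
    for fname, levels in features:
        if fname not in df.columns:
            continue
        vals = df[fname]
        present = [lv for lv in levels if (vals == lv).any()]
        if len(present) < 2:
            continue
        rest = present[1:]
        for bits in range(2 ** len(rest)):
            left_levels = [present[0]] + [
                lv for i, lv in enumerate(rest) if bits & (1 << i)
            ]
            if len(left_levels) == len(present):
                continue
            mask = vals.isin(left_levels)
            nl = int(mask.sum())
            if nl < min_leaf or len(df) - nl < min_leaf:
                continue
            sse = _sse(y[mask]) + _sse(y[~mask])
            if best is None or sse < best[0] - 1e-12:
                best = (sse, fname, tuple(left_levels), mask)
    return best


def fit_tree(
    table: pd.DataFrame,
    outcome: str,
    features: list | None = None,
    max_depth: int = MAX_DEPTH,
    min_split: int = MIN_SPLIT,
    min_leaf: int = MIN_LEAF,
) -> TreeNode:
    """Fit a regression tree to a summary table.

    ``features`` is a list of (name, ordered levels); defaults to the
    design features plus method and prescreening.  A constant outcome
    yields a single leaf.
    """
    features = DEFAULT_FEATURES if features is None else features

    def grow(df, depth):
        node = TreeNode(mean=float(df[outcome].mean()), n=len(df), depth=depth)
        if depth >= max_depth or len(df) < min_split:
            return node
        best = _best_split(df, outcome, features, min_leaf)
        if best is None:
            return node
        sse, fname, left_levels, mask = best
        if _sse(df[outcome]) - sse <= 1e-12:  # zero improvement: stop
            return node
        node.feature = fname
        node.left_levels = left_levels
        node.left = grow(df[mask], depth + 1)
        node.right = grow(df[~mask], depth + 1)
        return node

    return grow(table.reset_index(drop=True), 0)


def render_tree(root: TreeNode, digits: int = 4) -> str:
    """Deterministic indented text rendering with node means."""
    lines = []

    def fmt_levels(levels):
        return "{" + ", ".join(str(lv) for lv in levels) + "}"

    def walk(node, prefix, label):
        lines.append(f"{prefix}{label}mean={node.mean:.{digits}f} n={node.n}")
        if not node.is_leaf:
            walk(node.left, prefix + "  ",
                 f"[{node.feature} in {fmt_levels(node.left_levels)}] ")
            walk(node.right, prefix + "  ",
                 f"[{node.feature} not in {fmt_levels(node.left_levels)}] ")

    walk(root, "", "")
    return "\n".join(lines)


def tree_to_json(root: TreeNode, path=None) -> str:
    """Structured JSON export (nodes, splits, means)."""
    text = json.dumps(root.to_dict(), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
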