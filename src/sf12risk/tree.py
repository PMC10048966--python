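"""CART risk stratification with a-priori / a-posteriori risk reporting.

The fitted tree is re-expressed as a :class:`RiskTree` whose nodes carry
exact integer counts (samples reaching the node and positive samples among
them), so that node risks are exact proportions, risk deltas against the
parent are well-defined, and conservation (counts of children summing to
the parent) can be checked exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "TreeConfig",
    "RiskTreeNode",
    "RiskTree",
    "fit_risk_tree",
    "path_risk_report",
    "check_conservation",
    "render_tree",
]


@dataclass
class TreeConfig:
    """Risk-tree settings: impurity, depth cap, min-leaf, feature list."""

    features: Sequence[str]
    criterion: str = "gini"
    max_depth: int = 3
    min_leaf_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be ≥ 1")
        if not self.features:
            raise ValueError("feature list must be non-empty")
        if not (0.0 < self.min_leaf_frac < 0.5):
            raise ValueError("min_leaf_frac must be in (0, 0.5)")


@dataclass
class RiskTreeNode:
    """One node: split rule (or leaf), exact counts, and derived risk."""

    node_id: int
    n: int
    n_pos: int
    feature: str | None = None       # None for leaves
    threshold: float | None = None   # left child: feature <= threshold
    left: "RiskTreeNode | None" = None
    right: "RiskTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    @property
    def risk(self) -> float:
        return self.n_pos / self.n

    @property
    def risk_pct(self) -> float:
        return round(100.0 * self.risk, 2)

    def rule(self, branch: str) -> str:
        if self.feature is None:
            return ""
        op = "<=" if branch == "left" else ">"
        return f"{self.feature} {op} {self.threshold:g}"

    def to_dict(self) -> dict:
        out = {"node_id": self.node_id, "n": self.n, "n_pos": self.n_pos}
        if not self.is_leaf:
            out["feature"] = self.feature
            out["threshold"] = self.threshold
            out["left"] = self.left.to_dict()
            out["right"] = self.right.to_dict()
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "RiskTreeNode":
        node = cls(
            node_id=payload["node_id"],
            n=payload["n"],
            n_pos=payload["n_pos"],
            feature=payload.get("feature"),
            threshold=payload.get("threshold"),
        )
        if "left" in payload:
            node.left = cls.from_dict(payload["left"])
            node.right = cls.from_dict(payload["right"])
        return node


@dataclass
class RiskTree:
    """A fitted risk tree plus its configuration snapshot."""

    root: RiskTreeNode
    feature_names: list[str]
    config: dict = field(default_factory=dict)

    def walk(self) -> Iterator[tuple[RiskTreeNode, RiskTreeNode | None, list[str]]]:
        """Yield (node, parent, condition chain) in pre-order."""
        stack = [(self.root, None, [])]
        while stack:
            node, parent, conds = stack.pop(0)
            yield node, parent, conds
            if not node.is_leaf:
                stack.append((node.left, node, conds + [node.rule("left")]))
                stack.append((node.right, node, conds + [node.rule("right")]))

    @property
    def a_priori_risk(self) -> float:
        return self.root.risk

    def depth(self) -> int:
        def _d(node: RiskTreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def split_features_by_depth(self) -> dict[int, list[str]]:
        """Split features used at each depth (root = depth 0)."""
        out: dict[int, list[str]] = {}
        def _collect(node: RiskTreeNode, depth: int) -> None:
            if node.is_leaf:
                return
            out.setdefault(depth, []).append(node.feature)
            _collect(node.left, depth + 1)
            _collect(node.right, depth + 1)
        _collect(self.root, 0)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "feature_names": self.feature_names,
            "config": self.config,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "RiskTree":
        return cls(
            root=RiskTreeNode.from_dict(payload["root"]),
            feature_names=list(payload["feature_names"]),
            config=payload.get("config", {}),
        )

    @classmethod
    def from_json(cls, source) -> "RiskTree":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_risk_tree(data, labels, cfg: TreeConfig) -> RiskTree:
    """Fit a CART on the selected raw features and annotate exact risks.

    ``data`` is a DataFrame (or array with cfg.features giving column
    order); splits are on raw feature scales.  Single-class data produce a
    root-only tree with a warning.  The fit is deterministic given (data,
    cfg).
    """
    if isinstance(data, pd.DataFrame):
        missing = [f for f in cfg.features if f not in data.columns]
        if missing:
            raise ValueError(f"selected feature(s) missing from data: {missing}")
        X = data[list(cfg.features)].to_numpy(float)
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != len(cfg.features):
            raise ValueError("array width must match cfg.features")
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("data and labels disagree on n")
    n = len(y)
    n_pos_total = int(y.sum())
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: returning a root-only tree", stacklevel=2)
        root = RiskTreeNode(node_id=0, n=n, n_pos=n_pos_total)
        return RiskTree(root=root, feature_names=list(cfg.features), config=_cfg_dict(cfg))
    clf = DecisionTreeClassifier(
        criterion=cfg.criterion,
        max_depth=cfg.max_depth,
        min_samples_leaf=max(1, math.ceil(cfg.min_leaf_frac * n)),
        random_state=cfg.seed,
    )
    clf.fit(X, y)
    t = clf.tree_
    # sklearn stores per-node class counts in tree_.value scaled to
    # probabilities in recent versions; recover exact counts from the
    # training data by routing samples through the tree.
    node_indicator = clf.decision_path(X)
    counts = np.asarray(node_indicator.sum(axis=0)).ravel().astype(int)
    pos_counts = np.asarray(node_indicator[y == 1].sum(axis=0)).ravel().astype(int)

    def build(idx: int) -> RiskTreeNode:
        node = RiskTreeNode(node_id=int(idx), n=int(counts[idx]), n_pos=int(pos_counts[idx]))
        if t.children_left[idx] != -1:
            node.feature = cfg.features[int(t.feature[idx])]
            node.threshold = float(t.threshold[idx])
            node.left = build(t.children_left[idx])
            node.right = build(t.children_right[idx])
        return node

    return RiskTree(root=build(0), feature_names=list(cfg.features), config=_cfg_dict(cfg))


def _cfg_dict(cfg: TreeConfig) -> dict:
    return {
        "features": list(cfg.features),
        "criterion": cfg.criterion,
        "max_depth": cfg.max_depth,
        "min_leaf_frac": cfg.min_leaf_frac,
        "seed": cfg.seed,
    }


# ---------------------------------------------------------------------------
# Reporting and checks
# ---------------------------------------------------------------------------


def path_risk_report(tree: RiskTree) -> pd.DataFrame:
    """Per-node report: condition chain, n, risk %, signed delta vs parent.

    The root's delta is blank (it is the a-priori risk).  Risks and deltas
    are percentages rounded to two decimals; the highest-risk leaf is
    flagged.
    """
    rows = []
    for node, parent, conds in tree.walk():
        delta = (
            None
            if parent is None
            else round(100.0 * (node.risk - parent.risk), 2)
        )
        rows.append(
            {
                "node_id": node.node_id,
                "condition": " AND ".join(conds) if conds else "(a priori)",
                "n": node.n,
                "risk_pct": node.risk_pct,
                "delta_pct": delta,
                "is_leaf": node.is_leaf,
            }
        )
    df = pd.DataFrame(rows)
    leaf_mask = df["is_leaf"]
    max_leaf_risk = df.loc[leaf_mask, "risk_pct"].max()
    df["highest_risk_leaf"] = leaf_mask & (df["risk_pct"] == max_leaf_risk)
    return df


def check_conservation(tree: RiskTree) -> tuple[bool, list[int]]:
    """Verify exact count conservation at every internal node.

    Checks n(parent) = n(left) + n(right) and the same for positive counts
    (which implies risk(parent) = Σ risk(child)·n(child)/n(parent) exactly).
    Returns (pass, offending node ids).
    """
    bad: list[int] = []
    for node, _, _ in tree.walk():
        if node.is_leaf:
            continue
        if node.left.n + node.right.n != node.n:
            bad.append(node.node_id)
        elif node.left.n_pos + node.right.n_pos != node.n_pos:
            bad.append(node.node_id)
    return (len(bad) == 0, bad)


def render_tree(tree: RiskTree, fmt: str = "text") -> str:
    """Render as an indented text outline or a DOT graph.

    Node labels carry "condition | n | risk% | Δ"; rendering is
    deterministic (same tree ⇒ byte-identical output).
    """
    if fmt == "text":
        return _render_text(tree)
    if fmt == "dot":
        return _render_dot(tree)
    raise ValueError(f"unknown format {fmt!r}; use 'text' or 'dot'")


def _node_label(node: RiskTreeNode, parent: RiskTreeNode | None, cond: str) -> str:
    delta = "" if parent is None else f" | Δ {100.0 * (node.risk - parent.risk):+.2f}"
    cond = cond or "a priori"
    return f"{cond} | n={node.n} | risk {node.risk_pct:.2f}%{delta}"


def _render_text(tree: RiskTree) -> str:
    lines: list[str] = []

    def visit(node: RiskTreeNode, parent: RiskTreeNode | None, cond: str, depth: int):
        lines.append("  " * depth + _node_label(node, parent, cond))
        if not node.is_leaf:
            visit(node.left, node, node.rule("left"), depth + 1)
            visit(node.right, node, node.rule("right"), depth + 1)

    visit(tree.root, None, "", 0)
    return "\n".join(lines) + "\n"


def _render_dot(tree: RiskTree) -> str:
    lines = ["digraph risk_tree {", '  node [shape=box, fontname="Helvetica"];']
    edges: list[str] = []

    def visit(node: RiskTreeNode, parent: RiskTreeNode | None, cond: str):
        label = _node_label(node, parent, cond).replace('"', r"\"")
        lines.append(f'  n{node.node_id} [label="{label}"];')
        if parent is not None:
            edges.append(f"  n{parent.node_id} -> n{node.node_id};")
        if not node.is_leaf:
            visit(node.left, node, node.rule("left"))
            visit(node.right, node, node.rule("right"))

    visit(tree.root, None, "")
    return "\n".join(lines + edges + ["}"]) + "\n"
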