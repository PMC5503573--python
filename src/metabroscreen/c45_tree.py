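"""Gain-ratio decision-tree induction on continuous ion intensities.

This follows the C4.5 conventions for continuous attributes: binary splits at
midpoints between consecutive observed values, split selection by gain ratio
among candidates whose information gain reaches the mean gain of all
candidate splits, and optional bottom-up subtree-replacement pruning using
the upper confidence bound of the binomial leaf error rate (the J48
convention, default confidence 0.25).

Classes are the strings "case" and "control"; leaf ties predict "case",
favouring sensitivity.  Missing-value fractional routing is not implemented:
the screening stage guarantees candidates are detected in most samples and
zeros are treated as literal intensities.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .feature_io import CASE, CONTROL, IonID

__all__ = [
    "TreeConfig",
    "TreeNode",
    "entropy",
    "gain_ratio",
    "best_split",
    "build_tree",
    "predict",
    "predict_matrix",
    "to_text",
    "parse_text",
    "tree_to_json",
    "tree_from_json",
    "tree_size",
]

CLASSES = (CASE, CONTROL)


@dataclass(frozen=True)
class TreeConfig:
    """Induction settings mirroring the common J48 defaults."""

    min_leaf: int = 2
    prune: bool = True
    prune_confidence: float = 0.25

    def validate(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be at least 1")
        if not 0 < self.prune_confidence <= 0.5:
            raise ValueError("prune_confidence must be in (0, 0.5]")


@dataclass
class TreeNode:
    """Internal node (ion + threshold, <= goes left) or leaf (class + counts)."""

    kind: str  # "internal" | "leaf"
    split_ion: str | None = None       # canonical ion label
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    predicted_class: str | None = None
    class_counts: tuple[int, int] | None = None  # (case, control) routed here

    def is_leaf(self) -> bool:
        return self.kind == "leaf"


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits of a class-count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def gain_ratio(
    parent_counts: Sequence[float], child_counts_list: Sequence[Sequence[float]]
) -> float:
    """Information gain over split information; 0 when the split info is 0."""
    parent = np.asarray(parent_counts, dtype=float)
    total = parent.sum()
    children = [np.asarray(c, dtype=float) for c in child_counts_list]
    if np.any(parent < 0) or any(np.any(c < 0) for c in children):
        raise ValueError("class counts must be nonnegative")
    if not np.allclose(sum(children), parent):
        raise ValueError("children counts must sum to the parent counts")
    gain = entropy(parent)
    split_info = 0.0
    for c in children:
        frac = c.sum() / total
        gain -= frac * entropy(c)
        if frac > 0:
            split_info -= frac * math.log2(frac)
    if split_info == 0:
        return 0.0
    return gain / split_info


def _info_gain(parent_h: float, total: int, left: np.ndarray, right: np.ndarray) -> float:
    nl, nr = left.sum(), right.sum()
    return parent_h - (nl / total) * entropy(left) - (nr / total) * entropy(right)


def best_split(
    values: Sequence[float],
    labels: Sequence[str],
    cfg: TreeConfig | None = None,
) -> tuple[float, float] | None:
    """Best midpoint threshold for one continuous attribute.

    Evaluates every midpoint between consecutive distinct sorted values whose
    branches both hold at least ``min_leaf`` samples; among splits with
    information gain at least the mean gain of all candidates, returns the
    one maximising gain ratio (ties towards the smaller threshold), or None
    when no admissible split exists.
    """
    cfg = cfg or TreeConfig()
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    total = v.size
    is_case = (y == CASE).astype(int)
    parent = np.array([is_case.sum(), total - is_case.sum()])
    if parent.min() == 0 or total < 2 * cfg.min_leaf:
        return None
    parent_h = entropy(parent)

    cum_case = np.cumsum(is_case)
    cum_all = np.arange(1, total + 1)
    candidates: list[tuple[float, float, float]] = []  # (threshold, gain, ratio)
    for i in range(total - 1):
        if v[i] == v[i + 1]:
            continue
        nl = cum_all[i]
        nr = total - nl
        if nl < cfg.min_leaf or nr < cfg.min_leaf:
            continue
        left = np.array([cum_case[i], nl - cum_case[i]])
        right = parent - left
        gain = _info_gain(parent_h, total, left, right)
        ratio = gain_ratio(parent, [left, right])
        thr = (v[i] + v[i + 1]) / 2.0
        candidates.append((thr, gain, ratio))
    if not candidates:
        return None
    mean_gain = sum(c[1] for c in candidates) / len(candidates)
    # C4.5 gain-ratio guard: only splits with at least average gain compete
    admissible = [c for c in candidates if c[1] >= mean_gain - 1e-12]
    if not admissible:
        return None
    best = max(admissible, key=lambda c: (c[2], -c[0]))
    if best[1] <= 0:
        return None
    return best[0], best[2]


def _counts(labels: np.ndarray) -> tuple[int, int]:
    return int((labels == CASE).sum()), int((labels == CONTROL).sum())


def _majority(counts: tuple[int, int]) -> str:
    # tie predicts case, favouring sensitivity
    return CASE if counts[0] >= counts[1] else CONTROL


def _grow(
    X: np.ndarray, y: np.ndarray, ion_labels: list[str], cfg: TreeConfig
) -> TreeNode:
    counts = _counts(y)
    if min(counts) == 0 or y.size < 2 * cfg.min_leaf:
        return TreeNode(kind="leaf", predicted_class=_majority(counts),
                        class_counts=counts)
    best: tuple[int, float, float] | None = None  # (feature, threshold, ratio)
    for f in range(X.shape[1]):
        res = best_split(X[:, f], y, cfg)
        if res is None:
            continue
        thr, ratio = res
        if best is None or ratio > best[2] + 1e-12:
            best = (f, thr, ratio)
    if best is None:
        return TreeNode(kind="leaf", predicted_class=_majority(counts),
                        class_counts=counts)
    f, thr, _ = best
    mask = X[:, f] <= thr
    return TreeNode(
        kind="internal",
        split_ion=ion_labels[f],
        threshold=thr,
        left=_grow(X[mask], y[mask], ion_labels, cfg),
        right=_grow(X[~mask], y[~mask], ion_labels, cfg),
        class_counts=counts,
    )


def _added_errors(n: float, e: float, cf: float) -> float:
    """C4.5 pessimistic extra errors for a leaf with n samples and e errors."""
    if n == 0:
        return 0.0
    if e < 1e-9:
        return n * (1.0 - cf ** (1.0 / n))
    if e < 1:
        base = n * (1.0 - cf ** (1.0 / n))
        return base + e * (_added_errors(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = float(norm.ppf(1.0 - cf))
    f = (e + 0.5) / n
    upper = (f + z * z / (2 * n) + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return upper * n - e


def _leaf_pessimistic(counts: tuple[int, int], cf: float) -> float:
    n = counts[0] + counts[1]
    e = n - max(counts)
    return e + _added_errors(n, e, cf)


def _prune(node: TreeNode, cf: float) -> TreeNode:
    if node.is_leaf():
        return node
    node.left = _prune(node.left, cf)
    node.right = _prune(node.right, cf)
    subtree_err = _subtree_pessimistic(node, cf)
    leaf_err = _leaf_pessimistic(node.class_counts, cf)
    if leaf_err <= subtree_err + 0.1:
        return TreeNode(
            kind="leaf",
            predicted_class=_majority(node.class_counts),
            class_counts=node.class_counts,
        )
    return node


def _subtree_pessimistic(node: TreeNode, cf: float) -> float:
    if node.is_leaf():
        return _leaf_pessimistic(node.class_counts, cf)
    return _subtree_pessimistic(node.left, cf) + _subtree_pessimistic(node.right, cf)


def build_tree(
    X: np.ndarray,
    labels: Sequence[str],
    ions: Sequence[IonID | str],
    cfg: TreeConfig | None = None,
) -> TreeNode:
    """Induce a decision tree on candidate-ion intensities.

    ``X`` is (n_samples, n_candidates); ``labels`` are "case"/"control";
    ``ions`` name the columns.  Growth stops on purity, ``min_leaf``, or when
    no admissible split remains; pruning (if enabled) replaces subtrees whose
    pessimistic error is no better than predicting the majority class.
    """
    cfg = cfg or TreeConfig()
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.size == 0 or y.size == 0:
        raise ValueError("empty training data")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes in the training data")
    ion_labels = [i.label if isinstance(i, IonID) else str(i) for i in ions]
    if len(ion_labels) != X.shape[1]:
        raise ValueError("number of ion labels must match columns of X")
    tree = _grow(X, y, ion_labels, cfg)
    if cfg.prune:
        tree = _prune(tree, cfg.prune_confidence)
    return tree


def predict(tree: TreeNode, intensities: Mapping[str, float]) -> str:
    """Route a sample (ion label -> intensity) to a leaf class."""
    node = tree
    while not node.is_leaf():
        if node.split_ion not in intensities:
            raise KeyError(f"sample is missing ion {node.split_ion!r}")
        v = intensities[node.split_ion]
        node = node.left if v <= node.threshold else node.right
    return node.predicted_class


def predict_matrix(
    tree: TreeNode, X: np.ndarray, ions: Sequence[IonID | str]
) -> np.ndarray:
    ion_labels = [i.label if isinstance(i, IonID) else str(i) for i in ions]
    X = np.asarray(X, dtype=float)
    return np.array(
        [predict(tree, dict(zip(ion_labels, row))) for row in X], dtype=object
    )


def tree_size(tree: TreeNode) -> int:
    """Total number of nodes."""
    if tree.is_leaf():
        return 1
    return 1 + tree_size(tree.left) + tree_size(tree.right)


def to_text(tree: TreeNode) -> str:
    """J48-style indented rule listing; round-trips through :func:`parse_text`."""
    lines: list[str] = []

    def emit(node: TreeNode, depth: int) -> None:
        prefix = "|   " * depth
        if node.is_leaf():
            n = sum(node.class_counts)
            err = n - max(node.class_counts)
            lines.append(f"{prefix}: {node.predicted_class} ({n}/{err})")
            return
        thr = repr(float(node.threshold))
        lines.append(f"{prefix}{node.split_ion} <= {thr}")
        emit(node.left, depth + 1)
        lines.append(f"{prefix}{node.split_ion} > {thr}")
        emit(node.right, depth + 1)

    emit(tree, 0)
    return "\n".join(lines) + "\n"


_LEAF_RE = re.compile(r"^: (\w+) \((\d+)/(\d+)\)$")
_SPLIT_RE = re.compile(r"^(.+) (<=|>) ([-+0-9.e]+)$")


def parse_text(text: str) -> TreeNode:
    """Parse the :func:`to_text` listing back into an equivalent tree."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    pos = 0

    def depth_of(line: str) -> int:
        d = 0
        while line.startswith("|   "):
            d += 1
            line = line[4:]
        return d

    def strip(line: str) -> str:
        return line[4 * depth_of(line):]

    def parse_node(depth: int) -> TreeNode:
        nonlocal pos
        line = strip(lines[pos])
        m = _LEAF_RE.match(line)
        if m:
            pos += 1
            cls, n, err = m.group(1), int(m.group(2)), int(m.group(3))
            counts = (n - err, err) if cls == CASE else (err, n - err)
            return TreeNode(kind="leaf", predicted_class=cls, class_counts=counts)
        m = _SPLIT_RE.match(line)
        if m is None or m.group(2) != "<=":
            raise ValueError(f"cannot parse tree line: {line!r}")
        ion, thr = m.group(1), float(m.group(3))
        pos += 1
        left = parse_node(depth + 1)
        # the matching "> thr" line
        line2 = strip(lines[pos])
        m2 = _SPLIT_RE.match(line2)
        if m2 is None or m2.group(2) != ">":
            raise ValueError(f"expected '>' branch, got: {line2!r}")
        pos += 1
        right = parse_node(depth + 1)
        return TreeNode(kind="internal", split_ion=ion, threshold=thr,
                        left=left, right=right)

    return parse_node(0)


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf():
        return {
            "kind": "leaf",
            "predicted_class": node.predicted_class,
            "class_counts": list(node.class_counts),
        }
    return {
        "kind": "internal",
        "split_ion": node.split_ion,
        "threshold": node.threshold,
        "class_counts": list(node.class_counts) if node.class_counts else None,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if d["kind"] == "leaf":
        return TreeNode(
            kind="leaf",
            predicted_class=d["predicted_class"],
            class_counts=tuple(d["class_counts"]),
        )
    return TreeNode(
        kind="internal",
        split_ion=d["split_ion"],
        threshold=d["threshold"],
        class_counts=tuple(d["class_counts"]) if d.get("class_counts") else None,
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def tree_to_json(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_node_to_dict(tree), indent=2, sort_keys=True) + "\n")


def tree_from_json(path: str | Path) -> TreeNode:
    return _node_from_dict(json.loads(Path(path).read_text()))
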