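"""Decision-tree phenotype classification on the variant matrix.

A deliberately transparent CART implementation: greedy growth minimizing
weighted child Gini impurity over per-variant dosage thresholds (0.5 for
binary matrices, {0.5, 1.5} for ternary), ties broken by lowest row index
then lower threshold so that a given matrix, label set, depth and seed
always produce the same tree. Nodes carry the Gini score and per-class
sample counts ("value") that clinical decision-tree figures report.

The companion operations implement the single stratified 2/3 train, 1/3
test protocol; masking removes designated rows (e.g. known disease-causing
mutations) so the tree must classify from the residual genetic background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_matrix import GenotypeMatrix, VariantKey

__all__ = [
    "TreeNode",
    "TreeModel",
    "ClassificationReport",
    "gini_impurity",
    "split_train_test",
    "train_tree",
    "mask_variants",
    "classification_report",
    "export_tree_rules",
]


def gini_impurity(counts: Sequence[int]) -> float:
    """Gini impurity ``1 − Σ (c/total)²`` of per-class sample counts.

    Zero means the node is pure (one class only).
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 0):
        raise ValueError(f"counts must be non-negative, got {counts}")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero counts: impurity undefined")
    p = c / total
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """One node of a fitted tree.

    Internal nodes carry the splitting variant and dosage threshold
    (samples with dosage ≤ threshold go left); leaves carry only the
    majority class. ``value`` is the per-class sample count in the
    training data reaching the node.
    """

    gini: float
    value: np.ndarray
    predicted_class: object
    split_variant: VariantKey | None = None
    threshold: float | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    row_index: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class TreeModel:
    """Fitted decision tree over the variants of a genotype matrix."""

    root: TreeNode
    classes: list
    variants: list[VariantKey]
    mode: str
    max_depth: int

    def predict_values(self, values: np.ndarray) -> list:
        """Predict class labels for a variants × samples dosage array."""
        if values.shape[0] != len(self.variants):
            raise ValueError("feature rows do not match the training variants")
        out = []
        for j in range(values.shape[1]):
            node = self.root
            while not node.is_leaf:
                left, right = node.children
                node = left if values[node.row_index, j] <= node.threshold else right
            out.append(node.predicted_class)
        return out

    def predict(self, matrix: GenotypeMatrix) -> dict[str, object]:
        idx = [matrix.index_of(v) for v in self.variants]
        preds = self.predict_values(matrix.values[idx, :])
        return dict(zip(matrix.samples, preds))

    @property
    def splitting_variants(self) -> list[VariantKey]:
        """Distinct splitting variants in depth-first order."""
        seen: list[VariantKey] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if node.split_variant not in seen:
                seen.append(node.split_variant)
            walk(node.children[0])
            walk(node.children[1])

        walk(self.root)
        return seen

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else sum(count(c) for c in node.children)
        return count(self.root)

    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {
                "gini": node.gini,
                "value": [int(v) for v in node.value],
                "class": str(node.predicted_class),
            }
            if not node.is_leaf:
                d["variant"] = node.split_variant.label
                d["threshold"] = node.threshold
                d["children"] = [node_dict(c) for c in node.children]
            return d
        return {
            "classes": [str(c) for c in self.classes],
            "mode": self.mode,
            "max_depth": self.max_depth,
            "root": node_dict(self.root),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1/support plus accuracy and confusion.

    Precision = TP / (TP + FP), recall = TP / (TP + FN),
    F1 = 2·(precision·recall)/(precision + recall); precision of a class
    never predicted is reported as 0 and listed in ``zero_division``.
    """

    classes: list
    precision: dict
    recall: dict
    f1: dict
    support: dict
    accuracy: float
    confusion: pd.DataFrame
    zero_division: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
        }).loc[self.classes]


def classification_report(y_true: Sequence, y_pred: Sequence) -> ClassificationReport:
    """One-vs-rest classification metrics from true and predicted labels."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    classes = sorted(set(y_true) | set(y_pred), key=str)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y_true, y_pred):
        confusion.loc[t, p] += 1
    precision, recall, f1, support = {}, {}, {}, {}
    zero_division = []
    for c in classes:
        tp = int(confusion.loc[c, c])
        fp = int(confusion[c].sum()) - tp
        fn = int(confusion.loc[c].sum()) - tp
        if tp + fp == 0:
            precision[c] = 0.0
            zero_division.append(c)
        else:
            precision[c] = tp / (tp + fp)
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        f1[c] = (0.0 if precision[c] + recall[c] == 0
                 else 2 * precision[c] * recall[c] / (precision[c] + recall[c]))
        support[c] = tp + fn
    accuracy = float(np.trace(confusion.to_numpy())) / len(y_true)
    return ClassificationReport(classes, precision, recall, f1, support,
                                accuracy, confusion, zero_division)


def split_train_test(
    samples: Sequence[str],
    labels: Mapping[str, object],
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random train/test partition of the cohort.

    Per class, ``round(train_fraction · n_class)`` samples (clamped to
    keep at least one train and one test sample per class) are drawn
    into the training set. Deterministic for a given seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    by_class: dict = {}
    for s in samples:
        by_class.setdefault(labels[s], []).append(s)
    singleton = [str(c) for c, members in by_class.items() if len(members) < 2]
    if singleton:
        raise ValueError(f"classes with fewer than 2 samples cannot be split: {singleton}")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    for c in sorted(by_class, key=str):
        members = by_class[c]
        n_train = int(np.clip(round(train_fraction * len(members)),
                              1, len(members) - 1))
        picked = rng.permutation(len(members))[:n_train]
        train.update(members[i] for i in picked)
    train_ids = [s for s in samples if s in train]
    test_ids = [s for s in samples if s not in train]
    return train_ids, test_ids


def _grow(values: np.ndarray, y: np.ndarray, n_classes: int, classes: list,
          thresholds: tuple[float, ...], max_depth: int, depth: int) -> TreeNode:
    counts = np.bincount(y, minlength=n_classes)
    gini = gini_impurity(counts)
    majority = classes[int(np.argmax(counts))]  # argmax: first class on ties
    node = TreeNode(gini=gini, value=counts, predicted_class=majority)
    if gini == 0.0 or depth >= max_depth:
        return node

    onehot = np.eye(n_classes, dtype=np.int64)[y]  # samples x classes
    total = y.size
    best = None  # (weighted_gini, row, thr, left_mask)
    for thr in thresholds:
        left = values <= thr  # features x samples
        left_counts = left.astype(np.int64) @ onehot          # features x classes
        right_counts = counts[None, :] - left_counts
        n_left = left_counts.sum(axis=1)
        n_right = total - n_left
        with np.errstate(invalid="ignore", divide="ignore"):
            g_left = 1.0 - (left_counts ** 2).sum(axis=1) / np.maximum(n_left, 1) ** 2
            g_right = 1.0 - (right_counts ** 2).sum(axis=1) / np.maximum(n_right, 1) ** 2
        wg = (n_left * g_left + n_right * g_right) / total
        wg[(n_left == 0) | (n_right == 0)] = np.inf  # not a split
        f = int(np.argmin(wg))  # first minimum: lowest row index
        # priority: smaller impurity, then lower row, then lower threshold
        # (thresholds iterate ascending, so full ties keep the earlier one)
        if (best is None or wg[f] < best[0] - 1e-12
                or (abs(wg[f] - best[0]) <= 1e-12 and f < best[1])):
            best = (float(wg[f]), f, thr, left[f])
    if best is None or best[0] >= gini - 1e-12:
        return node  # no strictly improving split
    _, row, thr, left_mask = best
    node.threshold = thr
    node.row_index = row
    node.children = (
        _grow(values[:, left_mask], y[left_mask], n_classes, classes,
              thresholds, max_depth, depth + 1),
        _grow(values[:, ~left_mask], y[~left_mask], n_classes, classes,
              thresholds, max_depth, depth + 1),
    )
    return node


def train_tree(
    matrix: GenotypeMatrix,
    labels: Mapping[str, object],
    max_depth: int = 4,
    seed: int = 0,
    train_fraction: float = 2 / 3,
) -> tuple[TreeModel, ClassificationReport, ClassificationReport]:
    """Fit a CART tree on a stratified split and report train/test metrics.

    Returns ``(model, train_report, test_report)``. The tree is grown
    greedily on Gini impurity with deterministic tie-breaking (lowest
    row index, then lower threshold) and stops at ``max_depth``, purity,
    or when no split strictly reduces the weighted impurity.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    missing = [s for s in matrix.samples if s not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    classes = sorted({labels[s] for s in matrix.samples}, key=str)
    if len(classes) < 2:
        raise ValueError("need at least two classes to classify")
    train_ids, test_ids = split_train_test(matrix.samples, labels,
                                           train_fraction, seed)
    class_code = {c: i for i, c in enumerate(classes)}
    col = {s: j for j, s in enumerate(matrix.samples)}
    thresholds = (0.5,) if matrix.mode == "binary" else (0.5, 1.5)

    train_cols = [col[s] for s in train_ids]
    X_train = matrix.values[:, train_cols].astype(np.int64)
    y_train = np.array([class_code[labels[s]] for s in train_ids])
    root = _grow(X_train, y_train, len(classes), classes, thresholds,
                 max_depth, depth=0)
    # re-index row splits from node-local to matrix rows: _grow subsets only
    # columns, so row indices are already matrix rows; attach variant keys
    def attach(node: TreeNode) -> None:
        if node.is_leaf:
            return
        node.split_variant = matrix.variants[node.row_index]
        attach(node.children[0])
        attach(node.children[1])
    attach(root)

    model = TreeModel(root=root, classes=classes, variants=list(matrix.variants),
                      mode=matrix.mode, max_depth=max_depth)
    pred_train = model.predict_values(matrix.values[:, train_cols])
    y_true_train = [labels[s] for s in train_ids]
    test_cols = [col[s] for s in test_ids]
    pred_test = model.predict_values(matrix.values[:, test_cols])
    y_true_test = [labels[s] for s in test_ids]
    return (model,
            classification_report(y_true_train, pred_train),
            classification_report(y_true_test, pred_test))


def mask_variants(matrix: GenotypeMatrix,
                  keys: Sequence[VariantKey | str]) -> GenotypeMatrix:
    """Remove the named variant rows (e.g. known causal mutations).

    Keys may be :class:`VariantKey` objects, rsids, or
    ``chrom:pos:ref:alt`` labels. Unresolvable keys raise, naming them.
    """
    if not keys:
        return GenotypeMatrix(list(matrix.variants), list(matrix.samples),
                              matrix.values.copy(), matrix.mode)
    rows, unresolved = [], []
    for key in keys:
        try:
            rows.append(matrix.index_of(key))
        except KeyError:
            unresolved.append(str(key))
    if unresolved:
        raise KeyError(f"variants not found in matrix: {unresolved}")
    return matrix.drop_variants(rows)


def export_tree_rules(model: TreeModel,
                      gene_map: Mapping[str, str] | None = None) -> str:
    """Human-readable depth-first listing of the fitted tree.

    Internal nodes show the splitting variant, threshold, Gini and class
    counts; leaves show the predicted class. The footer counts distinct
    splitting variants (and genes, when a ``variant label → gene`` or
    ``rsid → gene`` map is supplied).
    """
    if model.root is None:  # pragma: no cover - TreeModel always has a root
        raise ValueError("model is not fitted")
    lines: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        pad = "  " * depth
        if node.is_leaf:
            lines.append(f"{pad}leaf gini={node.gini:.4f} "
                         f"value={list(map(int, node.value))} "
                         f"class={node.predicted_class}")
            return
        lines.append(f"{pad}split {node.split_variant.label} "
                     f"<= {node.threshold} gini={node.gini:.4f} "
                     f"value={list(map(int, node.value))}")
        walk(node.children[0], depth + 1)
        walk(node.children[1], depth + 1)

    walk(model.root, 0)
    used = model.splitting_variants
    lines.append(f"# distinct splitting variants: {len(used)}")
    if gene_map is not None:
        genes = set()
        for v in used:
            gene = gene_map.get(v.label) or (v.rsid and gene_map.get(v.rsid))
            if gene:
                genes.add(gene)
        lines.append(f"# distinct genes: {len(genes)}")
    if not used:
        lines.append(f"# majority class: {model.root.predicted_class}")
    return "\n".join(lines)
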