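"""CART decision trees over the 10-predictor feature table.

Greedy binary recursive partitioning minimizing Gini impurity
G = 1 - sum_k p_k^2, with exhaustive split search over every feature and
every midpoint of consecutive sorted unique values. Routing convention:
``value <= threshold`` goes left (the boundary goes left). Determinism is
guaranteed by explicit tie-breaks: smaller weighted child impurity first,
then earlier feature in declared column order, then smaller threshold.

Besides learned trees, three fixed-cutoff classifiers encode the published
clinical rules: a depth-3 three-subtype tree (age 32 yr, then v_e
0.175e-3, then k_ep 2.649e-3 on the printed scale), a tumor-volume stump
separating Hodgkin from non-Hodgkin lymphoma at 45183.50 mm^3, and a
depth-2 k_ep tree (2.1489e-3, 1.009e-3) grading thymoma invasiveness.
Which side of each cutoff carries which label is not part of the published
rules; the defaults here follow the group-level directions of the cohort
statistics (lymphoma younger; carcinoma higher v_e, lower k_ep) and every
leaf stays overridable through the ``orientation`` mapping.

Missing values are rejected at prediction time: no surrogate splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PUBLISHED_TREE_NAMES = ("pmt3", "lymphoma_subtype", "thymoma_invasiveness")


def gini(counts: np.ndarray) -> float:
    """Gini impurity of a class-count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """One node; leaves have ``feature is None``."""

    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    prediction: Optional[str] = None
    counts: Optional[Dict[str, int]] = None
    impurity: float = 0.0
    n: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d: dict = {"counts": self.counts, "n": self.n, "impurity": self.impurity}
        if self.is_leaf:
            d["leaf"] = self.prediction
        else:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                prediction=self.prediction,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "leaf" in d:
            return cls(prediction=d["leaf"], counts=d.get("counts"),
                       n=d.get("n", 0), impurity=d.get("impurity", 0.0))
        return cls(
            feature=d["feature"],
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
            prediction=d.get("prediction"),
            counts=d.get("counts"),
            n=d.get("n", 0),
            impurity=d.get("impurity", 0.0),
        )


class DecisionTree:
    """A binary rule tree over named features; learned or published."""

    def __init__(
        self,
        root: TreeNode,
        classes: Sequence[str],
        feature_names: Sequence[str],
        provenance: str = "learned",
        hyperparams: Optional[dict] = None,
    ):
        self.root = root
        self.classes = tuple(classes)
        self.feature_names = tuple(feature_names)
        self.provenance = provenance
        self.hyperparams = dict(hyperparams or {})

    # -- prediction ---------------------------------------------------------
    def predict_row(self, row) -> str:
        node = self.root
        while not node.is_leaf:
            try:
                val = row[node.feature]
            except (KeyError, IndexError) as exc:
                raise KeyError(f"feature '{node.feature}' missing from row") from exc
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise ValueError(f"missing value for feature '{node.feature}'")
            node = node.left if val <= node.threshold else node.right
        return node.prediction

    def predict(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            rows = (r for _, r in table.iterrows())
        else:
            rows = iter(table)
        return np.array([self.predict_row(r) for r in rows], dtype=object)

    # -- structure ----------------------------------------------------------
    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def internal_nodes(self) -> List[TreeNode]:
        out: List[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "features": list(self.feature_names),
            "provenance": self.provenance,
            "hyperparams": self.hyperparams,
            "root": self.root.to_dict(),
        }

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            classes=d["classes"],
            feature_names=d["features"],
            provenance=d.get("provenance", "learned"),
            hyperparams=d.get("hyperparams", {}),
        )

    @classmethod
    def from_json(cls, source) -> "DecisionTree":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                d = json.loads(s)
            else:
                with open(s) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the rule tree."""
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            my_id = counter[0]
            counter[0] += 1
            if node.is_leaf:
                label = f"{node.prediction}"
                if node.counts:
                    label += f"\\n{node.counts}"
                lines.append(f'  n{my_id} [label="{label}", style=filled];')
            else:
                lines.append(f'  n{my_id} [label="{node.feature} <= {node.threshold:g}"];')
                lid = walk(node.left)
                rid = walk(node.right)
                lines.append(f'  n{my_id} -> n{lid} [label="yes"];')
                lines.append(f'  n{my_id} -> n{rid} [label="no"];')
            return my_id

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# growing


def _best_split(
    X: np.ndarray, y_codes: np.ndarray, n_classes: int, min_samples_leaf: int
) -> Optional[Tuple[int, float, float]]:
    """Exhaustive (feature, threshold) minimizing weighted child Gini.

    Returns (feature index, threshold, weighted impurity) or None when no
    admissible split exists. Ties: first feature in column order, then the
    smallest threshold.
    """
    n, p = X.shape
    best: Optional[Tuple[int, float, float]] = None
    for j in range(p):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        xs = col[order]
        ys = y_codes[order]
        if xs[0] == xs[-1]:
            continue  # constant feature
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left_counts = np.cumsum(onehot, axis=0)  # counts with <= position i
        total = left_counts[-1]
        # candidate boundaries: between distinct consecutive values
        boundary = np.nonzero(xs[:-1] < xs[1:])[0]  # split after index b
        for b in boundary:
            n_left = b + 1
            n_right = n - n_left
            if n_left < min_samples_leaf or n_right < min_samples_leaf:
                continue
            lc = left_counts[b]
            rc = total - lc
            g = (n_left * gini(lc) + n_right * gini(rc)) / n
            thr = (xs[b] + xs[b + 1]) / 2.0
            if best is None or g < best[2] or (g == best[2] and (j, thr) < (best[0], best[1])):
                best = (j, thr, g)
    return best


def _majority(counts: Dict[str, int], classes: Sequence[str]) -> str:
    # ties go to the earlier class in declared order
    best = None
    for c in classes:
        k = counts.get(c, 0)
        if best is None or k > counts.get(best, 0):
            best = c
    return best


class CartModel:
    """CART specification: a feature table, labels and stopping rules.

    ``fit`` grows the tree and returns :class:`CartResults`. Default
    stopping rules target small clinical cohorts: ``max_depth=3``,
    ``min_samples_split=4``, ``min_samples_leaf=2``; no pruning, no
    surrogate splits.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[str],
        max_depth: int = 3,
        min_samples_split: int = 4,
        min_samples_leaf: int = 2,
        classes: Optional[Sequence[str]] = None,
    ):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if X.isna().any().any():
            raise ValueError("missing values not supported (no surrogate splits)")
        self.X = X
        self.y = y
        self.classes = tuple(classes) if classes is not None else tuple(sorted(set(y)))
        unknown = set(y) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {unknown}")
        if max_depth < 0 or min_samples_leaf < 1 or min_samples_split < 2:
            raise ValueError("invalid stopping rules")
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf

    def fit(self) -> "CartResults":
        Xv = self.X.to_numpy(dtype=float)
        code = {c: i for i, c in enumerate(self.classes)}
        y_codes = np.array([code[v] for v in self.y])
        names = list(self.X.columns)
        n_classes = len(self.classes)

        def counts_dict(codes: np.ndarray) -> Dict[str, int]:
            bc = np.bincount(codes, minlength=n_classes)
            return {c: int(k) for c, k in zip(self.classes, bc)}

        def build(idx: np.ndarray, depth: int) -> TreeNode:
            codes = y_codes[idx]
            cd = counts_dict(codes)
            node = TreeNode(
                counts=cd,
                n=int(idx.size),
                impurity=gini(np.bincount(codes, minlength=n_classes).astype(float)),
                prediction=_majority(cd, self.classes),
            )
            pure = len(np.unique(codes)) <= 1
            if depth >= self.max_depth or pure or idx.size < self.min_samples_split:
                return node
            split = _best_split(Xv[idx], codes, n_classes, self.min_samples_leaf)
            if split is None:
                return node
            j, thr, _ = split
            go_left = Xv[idx, j] <= thr
            node.feature = names[j]
            node.threshold = float(thr)
            node.left = build(idx[go_left], depth + 1)
            node.right = build(idx[~go_left], depth + 1)
            return node

        root = build(np.arange(len(self.y)), 0)
        tree = DecisionTree(
            root,
            classes=self.classes,
            feature_names=names,
            provenance="learned",
            hyperparams={
                "max_depth": self.max_depth,
                "min_samples_split": self.min_samples_split,
                "min_samples_leaf": self.min_samples_leaf,
            },
        )
        return CartResults(self, tree)


class CartResults:
    """A grown tree plus the training-sample statistics behind it."""

    def __init__(self, model: CartModel, tree: DecisionTree):
        self.model = model
        self.tree = tree

    def predict(self, table) -> np.ndarray:
        return self.tree.predict(table)

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.X) == self.model.y))

    def importance(self) -> pd.DataFrame:
        return variable_importance(self.tree)

    def summary(self) -> str:
        imp = self.importance()
        lines = [
            "CART decision tree",
            "==================",
            f"  n = {len(self.model.y)}, classes = {list(self.tree.classes)}",
            f"  depth = {self.tree.depth}, "
            f"internal nodes = {len(self.tree.internal_nodes())}",
            f"  training accuracy = {100 * self.training_accuracy():.2f}%",
            "",
            "  normalized importance (%):",
        ]
        for _, row in imp.iterrows():
            if row["raw"] > 0:
                lines.append(f"    {row['feature']:<14s} {row['normalized']:6.1f}")
        return "\n".join(lines)


def grow_tree(
    X: pd.DataFrame,
    y: Sequence[str],
    max_depth: int = 3,
    min_samples_split: int = 4,
    min_samples_leaf: int = 2,
    classes: Optional[Sequence[str]] = None,
) -> CartResults:
    """Functional wrapper around :class:`CartModel`."""
    return CartModel(
        X, y, max_depth=max_depth, min_samples_split=min_samples_split,
        min_samples_leaf=min_samples_leaf, classes=classes,
    ).fit()


def variable_importance(
    tree: DecisionTree,
    X: Optional[pd.DataFrame] = None,
    y: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-feature impurity-decrease importance, raw and normalized.

    raw(feature) = sum over nodes splitting on it of
    (node fraction of samples) * (parent Gini - weighted child Gini);
    normalized = 100 * raw / max(raw). Passing (X, y) re-populates node
    counts by routing the data (needed for published trees, which carry no
    training sample).
    """
    if X is not None:
        if y is None:
            raise ValueError("y required when X given")
        populate_counts(tree, X, y)
    n_root = tree.root.n
    if n_root == 0:
        raise ValueError("tree carries no sample counts; pass (X, y)")
    raw = {f: 0.0 for f in tree.feature_names}
    for node in tree.internal_nodes():
        child = (node.left.n * node.left.impurity + node.right.n * node.right.impurity) / node.n
        decrease = node.impurity - child
        raw[node.feature] = raw.get(node.feature, 0.0) + decrease * (node.n / n_root)
    mx = max(raw.values()) if raw else 0.0
    rows = [
        {
            "feature": f,
            "raw": r,
            "normalized": (100.0 * r / mx) if mx > 0 else 0.0,
        }
        for f, r in raw.items()
    ]
    df = pd.DataFrame(rows).sort_values("raw", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def populate_counts(tree: DecisionTree, X: pd.DataFrame, y: Sequence[str]) -> None:
    """Route (X, y) through the tree, filling node counts/impurity in place."""
    y = np.asarray(y, dtype=object)
    classes = tree.classes
    code = {c: i for i, c in enumerate(classes)}

    def fill(node: TreeNode, idx: np.ndarray) -> None:
        codes = np.array([code[y[i]] for i in idx], dtype=int)
        bc = np.bincount(codes, minlength=len(classes)).astype(float)
        node.counts = {c: int(k) for c, k in zip(classes, bc)}
        node.n = int(idx.size)
        node.impurity = gini(bc)
        if node.is_leaf:
            return
        vals = X[node.feature].to_numpy(dtype=float)[idx]
        fill(node.left, idx[vals <= node.threshold])
        fill(node.right, idx[vals > node.threshold])

    fill(tree.root, np.arange(len(y)))


# ---------------------------------------------------------------------------
# published fixed-cutoff trees (feature columns on the printed scale:
# kep/ve in 1e-3 units, volume in mm^3, age in years)

PMT3_CUTOFFS = {"age_yr": 32.0, "ve": 0.175, "kep": 2.649}
LYMPHOMA_VOLUME_CUTOFF = 45183.50
INVASIVENESS_CUTOFFS = {"kep_1": 2.1489, "kep_2": 1.009}

_DEFAULT_ORIENTATIONS = {
    "pmt3": {
        "young": "lymphoma",          # age <= 32
        "low_ve": "thymoma",          # age > 32, ve <= 0.175
        "low_kep": "thymic_carcinoma",  # age > 32, ve > 0.175, kep <= 2.649
        "high_kep": "thymoma",        # age > 32, ve > 0.175, kep > 2.649
    },
    "lymphoma_subtype": {
        "small": "non_hodgkin",       # volume <= 45183.50 mm^3
        "large": "hodgkin",
    },
    "thymoma_invasiveness": {
        "low_kep": "invasive",        # kep <= 1.009
        "mid_kep": "noninvasive",     # 1.009 < kep <= 2.1489
        "high_kep": "noninvasive",    # kep > 2.1489
    },
}


def published_tree(name: str, orientation: Optional[Dict[str, str]] = None) -> DecisionTree:
    """Fixed rule tree with the published cutoffs.

    ``orientation`` overrides the default leaf labels (keys as in
    ``_DEFAULT_ORIENTATIONS[name]``); the cutoffs themselves are fixed.
    """
    if name not in PUBLISHED_TREE_NAMES:
        raise ValueError(f"unknown published tree '{name}'; choose from {PUBLISHED_TREE_NAMES}")
    o = dict(_DEFAULT_ORIENTATIONS[name])
    if orientation:
        bad = set(orientation) - set(o)
        if bad:
            raise ValueError(f"unknown orientation keys: {sorted(bad)}")
        o.update(orientation)

    def leaf(label: str) -> TreeNode:
        return TreeNode(prediction=label)

    if name == "pmt3":
        kep_node = TreeNode(
            feature="kep", threshold=PMT3_CUTOFFS["kep"],
            left=leaf(o["low_kep"]), right=leaf(o["high_kep"]),
        )
        ve_node = TreeNode(
            feature="ve", threshold=PMT3_CUTOFFS["ve"],
            left=leaf(o["low_ve"]), right=kep_node,
        )
        root = TreeNode(
            feature="age_yr", threshold=PMT3_CUTOFFS["age_yr"],
            left=leaf(o["young"]), right=ve_node,
        )
        classes = ("lymphoma", "thymic_carcinoma", "thymoma")
    elif name == "lymphoma_subtype":
        root = TreeNode(
            feature="volume_mm3", threshold=LYMPHOMA_VOLUME_CUTOFF,
            left=leaf(o["small"]), right=leaf(o["large"]),
        )
        classes = ("hodgkin", "non_hodgkin")
    else:  # thymoma_invasiveness
        inner = TreeNode(
            feature="kep", threshold=INVASIVENESS_CUTOFFS["kep_2"],
            left=leaf(o["low_kep"]), right=leaf(o["mid_kep"]),
        )
        root = TreeNode(
            feature="kep", threshold=INVASIVENESS_CUTOFFS["kep_1"],
            left=inner, right=leaf(o["high_kep"]),
        )
        classes = ("invasive", "noninvasive")
    features = ("age_yr", "ktrans", "kep", "vp", "ve", "ttp_s", "cmax",
                "volume_mm3", "surface_mm2", "maxdiam_mm")
    return DecisionTree(root, classes=tuple(sorted(set(classes))), feature_names=features,
                        provenance=f"published:{name}")
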