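"""Quantitative IF-THEN rules from a decision tree trained on the full dataset.

A CART tree (Gini impurity) is fit on all samples with a chosen feature
prefix — no cross-validation split, since the goal here is
interpretation rather than performance estimation. Every root-to-leaf
path becomes one rule: a conjunction of threshold predicates over the
features on the path, predicting the leaf's majority class. Redundant
thresholds on the same feature are merged to the tightest interval, so
each feature appears at most twice per rule (one lower, one upper
bound). The rule set partitions feature space: exactly one rule fires
for any point, and applying the rules reproduces the tree's
predictions exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .encoders import FeatureMatrix
from .ifs_engine import ClassifierSpec


@dataclass
class Predicate:
    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:.6g}"


@dataclass
class Rule:
    predicates: list[Predicate]
    predicted_class: str
    support: int
    purity: float

    def fires(self, row: dict[str, float]) -> bool:
        return all(p.holds(row[p.feature]) for p in self.predicates)

    def __str__(self) -> str:
        if not self.predicates:
            cond = "TRUE"
        else:
            cond = " AND ".join(str(p) for p in self.predicates)
        return (
            f"IF {cond} THEN class = {self.predicted_class} "
            f"(support={self.support}, purity={self.purity:.3f})"
        )


@dataclass
class RuleSet:
    rules: list[Rule]
    classes: list[str]
    feature_subset: list[str]

    def __len__(self) -> int:
        return len(self.rules)

    def predict_row(self, row: dict[str, float]) -> str:
        fired = [r for r in self.rules if r.fires(row)]
        if len(fired) != 1:
            raise AssertionError(
                f"{len(fired)} rules fired; the rule set must partition feature space"
            )
        return fired[0].predicted_class

    def predict(self, X: np.ndarray) -> list[str]:
        X = np.asarray(X, dtype=float)
        out = []
        for i in range(X.shape[0]):
            row = {f: X[i, j] for j, f in enumerate(self.feature_subset)}
            out.append(self.predict_row(row))
        return out

    def to_text(self) -> str:
        return "\n".join(str(r) for r in self.rules)

    def to_json_dict(self) -> dict:
        return {
            "classes": self.classes,
            "feature_subset": self.feature_subset,
            "rules": [
                {
                    "predicates": [
                        {"feature": p.feature, "op": p.op, "threshold": p.threshold}
                        for p in r.predicates
                    ],
                    "class": r.predicted_class,
                    "support": r.support,
                    "purity": r.purity,
                }
                for r in self.rules
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def fit_full_tree(
    X: FeatureMatrix,
    y,
    top_k_features: list[str] | None = None,
    spec: ClassifierSpec | None = None,
) -> tuple[DecisionTreeClassifier, list[str]]:
    """Fit a CART tree on ALL samples over the given feature subset.

    Returns the fitted tree and the feature-name list in column order.
    """
    spec = spec or ClassifierSpec(family="dt")
    if spec.family != "dt":
        raise ValueError("rule extraction requires a decision-tree spec")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit a tree")
    if top_k_features is None:
        features = list(X.feature_names)
        values = X.values
    else:
        col = {n: j for j, n in enumerate(X.feature_names)}
        features = list(top_k_features)
        values = X.values[:, [col[f] for f in features]]
    tree = spec.build()
    tree.fit(values, y)
    return tree, features


def extract_rules(
    tree: DecisionTreeClassifier, feature_names: list[str], class_names: list[str] | None = None
) -> RuleSet:
    """One rule per leaf; thresholds on a shared feature merged tightest.

    The predicted class of a leaf is its majority training class; exact
    ties resolve to the lexicographically first class (consistent with
    the tree's own argmax over its sorted class order).
    """
    t = tree.tree_
    tree_classes = [str(c) for c in tree.classes_]
    if class_names is None:
        class_names = sorted(tree_classes)
    rules: list[Rule] = []

    def walk(node: int, bounds: dict[str, list[float | None]]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node].ravel()
            # sklearn >= 1.3 stores per-leaf class fractions; rescale to counts
            support = int(round(t.weighted_n_node_samples[node]))
            best = int(np.argmax(counts))
            purity = float(counts[best] / counts.sum())
            predicates = []
            for feat, (lo, hi) in bounds.items():
                if lo is not None and hi is not None and lo > hi:
                    raise AssertionError(f"empty interval for {feat}")
                if hi is not None:
                    predicates.append(Predicate(feat, "<=", hi))
                if lo is not None:
                    predicates.append(Predicate(feat, ">", lo))
            rules.append(
                Rule(
                    predicates=predicates,
                    predicted_class=tree_classes[best],
                    support=support,
                    purity=purity,
                )
            )
            return
        feat = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        lo, hi = bounds.get(feat, (None, None))
        # left branch: feat <= thr (tighten the upper bound)
        left = dict(bounds)
        left[feat] = [lo, thr if hi is None else min(hi, thr)]
        walk(t.children_left[node], left)
        # right branch: feat > thr (tighten the lower bound)
        right = dict(bounds)
        right[feat] = [thr if lo is None else max(lo, thr), hi]
        walk(t.children_right[node], right)

    walk(0, {})
    return RuleSet(rules=rules, classes=class_names, feature_subset=list(feature_names))


def rules_per_class(rule_set: RuleSet) -> dict[str, int]:
    """Rule counts per class; classes with no rules report 0."""
    if not rule_set.rules:
        raise ValueError("empty rule set")
    counts = {c: 0 for c in rule_set.classes}
    for r in rule_set.rules:
        counts.setdefault(r.predicted_class, 0)
        counts[r.predicted_class] += 1
    return counts


def rules_per_class_csv(counts: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("class,n_rules\n")
        for c in sorted(counts):
            fh.write(f"{c},{counts[c]}\n")
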