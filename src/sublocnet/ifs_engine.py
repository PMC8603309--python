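"""Incremental feature selection under SMOTE-balanced stratified k-fold CV.

Nested prefixes of a ranked feature list are evaluated with one of four
classifier families (random forest, SVM, kNN, decision tree). Class
imbalance is handled by SMOTE oversampling — by default applied inside
each training fold only, so synthetic samples never leak into test
folds. Performance is scored by the multiclass Matthews correlation
coefficient (Gorodkin's R_K), computed once on the pooled out-of-fold
predictions, together with overall and per-class accuracies. The prefix
with the highest MCC is the *optimum* model; the smallest prefix within
a tolerance of that MCC is the *compact* model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encoders import FeatureMatrix
from .feature_selection import RankedFeatureList

FAMILIES = ("rf", "svm", "knn", "dt")


@dataclass
class ClassifierSpec:
    """One of the four classifier families with documented defaults.

    rf: 100 trees; svm: linear kernel, C=1 (one-vs-one multiclass);
    knn: k=1, Euclidean; dt: CART with Gini impurity, unlimited depth.
    """

    family: str = "rf"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def build(self):
        p = dict(self.params)
        if self.family == "rf":
            return RandomForestClassifier(
                n_estimators=p.pop("n_trees", 100),
                random_state=self.seed,
                n_jobs=1,
                **p,
            )
        if self.family == "svm":
            return SVC(
                kernel=p.pop("kernel", "linear"),
                C=p.pop("C", 1.0),
                random_state=self.seed,
                **p,
            )
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=p.pop("k", 1), **p)
        return DecisionTreeClassifier(
            criterion=p.pop("criterion", "gini"),
            max_depth=p.pop("max_depth", None),
            random_state=self.seed,
            **p,
        )


@dataclass
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    smote: str = "train_folds_only"  # off | train_folds_only | pre_split
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.smote not in ("off", "train_folds_only", "pre_split"):
            raise ValueError(f"unknown smote mode {self.smote!r}")


@dataclass
class IFSCurve:
    subset_sizes: list[int]
    mcc: list[float]
    overall_acc: list[float]
    per_class_acc: list[dict[str, float]]
    classifier: ClassifierSpec

    def __post_init__(self) -> None:
        sizes = self.subset_sizes
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("subset sizes must be strictly increasing")
        if not (len(sizes) == len(self.mcc) == len(self.overall_acc) == len(self.per_class_acc)):
            raise ValueError("curve arrays misaligned")

    def to_csv(self, path) -> None:
        classes = sorted(self.per_class_acc[0]) if self.per_class_acc else []
        with open(path, "w") as fh:
            cols = ["size", "mcc", "overall_acc"] + [f"acc_{c}" for c in classes]
            fh.write(",".join(cols) + "\n")
            for i, size in enumerate(self.subset_sizes):
                row = [str(size), f"{self.mcc[i]:.6f}", f"{self.overall_acc[i]:.6f}"]
                row += [f"{self.per_class_acc[i][c]:.6f}" for c in classes]
                fh.write(",".join(row) + "\n")


def build_subsets(ranked: RankedFeatureList | list[str], step: int = 10) -> list[list[str]]:
    """Nested prefixes of sizes step, 2*step, ... up to the largest
    multiple of ``step`` not exceeding the list length (any remainder
    prefix is dropped)."""
    names = ranked.names if isinstance(ranked, RankedFeatureList) else list(ranked)
    if not names:
        raise ValueError("ranked feature list is empty")
    if step < 1:
        raise ValueError("step must be >= 1")
    return [names[:size] for size in range(step, len(names) + 1, step)]


def smote_oversample(
    X: np.ndarray, y, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE to parity: oversample every minority class up to the
    majority count.

    Originals are preserved verbatim (and come first in the output);
    each synthetic sample is x_i + u * (x_nn - x_i) with u ~ U(0, 1) and
    x_nn one of the min(k, class size - 1) nearest same-class neighbors
    of a randomly chosen class member. A singleton class is duplicated
    as-is (zero jitter).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("every class must have at least one sample")
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    new_rows, new_labels = [], []
    for cls, count in zip(classes, counts):
        deficit = int(n_max - count)
        if deficit == 0:
            continue
        members = X[y == cls]
        if count == 1:
            new_rows.append(np.repeat(members, deficit, axis=0))
            new_labels.extend([cls] * deficit)
            continue
        k_eff = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        _, nn_idx = nn.kneighbors(members)  # column 0 is the point itself
        base_idx = rng.integers(0, count, size=deficit)
        for i in base_idx:
            j = nn_idx[i, 1 + rng.integers(0, k_eff)]
            u = rng.random()
            new_rows.append((members[i] + u * (members[j] - members[i]))[None, :])
            new_labels.append(cls)
    if not new_rows:
        return X, y
    X_out = np.vstack([X] + new_rows)
    y_out = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
    return X_out, y_out


def labels_to_indicator(labels, classes: list) -> np.ndarray:
    """n x K 0-1 matrix with a single 1 per row marking the class."""
    index = {c: j for j, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


def multiclass_mcc(X_ind: np.ndarray, Y_ind: np.ndarray) -> float:
    """Gorodkin's K-category Matthews correlation coefficient.

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)) where X and Y are the
    0-1 predicted/actual class indicator matrices and the covariance is
    taken over all cells with per-column centering. A zero denominator
    (e.g. a constant predictor) yields 0 by convention.
    """
    X = np.asarray(X_ind, dtype=float)
    Y = np.asarray(Y_ind, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"indicator shapes differ: {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    num = float((Xc * Yc).sum())
    den = float(np.sqrt((Xc * Xc).sum() * (Yc * Yc).sum()))
    if den == 0.0:
        return 0.0
    return num / den


def _metrics(y_true, y_pred, classes) -> tuple[float, float, dict]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    mcc = multiclass_mcc(
        labels_to_indicator(y_pred, classes), labels_to_indicator(y_true, classes)
    )
    overall = float(np.mean(y_true == y_pred))
    per_class = {}
    for c in classes:
        mask = y_true == c
        per_class[c] = float(np.mean(y_pred[mask] == c)) if mask.any() else 0.0
    return mcc, overall, per_class


def _resolve_columns(X, features) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, FeatureMatrix):
        if features is None:
            return X.values, None
        col = {n: j for j, n in enumerate(X.feature_names)}
        missing = [f for f in features if f not in col]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return X.values[:, [col[f] for f in features]], None
    arr = np.asarray(X, dtype=float)
    if features is not None:
        arr = arr[:, list(features)]
    return arr, None


def evaluate_model(
    X,
    y,
    features=None,
    spec: ClassifierSpec | None = None,
    cv_config: CVConfig | None = None,
) -> tuple[float, float, dict]:
    """Stratified k-fold CV; metrics on the pooled out-of-fold predictions.

    With ``smote='train_folds_only'`` the training split of every fold
    is SMOTE-balanced before fitting, while test folds stay untouched.
    With ``'pre_split'`` the whole dataset is balanced first and folds
    are drawn from the augmented data (mirrors balancing the dataset
    before cross-validation). Returns (MCC, overall accuracy,
    per-class accuracy dict).
    """
    spec = spec or ClassifierSpec()
    cv = cv_config or CVConfig()
    values, _ = _resolve_columns(X, features)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())

    if cv.smote == "pre_split":
        values, y = smote_oversample(values, y, k=cv.smote_k, seed=cv.seed)

    skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    y_pred = np.empty(len(y), dtype=y.dtype)
    seen_in_train = set()
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The least populated class", category=UserWarning
        )
        folds = list(skf.split(values, y))
    for fold_i, (train, test) in enumerate(folds):
        X_tr, y_tr = values[train], y[train]
        if cv.smote == "train_folds_only":
            X_tr, y_tr = smote_oversample(
                X_tr, y_tr, k=cv.smote_k, seed=cv.seed + fold_i
            )
        seen_in_train.update(np.unique(y_tr).tolist())
        clf = spec.build()
        clf.fit(X_tr, y_tr)
        y_pred[test] = clf.predict(values[test])
    never_trained = set(classes) - seen_in_train
    if never_trained:
        warnings.warn(
            f"classes never present in any training fold: {sorted(never_trained)}"
        )
    return _metrics(y, y_pred, classes)


def run_ifs(
    ranked: RankedFeatureList,
    X: FeatureMatrix,
    y,
    spec: ClassifierSpec | None = None,
    step: int = 10,
    cv_config: CVConfig | None = None,
) -> IFSCurve:
    """Evaluate every nested prefix of the ranked list; return the curve."""
    spec = spec or ClassifierSpec()
    subsets = build_subsets(ranked, step)
    sizes, mccs, accs, per_class = [], [], [], []
    for subset in subsets:
        mcc, acc, pca = evaluate_model(X, y, subset, spec, cv_config)
        sizes.append(len(subset))
        mccs.append(mcc)
        accs.append(acc)
        per_class.append(pca)
    return IFSCurve(sizes, mccs, accs, per_class, spec)


def select_optimum(curve: IFSCurve) -> tuple[int, dict]:
    """Subset size with the highest MCC; ties go to the smallest size."""
    if not curve.subset_sizes:
        raise ValueError("empty IFS curve")
    i = int(np.argmax(curve.mcc))  # first max = smallest size (sizes increase)
    return curve.subset_sizes[i], _point_metrics(curve, i)


def select_compact(curve: IFSCurve, tolerance: float = 0.03) -> tuple[int, dict]:
    """Smallest subset size whose MCC is within ``tolerance`` of the max."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    best = max(curve.mcc)
    for i, m in enumerate(curve.mcc):
        if m >= best - tolerance:
            return curve.subset_sizes[i], _point_metrics(curve, i)
    raise AssertionError("unreachable: max MCC is always within tolerance")


def _point_metrics(curve: IFSCurve, i: int) -> dict:
    return {
        "mcc": curve.mcc[i],
        "overall_acc": curve.overall_acc[i],
        "per_class_acc": curve.per_class_acc[i],
    }
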