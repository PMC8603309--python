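"""Feature screening (shadow-feature Boruta) and ranking (mRMR, MID form).

Boruta is an all-relevant filter: at every iteration the surviving
features are paired with shuffled "shadow" copies, a random forest is
fit on the combined matrix, and a real feature scores a *hit* when its
importance exceeds the maximum shadow importance. A two-sided binomial
test on the running hit count — two-step corrected: BH-FDR across
features plus a per-iteration Bonferroni factor for repeated testing —
confirms or rejects features; undecided features stay tentative.

mRMR ranks features greedily by mutual information: the next feature
maximizes relevance to the class label minus mean redundancy with the
features already picked (the MID criterion). Continuous features are
discretized into three states at mu +/- alpha*sigma first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mutual_info_score

from .encoders import FeatureMatrix


@dataclass
class BorutaResult:
    confirmed: set[str]
    rejected: set[str]
    tentative: set[str]
    n_iterations: int
    hit_counts: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "confirmed": sorted(self.confirmed),
            "rejected": sorted(self.rejected),
            "tentative": sorted(self.tentative),
            "n_iterations": self.n_iterations,
            "hit_counts": dict(sorted(self.hit_counts.items())),
        }


@dataclass
class RankedFeatureList:
    names: list[str]
    scores: list[float]
    method: str = "mrmr-mid"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank,feature\n")
            for i, name in enumerate(self.names, start=1):
                fh.write(f"{i},{name}\n")


@dataclass
class DiscretizedMatrix:
    states: np.ndarray  # integer matrix over {-1, 0, +1}
    thresholds: list[tuple[float, float]] = field(default_factory=list)


def _as_array_and_names(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, FeatureMatrix):
        return X.values, list(X.feature_names)
    arr = np.asarray(X, dtype=float)
    return arr, [f"f{j}" for j in range(arr.shape[1])]


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of rejected nulls."""
    m = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order]
    below = ranked <= alpha * (np.arange(1, m + 1) / m)
    out = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.max(np.flatnonzero(below))
        out[order[: cutoff + 1]] = True
    return out


def boruta_filter(
    X,
    y,
    n_iterations: int = 100,
    alpha: float = 0.05,
    percentile: float = 100.0,
    seed: int = 0,
    rf_params: dict | None = None,
) -> BorutaResult:
    """Shadow-feature relevance screen.

    Parameters mirror the usual Boruta defaults: up to ``n_iterations``
    rounds (early stop once nothing is undecided), hit threshold at the
    ``percentile`` of shadow importances (100 = max shadow), two-sided
    binomial decisions at level ``alpha`` under the two-step
    multiplicity correction.
    """
    values, names = _as_array_and_names(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("Boruta needs at least 2 classes in y")
    if n_iterations < 10:
        raise ValueError("n_iterations must be >= 10")
    rng = np.random.default_rng(seed)
    params = {"n_estimators": 100, "max_depth": 7, "n_jobs": 1}
    params.update(rf_params or {})

    n_features = len(names)
    undecided = np.ones(n_features, dtype=bool)
    hits = np.zeros(n_features, dtype=int)
    confirmed = np.zeros(n_features, dtype=bool)
    rejected = np.zeros(n_features, dtype=bool)

    it = 0
    for it in range(1, n_iterations + 1):
        idx = np.flatnonzero(undecided)
        if idx.size == 0:
            it -= 1
            break
        real = values[:, idx]
        shadow = real.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        combined = np.hstack([real, shadow])
        rf = RandomForestClassifier(
            random_state=int(rng.integers(2**31 - 1)), **params
        )
        rf.fit(combined, y)
        imp = rf.feature_importances_
        real_imp, shadow_imp = imp[: idx.size], imp[idx.size :]
        threshold = np.percentile(shadow_imp, percentile)
        hits[idx[real_imp > threshold]] += 1

        # two-step binomial decisions on the running hit counts:
        # BH-FDR across the features still in play, AND alpha/iteration
        # for repeatedly testing the same feature as rounds accumulate
        p_hi = binom.sf(hits[idx] - 1, it, 0.5)   # P(>= hits) under null
        p_lo = binom.cdf(hits[idx], it, 0.5)      # P(<= hits) under null
        confirm = _bh_reject(p_hi, alpha) & (p_hi <= alpha / it)
        reject = _bh_reject(p_lo, alpha) & (p_lo <= alpha / it)
        confirmed[idx[confirm]] = True
        rejected[idx[reject & ~confirm]] = True
        undecided &= ~(confirmed | rejected)

    return BorutaResult(
        confirmed={names[j] for j in np.flatnonzero(confirmed)},
        rejected={names[j] for j in np.flatnonzero(rejected)},
        tentative={names[j] for j in np.flatnonzero(undecided)},
        n_iterations=it,
        hit_counts={names[j]: int(hits[j]) for j in range(n_features)},
    )


def discretize(X, alpha_sd: float = 1.0) -> DiscretizedMatrix:
    """Per-feature 3-state coding: -1 below mu-alpha*sigma, +1 above
    mu+alpha*sigma, 0 between. Constant features map to all zeros."""
    if alpha_sd <= 0:
        raise ValueError("alpha_sd must be > 0")
    values, _ = _as_array_and_names(X)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    lo, hi = mu - alpha_sd * sd, mu + alpha_sd * sd
    states = np.zeros(values.shape, dtype=np.int8)
    nonconstant = sd > 0
    states[:, nonconstant] = np.where(
        values[:, nonconstant] < lo[nonconstant],
        -1,
        np.where(values[:, nonconstant] > hi[nonconstant], 1, 0),
    )
    return DiscretizedMatrix(
        states=states, thresholds=list(zip(lo.tolist(), hi.tolist()))
    )


def mutual_information(a_states, b_states) -> float:
    """Plug-in mutual information of two discrete vectors, in nats."""
    a = np.asarray(a_states).ravel()
    b = np.asarray(b_states).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be equal-length non-empty vectors")
    return float(mutual_info_score(a, b))


def mrmr_rank(
    X,
    y,
    n_select: int | None = None,
    alpha_sd: float = 1.0,
    prediscretized: bool = False,
) -> RankedFeatureList:
    """Greedy MID ranking of features.

    The first feature maximizes I(f; y); each later pick maximizes
    I(f; y) - mean_{s in selected} I(f; s). Ties (within 1e-12) break
    lexicographically on feature name, making the order deterministic.
    """
    values, names = _as_array_and_names(X)
    y = np.asarray(y)
    n_features = len(names)
    if n_select is None:
        n_select = n_features
    if n_select <= 0:
        raise ValueError("n_select must be > 0")
    if n_select > n_features:
        raise ValueError("n_select exceeds the number of features")
    states = values if prediscretized else discretize(values, alpha_sd).states

    relevance = np.array(
        [mutual_information(states[:, j], y) for j in range(n_features)]
    )
    redundancy_sum = np.zeros(n_features)
    selected: list[int] = []
    selected_scores: list[float] = []
    remaining = set(range(n_features))
    # candidate order sorted by name implements the lexicographic tie-break
    name_order = sorted(range(n_features), key=lambda j: names[j])

    for step in range(n_select):
        best_j, best_score = -1, -np.inf
        for j in name_order:
            if j not in remaining:
                continue
            score = relevance[j]
            if selected:
                score -= redundancy_sum[j] / len(selected)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        selected_scores.append(float(best_score))
        remaining.discard(best_j)
        if step < n_select - 1:
            for j in remaining:
                redundancy_sum[j] += mutual_information(
                    states[:, j], states[:, best_j]
                )

    return RankedFeatureList(
        names=[names[j] for j in selected], scores=selected_scores
    )
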