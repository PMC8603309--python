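"""End-to-end workflow: encode -> Boruta -> mRMR -> IFS -> rules.

This is the glue the command-line interface and the benchmark
experiments run. Feature screening and ranking always operate on the
original samples only — SMOTE-balanced samples are created later,
inside the cross-validation folds of the IFS stage, and never reach
Boruta or mRMR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import FeatureMatrix, concat_features, encode_enrichment, encode_network
from .feature_selection import BorutaResult, RankedFeatureList, boruta_filter, mrmr_rank
from .ifs_engine import (
    ClassifierSpec,
    CVConfig,
    IFSCurve,
    run_ifs,
    select_compact,
    select_optimum,
)
from .rule_extraction import RuleSet, extract_rules, fit_full_tree, rules_per_class
from .synthetic_benchmark import Benchmark


@dataclass
class PipelineResult:
    features: FeatureMatrix
    boruta: BorutaResult
    ranked: RankedFeatureList | None
    curve: IFSCurve | None
    optimum: tuple[int, dict] | None
    compact: tuple[int, dict] | None

    @property
    def optimum_mcc(self) -> float:
        if self.optimum is None:
            return 0.0  # no surviving features, no model
        return self.optimum[1]["mcc"]

    @property
    def optimum_acc(self) -> float:
        if self.optimum is None:
            return 0.0
        return self.optimum[1]["overall_acc"]


def encode_benchmark_features(benchmark: Benchmark) -> FeatureMatrix:
    """Network + KEGG-enrichment + GO-enrichment features for all proteins."""
    ids = benchmark.dataset.ids
    cfg = benchmark.enrichment_config()
    blocks = [encode_network(ids, benchmark.network)]
    for key in ("kegg", "go"):
        blocks.append(
            encode_enrichment(ids, benchmark.network, benchmark.catalogs[key], cfg)
        )
    return concat_features(*blocks)


def screen_and_rank(
    features: FeatureMatrix,
    y,
    seed: int = 0,
    boruta_iterations: int = 100,
    boruta_alpha: float = 0.05,
) -> tuple[BorutaResult, RankedFeatureList | None]:
    """Boruta on the original samples, then mRMR over the survivors.

    If Boruta confirms nothing, tentative features are ranked instead;
    if nothing survives at all the ranking is None (no model can be
    built, a legitimate outcome on signal-free data).
    """
    result = boruta_filter(
        features, y, n_iterations=boruta_iterations, alpha=boruta_alpha, seed=seed
    )
    survivors = sorted(result.confirmed) or sorted(result.tentative)
    if not survivors:
        return result, None
    col = {n: j for j, n in enumerate(features.feature_names)}
    sub = FeatureMatrix(
        sample_ids=list(features.sample_ids),
        feature_names=survivors,
        values=features.values[:, [col[n] for n in survivors]],
        groups={n: features.groups.get(n, "other") for n in survivors},
    )
    ranked = mrmr_rank(sub, np.asarray(y))
    return result, ranked


def run_pipeline(
    benchmark: Benchmark,
    spec: ClassifierSpec | None = None,
    step: int = 5,
    cv_config: CVConfig | None = None,
    seed: int = 0,
    boruta_iterations: int = 100,
    compact_tolerance: float = 0.03,
) -> PipelineResult:
    """Full workflow on a synthetic benchmark."""
    spec = spec or ClassifierSpec(family="rf", seed=seed)
    cv_config = cv_config or CVConfig(seed=seed)
    y = np.asarray(benchmark.dataset.labels)
    features = encode_benchmark_features(benchmark)
    boruta, ranked = screen_and_rank(
        features, y, seed=seed, boruta_iterations=boruta_iterations
    )
    if ranked is None:
        return PipelineResult(features, boruta, ranked, None, None, None)
    # with fewer survivors than one step, evaluate the whole survivor set once
    step_eff = min(step, len(ranked))
    curve = run_ifs(ranked, features, y, spec, step=step_eff, cv_config=cv_config)
    return PipelineResult(
        features,
        boruta,
        ranked,
        curve,
        select_optimum(curve),
        select_compact(curve, compact_tolerance),
    )


def confirmed_precision(result: PipelineResult, truth: dict) -> float:
    """Fraction of Boruta-confirmed features that were actually planted."""
    confirmed = result.boruta.confirmed
    if not confirmed:
        return 0.0
    planted = set(truth["planted_features"])
    return len(confirmed & planted) / len(confirmed)


def extract_benchmark_rules(
    benchmark: Benchmark,
    result: PipelineResult,
    top_k: int | None = None,
    seed: int = 0,
) -> tuple[RuleSet, dict[str, int]]:
    """Fit a full-data CART tree on the optimum prefix and read off rules."""
    if result.ranked is None:
        raise ValueError("pipeline produced no ranked features")
    if top_k is None:
        top_k = result.optimum[0] if result.optimum else len(result.ranked)
    subset = result.ranked.names[:top_k]
    y = np.asarray(benchmark.dataset.labels)
    tree, names = fit_full_tree(
        result.features, y, subset, ClassifierSpec(family="dt", seed=seed)
    )
    rules = extract_rules(tree, names, sorted(benchmark.dataset.classes))
    return rules, rules_per_class(rules)
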