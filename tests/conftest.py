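import numpy as np
import pytest

from sublocnet import BenchmarkConfig, generate_benchmark
from sublocnet.pipeline import run_pipeline


@pytest.fixture(scope="session")
def recovery_runs():
    """Full pipeline (encode -> Boruta -> mRMR -> IFS, rf, step 5) on the
    default benchmark for three seeds. Shared across modules because each
    run takes tens of seconds."""
    runs = []
    for seed in (1, 2, 3):
        bench = generate_benchmark(BenchmarkConfig(seed=seed))
        runs.append((bench, run_pipeline(bench, seed=seed)))
    return runs


@pytest.fixture(scope="session")
def null_runs():
    """Same pipeline with p_in = p_out (no within-class network signal)."""
    runs = []
    for seed in (1, 2, 3):
        bench = generate_benchmark(BenchmarkConfig(seed=seed, p_in=0.02, p_out=0.02))
        runs.append((bench, run_pipeline(bench, seed=seed)))
    return runs


@pytest.fixture
def small_benchmark():
    """Quick benchmark for structural tests (not the study conditions)."""
    return generate_benchmark(
        BenchmarkConfig(
            n_classes=3,
            class_sizes=[20, 10, 5],
            hubs_per_class=3,
            background_nodes=20,
            terms_per_class=4,
            noise_terms=10,
            seq_len_range=(60, 120),
            seed=42,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
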