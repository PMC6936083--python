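import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sglrr import (
    SgLRRParams,
    SubspaceSpec,
    build_affinity,
    build_knn_graph,
    generate_subspace_data,
    repeated_cluster_metrics,
    solve_sglrr,
)

# study conditions of the reference synthetic experiment: three independent
# 4-dimensional subspaces in 50 dimensions, 40 samples each, sigma = 0.01
CLEAN_SPEC = dict(
    n_subspaces=3, subspace_dim=4, ambient_dim=50, samples_per_subspace=40,
    noise_sigma=0.01,
)
CORRUPTION = dict(corruption_fraction=0.05, corruption_scale=5.0)
# the corruption experiment weights: gamma sized to the corruption, graph
# term off because the kNN graph itself is built on corrupted columns
ROBUST_PARAMS = dict(gamma=0.025, beta=0.0)

N_SEEDS = 10


def pipeline_metrics(seed: int, corrupt: bool = False, n_repeats: int = 10, **param_overrides):
    """Generate a fixture, run solve -> affinity -> repeated Ncuts, return summary."""
    extra = CORRUPTION if corrupt else {}
    spec = SubspaceSpec(seed=seed, **CLEAN_SPEC, **extra)
    X, labels = generate_subspace_data(spec)
    params = SgLRRParams(**param_overrides)
    graph = build_knn_graph(X, params.k_neighbors)
    solution = solve_sglrr(X, graph, params)
    aff = build_affinity(solution.Z)
    summary = repeated_cluster_metrics(
        aff, spec.n_subspaces, labels, n_repeats=n_repeats, seed=seed
    )
    summary["solution"] = solution
    return summary


@pytest.fixture(scope="session")
def clean_fixture():
    """Seed-0 clean 3-subspace dataset."""
    spec = SubspaceSpec(seed=0, **CLEAN_SPEC)
    X, labels = generate_subspace_data(spec)
    return spec, X, labels


@pytest.fixture(scope="session")
def clean_solution(clean_fixture):
    """Default-parameter sgLRR solve of the seed-0 clean dataset."""
    _, X, _ = clean_fixture
    params = SgLRRParams()
    graph = build_knn_graph(X, params.k_neighbors)
    return solve_sglrr(X, graph, params)


@pytest.fixture(scope="session")
def clean_runs():
    """Default-parameter end-to-end metrics on the clean fixture, 10 seeds."""
    return [pipeline_metrics(seed) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def robustness_runs():
    """Clean vs corrupted end-to-end accuracy at the corruption-experiment weights."""
    clean = [pipeline_metrics(s, corrupt=False, **ROBUST_PARAMS) for s in range(N_SEEDS)]
    corrupted = [pipeline_metrics(s, corrupt=True, **ROBUST_PARAMS) for s in range(N_SEEDS)]
    return clean, corrupted


def random_partition_pairs(n_pairs: int = 100, max_n: int = 12, seed: int = 7):
    """Random label-vector pairs for metric-oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        n = int(rng.integers(2, max_n + 1))
        kt = int(rng.integers(1, min(4, n) + 1))
        kp = int(rng.integers(1, min(4, n) + 1))
        out.append((rng.integers(0, kt, size=n), rng.integers(0, kp, size=n)))
    return out
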