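from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldabf import WindowConfig, matrix_from_arrays
from ldabf.simeval import SimParams, run_benchmark

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix():
    """6 haplotypes x 3 sites: a perfect-LD pair flanking an independent site."""
    alleles = np.array(
        [
            [1, 0, 1],
            [1, 1, 1],
            [0, 0, 0],
            [0, 1, 0],
            [1, 0, 1],
            [0, 1, 0],
        ]
    )
    return matrix_from_arrays(alleles, positions=[100, 300, 500], chrom="1")


@pytest.fixture
def window():
    return WindowConfig(1000)


def random_matrix(rng, n_hap=None, n_sites=None, span=2000):
    """Random segregating haplotype matrix on unique positions."""
    n_hap = n_hap or int(rng.integers(4, 16)) * 2
    n_sites = n_sites or int(rng.integers(1, 12))
    positions = rng.choice(np.arange(1, span), size=n_sites, replace=False)
    cols = []
    for _ in range(n_sites):
        c = rng.integers(0, 2, size=n_hap)
        while c.sum() in (0, n_hap):
            c = rng.integers(0, 2, size=n_hap)
        cols.append(c)
    return matrix_from_arrays(np.column_stack(cols), positions)


# Scaled-down power benchmark shared by the acceptance tests: the matched
# neutral arm plus the stable eq-0.25 and eq-0.5 balancing arms at the
# "younger" timescale, lambda = 50 rescaling, 200 replicates per arm.
BENCH_SEED = 11
BENCH_REPLICATES = 200


@pytest.fixture(scope="session")
def benchmark_result():
    scenarios = {
        "neutral": None,
        "eq25": SimParams(s=-0.01, h=-0.5, rescale_factor=50.0),
        "eq50": SimParams(s=0.01, h=100.0, rescale_factor=50.0),
    }
    return run_benchmark(
        scenarios,
        stats=("ld_abf", "tajimas_d"),
        n_replicates=BENCH_REPLICATES,
        seed=BENCH_SEED,
    )
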