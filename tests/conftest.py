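import numpy as np
import pandas as pd
import pytest

from eqtlnet.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic cohort shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast cohort for pipeline-level tests."""
    return simulate_dataset(
        SimConfig(
            seed=11,
            n_samples=120,
            n_variants=120,
            n_genes=80,
            n_cis_pairs=10,
            hotspot_n_targets=20,
        )
    )


def make_blocks(seed, n_samples=200, per_block=50, n_noise=50, loading=0.8):
    """Two planted co-expression blocks plus independent noise genes.

    Returns (expression genes x samples, truth labels 1/2/0).
    """
    rng = np.random.default_rng(seed)
    f1, f2 = rng.standard_normal(n_samples), rng.standard_normal(n_samples)
    genes = [loading * f1 + rng.standard_normal(n_samples) for _ in range(per_block)]
    genes += [loading * f2 + rng.standard_normal(n_samples) for _ in range(per_block)]
    genes += [rng.standard_normal(n_samples) for _ in range(n_noise)]
    X = pd.DataFrame(
        np.asarray(genes),
        index=[f"g{i:03d}" for i in range(len(genes))],
        columns=[f"s{i:03d}" for i in range(n_samples)],
    )
    truth = np.array([1] * per_block + [2] * per_block + [0] * n_noise)
    return X, truth
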