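import numpy as np
import pytest

import commresist as cr


@pytest.fixture
def tiny_counts():
    return cr.CountTable(
        ("OTU1", "OTU2", "OTU3"), ("A", "B"), np.array([[5, 0], [1, 2], [0, 3]])
    )


@pytest.fixture
def env_1d_pair():
    """Two samples at standardized 1-D coordinates -1 and +1."""
    return cr.StandardizedEnv(("A", "B"), ("v",), np.array([[-1.0], [1.0]]))


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated community, shared across the suite."""
    return cr.generate_community(cr.scenario_default())


@pytest.fixture(scope="session")
def default_tb(default_sim):
    std = cr.standardize_env(default_sim.env)
    return cr.tolerance_breadth_all(default_sim.counts, std)


@pytest.fixture(scope="session")
def default_ra(default_sim):
    rel = cr.to_relative_abundance(default_sim.counts)
    return cr.spearman_matrix(rel)


def random_count_table(rng, n_otus, n_samples, max_count=50):
    counts = rng.integers(0, max_count, size=(n_otus, n_samples))
    # ensure no empty OTU rows or sample columns
    for m in np.nonzero(counts.sum(axis=1) == 0)[0]:
        counts[m, rng.integers(n_samples)] = 1
    for j in np.nonzero(counts.sum(axis=0) == 0)[0]:
        counts[rng.integers(n_otus), j] = 1
    return cr.CountTable(
        tuple(f"O{m}" for m in range(n_otus)),
        tuple(f"S{j}" for j in range(n_samples)),
        counts,
    )


def random_std_env(rng, n_samples, n_vars):
    values = rng.normal(size=(n_samples, n_vars))
    values -= values.mean(axis=0)
    values /= values.std(axis=0, ddof=1)
    return cr.StandardizedEnv(
        tuple(f"S{j}" for j in range(n_samples)),
        tuple(f"v{i}" for i in range(n_vars)),
        values,
    )


def brute_force_tb(counts, env):
    """Independent oracle: explicit weighted-centroid then weighted-mean-distance loop."""
    out = np.empty(counts.n_otus)
    for m in range(counts.n_otus):
        a = counts.counts[m].astype(float)
        occ = np.nonzero(a > 0)[0]
        centroid = np.zeros(env.values.shape[1])
        for j in occ:
            centroid += a[j] * env.values[j]
        centroid /= a[occ].sum()
        z = 0.0
        for j in occ:
            z += a[j] * np.sqrt(((env.values[j] - centroid) ** 2).sum())
        out[m] = z / a[occ].sum()
    return out
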