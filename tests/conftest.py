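import numpy as np
import pytest

import mcascreen as m


@pytest.fixture(scope="session")
def small_probe_map():
    """Two chromosomes x 600 probes, 80 Mb each."""
    return m.make_probe_map(2, 600, 80_000_000, seed=1)


@pytest.fixture(scope="session")
def small_arm_map():
    return m.make_arm_map(2, 80_000_000)


@pytest.fixture(scope="session")
def full_probe_map():
    """Array-scale scaffold: 22 chromosomes x 2000 probes, 100 Mb each."""
    return m.make_probe_map(22, 2000, 100_000_000, seed=1)


@pytest.fixture(scope="session")
def full_arm_map():
    return m.make_arm_map(22, 100_000_000)


def naive_split_scan(v, min_points):
    """Exhaustive single-split search: argmax of the pooled two-sample
    t statistic, computed independently of the production scan."""
    v = np.asarray(v, float)
    n = v.size
    best_k, best_t = -1, 0.0
    for k in range(min_points, n - min_points + 1):
        left, right = v[:k], v[k:]
        ml, mr = left.mean(), right.mean()
        ss = ((left - ml) ** 2).sum() + ((right - mr) ** 2).sum()
        pooled = ss / max(n - 2, 1)
        denom = np.sqrt(max(pooled * (1 / k + 1 / (n - k)), 1e-300))
        t = abs(ml - mr) / denom
        if t > best_t:
            best_k, best_t = k, t
    return best_k, best_t
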