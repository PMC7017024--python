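import math

import numpy as np
import pytest

from cckit import ccparse, ccquant, simdata


def fisher_oracle(k1, n1, k2, n2):
    """Two-sided Fisher p by full enumeration of 2x2 tables with fixed margins."""
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
            if max(0, c1 - (n - r1)) <= x <= min(r1, c1)
            else 0.0
        )

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(min(r1, c1) + 1) if pmf(x) <= p_obs * (1 + 1e-9))


@pytest.fixture(scope="session")
def scenario():
    """Standard synthetic study: 200 kb, 40 genes, 12 bound, 5000 events."""
    return simdata.make_callingcard_scenario(seed=1)


@pytest.fixture(scope="session")
def events(scenario):
    return simdata.simulate_insertions(scenario.genome, scenario.model, "wt_rep1", seed=11)


@pytest.fixture(scope="session")
def sites(events):
    return ccquant.collapse_umis(events)


@pytest.fixture(scope="session")
def small_genome():
    """10 kb single-chromosome genome with 3 planted consensus sites."""
    return simdata.make_genome(1, 10_000, 3, seed=7, ensure_near_ttaa=100)


@pytest.fixture(scope="session")
def genome_index(small_genome):
    return ccparse.GenomeIndex(small_genome.sequences)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
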