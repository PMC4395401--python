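import numpy as np
import pandas as pd
import pytest

from arraymap import SimConfig, simulate_ril_population
from arraymap.simulate import simulate_array_signals


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_chromosomes=2, chrom_length_cm=(90.0, 80.0), chrom_length_mb=(25.0, 20.0),
        n_markers=(120, 80), n_rils=60, seed=3)


@pytest.fixture(scope="session")
def small_population(small_config):
    calls, truth = simulate_ril_population(small_config)
    return calls, truth


@pytest.fixture(scope="session")
def small_signals(small_config, small_population):
    calls, _ = small_population
    return simulate_array_signals(calls, small_config)


@pytest.fixture(scope="session")
def map_config():
    """Single chromosome at the map-recovery benchmark size."""
    return SimConfig(n_chromosomes=1, chrom_length_cm=100.0, chrom_length_mb=30.0,
                     n_markers=200, n_rils=120, seed=5)


def random_calls(n_markers, n_samples, rng, p=(0.49, 0.02, 0.49)):
    """iid genotype matrix used by filtering tests."""
    vals = rng.choice(["AA", "AB", "BB"], size=(n_markers, n_samples), p=p)
    return pd.DataFrame(vals,
                        index=[f"m{i:04d}" for i in range(n_markers)],
                        columns=[f"S{j:03d}" for j in range(n_samples)])
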