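import numpy as np
import pytest

import brcalike as bl


@pytest.fixture(scope="session")
def small_genome():
    return bl.SimGenome({"1": 10_000_000, "2": 10_000_000}, bin_size=20_000)


@pytest.fixture(scope="session")
def small_bins(small_genome):
    """1000-bin annotated grid shared across tests."""
    return bl.make_bin_grid(small_genome, seed=1)


@pytest.fixture(scope="session")
def medium_genome():
    """4 x 25 Mb autosomes: 5000 bins at 20 kb."""
    return bl.SimGenome({str(c): 25_000_000 for c in range(1, 5)}, bin_size=20_000)


@pytest.fixture(scope="session")
def medium_bins(medium_genome):
    return bl.make_bin_grid(medium_genome, seed=11)


@pytest.fixture(scope="session")
def flat_profile_inputs(medium_bins):
    """Flat-copy counts with a quadratic GC bias at depth 100."""
    counts = bl.simulate_counts(
        medium_bins, np.zeros(len(medium_bins)), mean_depth=100,
        gc_bias=(0.0, 1.2, -1.2), seed=12,
    )
    return medium_bins, counts
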