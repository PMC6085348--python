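import numpy as np
import pytest

from stormtrace import synthetic as syn


@pytest.fixture(scope="session")
def ref10():
    """Small two-pool reference: 10 gut + 10 environment organisms."""
    return syn.make_reference(seed=1, n_gut=10, n_env=10)


@pytest.fixture(scope="session")
def gradient_table(ref10):
    """40-sample contamination gradient (f from 0.005 to 0.5) with its profiles."""
    fs = np.geomspace(0.005, 0.5, 40)
    profiles = [
        syn.compose_community(ref10, f, 100 + i, sample_id=f"S{i + 1:03d}")
        for i, f in enumerate(fs)
    ]
    table = syn.simulate_amplicon_table(profiles, ref10, depth=10_000, seed=7)
    return table, profiles


@pytest.fixture(scope="session")
def two_group_table(ref10):
    """Six contaminated (f=0.3) and six clean (f=0) samples, one table.

    A high within-pool Dirichlet concentration gives the samples a shared
    background community, as stormwater from one catchment would have.
    """
    profiles = [
        syn.compose_community(ref10, 0.3, 200 + i, sample_id=f"C{i + 1}",
                              dirichlet_conc=20.0)
        for i in range(6)
    ] + [
        syn.compose_community(ref10, 0.0, 300 + i, sample_id=f"U{i + 1}",
                              dirichlet_conc=20.0)
        for i in range(6)
    ]
    table = syn.simulate_amplicon_table(profiles, ref10, depth=5_000, seed=9)
    groups = {
        "contaminated": [f"C{i + 1}" for i in range(6)],
        "clean": [f"U{i + 1}" for i in range(6)],
    }
    return table, groups
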