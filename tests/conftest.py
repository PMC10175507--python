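"""Shared fixtures: stimulus protocols and small synthetic datasets.

Everything is generated programmatically and seeded, so the suite is
deterministic and carries no stored data.
"""

import pytest

from spectint import build_protocol, process_dataset
from spectint.synth import make_cell, simulate_population


@pytest.fixture(scope="session")
def protocol_nofm():
    return build_protocol(seed=11, include_fm=False)


@pytest.fixture(scope="session")
def protocol_fm():
    return build_protocol(seed=11, include_fm=True)


@pytest.fixture(scope="session")
def noise_free_cell():
    return make_cell("a2_coincident", seed=[3, 0, 0], trial_noise_cv=0.0,
                     baseline_sd=0.0, include_fm=True)


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_cell, protocol_fm):
    ts = simulate_population([noise_free_cell], protocol_fm, seed=3)
    rt = process_dataset(ts, min_baseline_sd=1e-9)
    return ts, rt


@pytest.fixture(scope="session")
def noisy_population(protocol_fm):
    """12 a1-type cells at study noise levels, processed end to end."""
    cells = [make_cell("a1_asymmetric", seed=[9, i, 0], dsi_coupling=0.3)
             for i in range(12)]
    ts = simulate_population(cells, protocol_fm, seed=9)
    rt = process_dataset(ts)
    return cells, ts, rt
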