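import numpy as np
import pytest

import straudit as sa


@pytest.fixture(scope="session")
def tally_records():
    """Comparison records reconstructing the register audit's error tally."""
    return sa.records_from_tally()


@pytest.fixture(scope="session")
def small_register():
    """A default-shape synthetic register (234 individuals) with its truth."""
    design = sa.SimulationDesign.default(seed=123)
    params = sa.TrueModelParams()
    true_p, obs_p = sa.simulate_register(design, params, seed=11)
    return design, params, true_p, obs_p


@pytest.fixture(scope="session")
def small_records(small_register):
    _, _, true_p, obs_p = small_register
    return sa.compare_profiles(obs_p, true_p)


@pytest.fixture(scope="session")
def m1_spec():
    return sa.ModelSpec(frozenset({"LOCUS", "YEAR"}), frozenset({"IND"}))


@pytest.fixture(scope="session")
def m1_fit(small_records, m1_spec):
    """M1 fitted once to the synthetic register; reused across tests."""
    data = sa.build_design(small_records, m1_spec)
    return data, sa.fit(data, order=20)
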