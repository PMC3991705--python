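import copy

import pytest

from trialcea import UnitCostTable, generate_trial, rossini_default


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable.from_csv()


@pytest.fixture(scope="session")
def default_config():
    return rossini_default()


@pytest.fixture(scope="session")
def trial(default_config):
    """One full-size calibrated trial table (369 + 366 patients)."""
    return generate_trial(default_config, seed=42)


def small_config(n_i=60, n_c=60, **overrides):
    """A down-scaled copy of the default profile for fast tests."""
    cfg = copy.deepcopy(rossini_default())
    cfg.n_per_arm = (n_i, n_c)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def no_missingness_config(n_i=80, n_c=80):
    cfg = small_config(n_i, n_c)
    for spec in cfg.missingness.values():
        for arm in cfg.arm_labels:
            spec[arm] = 0.0
    cfg.mortality_rate = {a: 0.0 for a in cfg.arm_labels}
    return cfg


@pytest.fixture()
def complete_small_trial():
    """Small trial with no missingness and no deaths."""
    return generate_trial(no_missingness_config(), seed=5)
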