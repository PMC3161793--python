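import dataclasses

import pytest

from avpercept.preprocess import normalize_localizations
from avpercept.synthetic_data import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def default_table():
    """One default-calibration dataset (10 subjects x 2 tasks x 450 trials)."""
    return normalize_localizations(simulate_dataset(SimParams(seed=11)))


@pytest.fixture(scope="session")
def quiet_params():
    """Near-noiseless calibration: deterministic percepts and times."""
    return dataclasses.replace(
        SimParams(seed=5),
        bias_sd=0.0, sigma_a_uni=1e-9, sigma_a_bi=1e-9, sigma_v_uni=1e-9,
        sigma_v_bi=1e-9, sigma_jitter_sd=0.0, w_sd=0.0,
        delta_ecc_sd=0.0, sigma_logT=1e-9, sigma_logT_jitter_sd=0.0,
        subject_T_offset_sd=0.0)


@pytest.fixture(scope="session")
def quiet_table(quiet_params):
    return normalize_localizations(simulate_dataset(quiet_params))
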