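import numpy as np
import pandas as pd
import pytest

from tgios.synthetic_data import GeneratorConfig, generate_trial

TGI_TRUTH_THETA = {
    "kg_treatment": 0.00196,
    "ks_treatment": 0.0342,
    "kg_control": 0.00438,
    "ks_control": 0.0373,
    "ts0": 57.0,
}
TGI_TRUTH_OMEGA2 = {
    "kg_treatment": 1.90,
    "ks_treatment": 0.943,
    "kg_control": 1.10,
    "ks_control": 0.833,
    "ts0": 0.436,
}
TGI_TRUTH_SIGMA2 = 42.5

OS_TRUTH = {
    "intercept": 2.87,
    "log_kg": -0.642,
    "albumin": 0.0262,
    "ecog_ge1": -0.270,
    "race_asian": 0.319,
    "n_met_sites": -0.0733,
    "nlr": -0.0138,
    "liver_met_yes": -0.174,
    "baseline_sld": -0.00122,
    "line_2plus": -0.103,
    "sex_female": 0.0840,
    "log_scale": -0.225,
}


@pytest.fixture(scope="session")
def tiny_trial():
    """Small but complete virtual trial (fast enough for unit tests)."""
    cfg = GeneratorConfig(n_per_arm=20, n_baseline_only=3,
                          max_followup_weeks=80.0, seed=7)
    return generate_trial(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
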