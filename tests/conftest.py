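import numpy as np
import pandas as pd
import pytest

from anginatrial import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A modest complete trial reused by read-only tests."""
    return generate_trial(TrialConfig(n_per_arm=30, seed=123))


@pytest.fixture(scope="session")
def oracle_dataset():
    """Fixed n=12 three-category dataset with one binary covariate.

    Small enough for brute-force likelihood maximization, rich enough
    to identify two thresholds and one slope.
    """
    y = [0, 0, 1, 2, 1, 0, 2, 2, 1, 0, 1, 2]
    t = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
    return np.array(y, dtype=float), np.array(t, dtype=float)


def make_diary(patient_id, pre_episodes, fu_episodes, fu_meds=None, overrides=None):
    """Assemble a single-patient diary frame from day-value lists."""
    pre_days = len(pre_episodes)
    fu_days = len(fu_episodes)
    fu_meds = fu_meds if fu_meds is not None else [0] * fu_days
    overrides = overrides if overrides is not None else ["none"] * fu_days
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "day": list(range(-pre_days, 0)) + list(range(1, fu_days + 1)),
            "episodes": [float(e) for e in pre_episodes]
            + [float(e) if e is not None else np.nan for e in fu_episodes],
            "med_units": [0] * pre_days + list(fu_meds),
            "override": ["none"] * pre_days + list(overrides),
        }
    )
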