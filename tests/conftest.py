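import numpy as np
import pandas as pd
import pytest

from alphalat import GeneratorConfig, generate_dataset, make_sensor_array
from alphalat.dataset import SubjectData, TRIAL_COLUMNS


@pytest.fixture(scope="session")
def grid30():
    return make_sensor_array(30, "grid")


@pytest.fixture(scope="session")
def small_dataset():
    """Small paper-preset dataset shared by read-only tests."""
    cfg = GeneratorConfig.preset("paper", n_subjects=4, n_trials_per_condition=12, seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_subject(
    data,
    pre_target=None,
    rt=None,
    gaze=None,
    fs=300.0,
    hemifield=None,
    difficulty=None,
    eccentricity=None,
):
    """Hand-built SubjectData for rule-level tests.

    ``data`` is (n_trials, n_sensors, n_samples); omitted metadata falls
    back to innocuous defaults that no rejection rule fires on.
    """
    data = np.asarray(data, dtype=np.float32)
    n_tr, _, n_samp = data.shape
    if pre_target is None:
        pre_target = np.full(n_tr, n_samp / fs - 2.0)
    if rt is None:
        rt = np.full(n_tr, 0.6)
    if gaze is None:
        gaze = np.zeros((n_tr, 2, n_samp), dtype=np.float32)
    if hemifield is None:
        hemifield = np.resize(["left", "right"], n_tr)
    if difficulty is None:
        difficulty = np.resize(["easy"], n_tr)
    if eccentricity is None:
        eccentricity = np.resize(["near"], n_tr)
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_tr),
            "difficulty": difficulty,
            "eccentricity": eccentricity,
            "hemifield": hemifield,
            "pre_target_period": np.asarray(pre_target, dtype=float),
            "correct": np.ones(n_tr, dtype=bool),
            "rt": np.asarray(rt, dtype=float),
            "true_effect": np.zeros(n_tr),
        }
    )[TRIAL_COLUMNS]
    return SubjectData(
        subject="T01", trials=trials, data=data, gaze=np.asarray(gaze, np.float32), fs=fs
    )
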