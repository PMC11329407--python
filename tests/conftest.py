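import numpy as np
import pytest

import kneedeg as kd
from kneedeg.geometry import TEMPLATE_MEASUREMENTS


@pytest.fixture(scope="session")
def medial_template():
    return kd.build_template("medial")


@pytest.fixture(scope="session")
def lateral_template():
    return kd.build_template("lateral")


@pytest.fixture(scope="session")
def template_measurements():
    return TEMPLATE_MEASUREMENTS


@pytest.fixture(scope="session")
def small_cohort():
    return kd.generate_cohort(10, seed=42)


@pytest.fixture(scope="session")
def gait_curve():
    return kd.reference_curve()


@pytest.fixture(scope="session")
def trained_predictor():
    table = kd.make_training_table(500, seed=3)
    return kd.train_peak_predictor(table, seed=3)


@pytest.fixture(scope="session")
def median_subject():
    """A subject at the cohort median of every demographic variable."""
    return kd.Subject(
        id="median",
        age=58.0,
        sex="female",
        mass=73.6,
        height=166.5,
        walking_speed=1.37,
        joint_alignment=5.14,
        knee_side="right",
        kl_baseline=0,
        kl_followup=2,
    )


class ConstantPredictor:
    """Stub predictor returning fixed body-weight peaks."""

    def __init__(self, medial, lateral, total):
        self._peaks = (medial, lateral, total)

    def predict_subject(self, subject):
        return self._peaks


@pytest.fixture
def constant_predictor():
    return ConstantPredictor
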