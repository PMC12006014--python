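import numpy as np
import pandas as pd
import pytest

from cihmet import synthio


@pytest.fixture()
def study_spec():
    """The emulated cohort layout: 63 patients, 19 cases, coverage 54/49/44."""
    return synthio.default_cohort_spec(seed=11)


@pytest.fixture()
def small_views(study_spec):
    """Three small views with planted effects and biomarkers, plus truth."""
    truth = synthio.plan_truth(
        study_spec,
        {"CRT": 40, "plasma": 40, "urine": 40},
        n_dems=10,
        n_biomarkers=3,
        biomarker_log2fc=2.0,
    )
    views, metadata, mask = synthio.generate_views(study_spec, truth, noise_sd=1.0, missing_rate=0.05)
    return views, metadata, mask, truth


@pytest.fixture()
def printed_cohort():
    """A 63-patient metadata table reproducing the published cross-tabulation.

    Cells: males 30 normal / 12 case, females 14 / 7; BMI<24 30 / 9,
    BMI>=24 14 / 10; age<60 22 / 11, age>=60 22 / 8.
    """
    rows = []
    # (group, gender, n_male_cell) layout chosen so each marginal matches
    def add(n, group, gender, age, bmi):
        rows.extend({"group": group, "gender": gender, "age": age, "bmi": bmi} for _ in range(n))

    # normal (44): 30 male / 14 female; 22 under 60 / 22 over; 30 bmi<24 / 14 >=
    add(22, 0, "male", 50, 20)     # male, <60, bmi<24
    add(8, 0, "male", 65, 22)      # male, >=60, bmi<24
    add(14, 0, "female", 65, 30)   # female, >=60, bmi>=24
    # case (19): 12 male / 7 female; 11 under 60 / 8 over; 9 bmi<24 / 10 >=
    add(9, 1, "male", 50, 20)      # male, <60, bmi<24
    add(2, 1, "male", 50, 30)      # male, <60, bmi>=24
    add(1, 1, "male", 65, 30)      # male, >=60, bmi>=24
    add(7, 1, "female", 65, 30)    # female, >=60, bmi>=24
    meta = pd.DataFrame(rows, index=[f"P{i:03d}" for i in range(len(rows))])
    assert len(meta) == 63
    return meta


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
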