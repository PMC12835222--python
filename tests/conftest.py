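import warnings

import numpy as np
import pandas as pd
import pytest

from hemidiff.containers import CountMatrix
from hemidiff.de import run_two_stage
from hemidiff.presets import simulated_study_config
from hemidiff.samples import derive_severity
from hemidiff.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def cohort7():
    """Default study cohort: 14 PD + 10 control subjects, planted effects,
    40% of subjects with inverted module asymmetry."""
    return simulate_cohort(CohortSpec(seed=7, frac_sign_flip_subjects=0.4))


@pytest.fixture(scope="session")
def study_cfg():
    return simulated_study_config()


@pytest.fixture(scope="session")
def two_stage7(cohort7, study_cfg):
    counts, samples, _ = cohort7
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_two_stage(counts, samples, study_cfg)


@pytest.fixture
def tiny_counts():
    return CountMatrix(["gA", "gB"], ["s1", "s2"], np.array([[0, 1], [2, 3]]))


@pytest.fixture
def hand_sheet():
    """Two PD subjects (right / left onset) and one control, severity not
    yet derived."""
    rows = []
    for subj, status, onset, sex in [
        ("P1", "PD", "right", "male"),
        ("P2", "PD", "left", "female"),
        ("C1", "control", "NA", "female"),
    ]:
        for hemi in ("left", "right"):
            rows.append(
                {
                    "sample_id": f"{subj}_{hemi[0]}",
                    "subject_id": subj,
                    "hemisphere": hemi,
                    "status": status,
                    "onset_side": onset if status == "PD" else np.nan,
                    "sex": sex,
                    "age": 70.0,
                    "duration": 8.0 if status == "PD" else 0.0,
                    "rin": 7.0,
                    "library_size": 1_000_000,
                    "nuclei_per_mg": 5000.0,
                    "pmi": 10.0,
                    "braak": 2.5 if status == "PD" else 0.0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def hand_sheet_severity(hand_sheet):
    return derive_severity(hand_sheet)
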