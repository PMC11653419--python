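import numpy as np
import pandas as pd
import pytest

from uvsdt.synthetic import GroundTruth, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_cohort_csv(tmp_path):
    """Three-participant cohort file with one missing post-treatment score."""
    text = (
        "participant_id,age,sex,hearing_loss,thi_baseline,thi_post,ghsi_baseline,"
        "decision_sedep,decision_sedu,decision_pcu,tinnitus_duration,"
        "non_hearing_problems,tinnitus_type,referring_specialty\n"
        "P1,55,male,60,48,30,50,yes,yes,no,>6mo,none,tonal,orl\n"
        "P2,43,female,20,58,NA,40,no,not_applicable,yes,2-6mo,family,noise,gp\n"
        "P3,61,male,80,34,40,70,yes,no,no,>6mo,none,different,NA\n"
    )
    path = tmp_path / "toy.csv"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def complete_cohort():
    """Mid-sized synthetic cohort with no missingness, plus its truth table."""
    truth = GroundTruth(n=2000, missing_rates={}, seed=7)
    table, truth_table = simulate_cohort(truth)
    return truth, table, truth_table


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study conditions (n=145, MCAR missingness)."""
    truth = GroundTruth(seed=11)
    table, truth_table = simulate_cohort(truth)
    return truth, table, truth_table
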