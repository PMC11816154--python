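import numpy as np
import pytest

from lnaspire.cohort import (default_cohort_config, prior_median_truth,
                             PatientTruth)
from lnaspire.panels import (CHAR_ANTIGENS, characterization_panel,
                             identification_panel)
from lnaspire.templates import VIABLE_POPULATIONS


@pytest.fixture(scope="session")
def id_panel():
    return identification_panel()


@pytest.fixture(scope="session")
def char_panel():
    return characterization_panel()


def make_truth(group="NSCLC", seed=424242, antigens=None, **fractions):
    """PatientTruth with explicit population fractions (rest set to zero).

    Unspecified mass goes to neutrophils so the fractions always sum to 1.
    """
    fracs = {p: 0.0 for p in VIABLE_POPULATIONS}
    fracs.update({"debris": 0.0, "dead": 0.0})
    fracs.update(fractions)
    rest = 1.0 - sum(fracs.values())
    assert rest > -1e-12
    fracs["neutrophil"] += max(rest, 0.0)
    ag = {a: 0.5 for a in CHAR_ANTIGENS}
    if antigens:
        ag.update(antigens)
    return PatientTruth(patient_id=f"{group}-test", group=group,
                        population_fractions=fracs,
                        antigen_positive_fractions=ag,
                        wbc_per_ul=1000.0, seed=seed)


@pytest.fixture(scope="session")
def nsclc_median_truth():
    return prior_median_truth(default_cohort_config("NSCLC", master_seed=123))


@pytest.fixture(scope="session")
def sclc_median_truth():
    return prior_median_truth(default_cohort_config("SCLC", master_seed=123))
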