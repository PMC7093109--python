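import numpy as np
import pandas as pd
import pytest

from smokemort.riskmath import AgeBand
from smokemort.synthetic import StratumConfig, SyntheticCohortConfig, simulate_vital_stats


def make_cohort_config(
    population=100_000,
    p_current=0.3,
    p_former=0.0,
    noise="none",
    seed=0,
    rates=None,
    rr_current=None,
    rr_former=None,
    n_strata=1,
):
    rates = rates or {
        "lung_cancer": 0.0005,
        "coronary_heart_disease": 0.003,
        "other_cancers": 0.001,
    }
    rr_current = rr_current or {
        "lung_cancer": 20.0,
        "coronary_heart_disease": 3.0,
        "other_cancers": 2.0,
    }
    strata = tuple(
        StratumConfig(
            country="X",
            sex="male" if i % 2 == 0 else "female",
            age_band=AgeBand(35 + 10 * i, 45 + 10 * i),
            population=population,
            prevalence_current=p_current,
            prevalence_former=p_former,
        )
        for i in range(n_strata)
    )
    return SyntheticCohortConfig(
        strata=strata,
        baseline_never_rates=rates,
        rr_current=rr_current,
        rr_former=rr_former,
        noise=noise,
        seed=seed,
    )


@pytest.fixture
def noiseless_sim():
    return simulate_vital_stats(make_cohort_config(n_strata=2))


def microsim_oracle(population, p_current, never_rates, rr_current):
    """Per-individual brute-force attribution oracle.

    Assigns every individual a smoking status and cause-specific hazard,
    then counts expected deaths and the smoker excess, one person at a
    time.  Deliberately independent of the package's rate algebra.
    """
    n_smokers = int(round(p_current * population))
    is_smoker = np.zeros(population, dtype=bool)
    is_smoker[:n_smokers] = True
    deaths = {}
    attributable = {}
    for cause, never_rate in never_rates.items():
        hazard = np.where(is_smoker, never_rate * rr_current[cause], never_rate)
        deaths[cause] = float(hazard.sum())
        attributable[cause] = float((hazard[is_smoker] - never_rate).sum())
    return deaths, attributable


@pytest.fixture
def oracle():
    return microsim_oracle
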