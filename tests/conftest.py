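import numpy as np
import pandas as pd
import pytest

import neovanc as nv


@pytest.fixture(scope="session")
def pop():
    """Final-model population parameters (package defaults)."""
    return nv.PopulationParameters()


@pytest.fixture(scope="session")
def pk_typical():
    """Disposition parameters of a typical 1.68-kg subject."""
    return nv.PKParameters(cl=0.1612, vc=1.292, q=0.2169, vp=0.4788)


def make_doses(n=6, dose=23.5, interval=8.0, duration=1.0, start=0.0):
    return [nv.DoseEvent(start + i * interval, dose, duration, occasion=1)
            for i in range(n)]


@pytest.fixture
def simple_subject():
    """One q8h course with a trough and a peak sample and full covariates."""
    doses = make_doses(6)
    covs = [nv.CovariateRecord(d.time, body_weight=1.68, serum_creatinine=42.0,
                               pma=236.0 + d.time / 24.0) for d in doses]
    obs = [nv.ConcObservation(23.9, 11.2), nv.ConcObservation(25.0, 27.9)]
    return nv.SubjectRecord("S1", dose_events=doses, observations=obs,
                            covariate_series=covs, sex="F", birth_weight=1.32,
                            gestational_age=210.0)


@pytest.fixture(scope="session")
def small_cohort(pop):
    """20 synthetic subjects with simulated trough+peak observations."""
    cohort, truth = nv.generate_cohort(20, seed=1234)
    cohort = nv.simulate_observations(cohort, truth, pop, seed=1235)
    return cohort, truth


def make_table(rows):
    """Event-record DataFrame from a list of partial row dicts."""
    from neovanc.dataio import COLUMNS
    return pd.DataFrame(rows, columns=COLUMNS)
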