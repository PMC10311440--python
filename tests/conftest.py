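import numpy as np
import pandas as pd
import pytest

import erlurbi as e


@pytest.fixture(scope="session")
def atlantis_cohort_5000():
    """Large combination-arm cohort with exposures at the approved doses."""
    df = e.generate_covariates(5000, e.atlantis_experimental_profile(), seed=42)
    return e.assign_exposures(df, e.RegimenSpec(2.0, 40.0), seed=42)


@pytest.fixture(scope="session")
def os_sim_2000():
    """One simulated survival dataset from the published OS truth (n=2000)."""
    return e.simulate_os_dataset(2000, seed=7)


@pytest.fixture(scope="session")
def os_design_2000(os_sim_2000):
    d = e.os_design_matrix(os_sim_2000)
    d["time"] = os_sim_2000["time"].to_numpy()
    d["event"] = os_sim_2000["event"].to_numpy()
    d["censor_time"] = os_sim_2000["censor_time"].to_numpy()
    return d


@pytest.fixture(scope="session")
def os_fit_2000(os_design_2000):
    return e.fit_parametric_os(os_design_2000, "log-logistic", e.OS_COVARIATES)


@pytest.fixture(scope="session")
def orr_sim_2000():
    return e.simulate_orr_dataset(2000, seed=11)


@pytest.fixture(scope="session")
def orr_fit_2000(orr_sim_2000):
    return e.fit_emax_orr(orr_sim_2000)


def toy_surv_df(times, events, **covs):
    d = {"time": np.asarray(times, float), "event": np.asarray(events, int)}
    d.update({k: np.asarray(v, float) for k, v in covs.items()})
    return pd.DataFrame(d)
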