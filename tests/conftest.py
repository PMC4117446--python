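import numpy as np
import pandas as pd
import pytest

import onsetgwas as og


@pytest.fixture(scope="session")
def default_model():
    return og.default_prevalence_model()


@pytest.fixture(scope="session")
def small_cohort():
    """Two-centre cohort reused by read-only tests."""
    cfg = og.SimulationConfig(seed=11, n_centres=2, n_cases=300, n_controls=300,
                              m_snps=120, n_causal=10)
    return og.simulate_cohort(cfg)


@pytest.fixture()
def flat_model():
    """Constant prevalence across all ages (liability degenerates to status)."""
    return og.PrevalenceModel(
        age_grid=np.array([40.0, 90.0]),
        prevalence=np.array([0.08, 0.08]),
    )


def centres_dict(cohort):
    return {
        c: (cohort.phenotypes[cohort.phenotypes.centre == c].reset_index(drop=True),
            cohort.panels[c])
        for c in cohort.panels
    }


@pytest.fixture(scope="session")
def small_centres(small_cohort):
    return centres_dict(small_cohort)
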