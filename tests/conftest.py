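import numpy as np
import pytest

from voltraj import normative_model as nm
from voltraj import synthetic_data as sd
from voltraj.study_table import load_packaged_study_table


@pytest.fixture(scope="session")
def table_records():
    return load_packaged_study_table()


@pytest.fixture(scope="session")
def default_config():
    return sd.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def ft_scans(default_config):
    """One default 880-subject reference cohort."""
    return sd.generate_ft_cohort(default_config)


@pytest.fixture(scope="session")
def gmv_fit(ft_scans):
    return nm.fit_hybrid(ft_scans, "GMV")


@pytest.fixture(scope="session")
def gmv_band(gmv_fit):
    return nm.confidence_band(gmv_fit, nm.default_age_grid(), 0.95)


@pytest.fixture(scope="session")
def age_grid():
    return nm.default_age_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
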