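import numpy as np
import pytest

import sweetwin as sw


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


SMALL_CSV = """family_id,twin_order,zygosity,sex,age,cohort,liking,fl_sweet
F001,1,MZ,F,30,UK,60,4
F001,2,MZ,F,30,UK,70,5
F002,1,DZ_SS,M,25,UK,40,NA
F002,2,DZ_SS,M,25,UK,55,3
F003,1,DZ_OS,F,28,UK,80,6
"""


@pytest.fixture
def small_csv(tmp_path):
    p = tmp_path / "cohort.csv"
    p.write_text(SMALL_CSV)
    return p


@pytest.fixture
def small_cohort(small_csv):
    return sw.read_long_table(
        small_csv, {"liking": (0, 120), "fl_sweet": (1, 7)}
    )


@pytest.fixture(scope="session")
def uk_cohort():
    """One British-like simulated cohort, age-centered, with status labels."""
    spec = sw.preset("uk_like")
    co = sw.center_covariates(sw.simulate_cohort(spec, seed=11))
    return sw.discretize_status(co, "liking", spec.thresholds)


@pytest.fixture(scope="session")
def uk_pairs(uk_cohort):
    return sw.pair_wide(uk_cohort, "liking", covariates=("age", "sex"))
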