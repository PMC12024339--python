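import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tnzsize as tz

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings(
    "ignore",
    message="The Identity link function does not respect",
)


@pytest.fixture(scope="session")
def small_config() -> tz.SyntheticConfig:
    """A compact study: 9 sites, two years, 6 animals per site-year."""
    return tz.SyntheticConfig(years=(2022, 2023), n_per_site_year=6, seed=7)


@pytest.fixture(scope="session")
def small_data(small_config):
    return tz.simulate_all(small_config)


@pytest.fixture(scope="session")
def noiseless_tnz_config() -> tz.SyntheticConfig:
    """True LLT = 29, ULT = 31 at every site, no measurement noise."""
    return tz.SyntheticConfig(
        tnz_base_llt=29.0,
        tnz_base_ult=31.0,
        tnz_llt_temp_slope=0.0,
        tnz_ult_temp_slope=0.0,
        tnz_site_sd=0.0,
        rmr_noise_sd=0.0,
        n_sites=2,
        years=(2023,),
        seed=11,
    )


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    """Six records: one juvenile, one old, one pregnant adult, three eligible."""
    return pd.DataFrame(
        {
            "id": [f"A{i}" for i in range(6)],
            "site": ["S01"] * 6,
            "year": [2023] * 6,
            "sex": ["male", "female", "female", "male", "female", "male"],
            "stage": ["juvenile", "old", "adult I", "sub-adult", "adult II", "adult I"],
            "body_mass_g": [10.0, 40.0, 25.0, 20.0, 33.0, 27.0],
            "body_length_mm": [80.0, 120.0, 100.0, 95.0, 108.0, 103.0],
            "pregnant": [False, False, True, False, False, False],
        }
    )


def glmm_sim_frame(config: tz.SyntheticConfig):
    """Filtered records joined with the true site-level AnnMinTemp."""
    from tnzsize.body_size import filter_records
    from tnzsize.synthetic import gen_individuals, gen_sites

    sites, truth = gen_sites(config)
    recs = filter_records(gen_individuals(sites, config, truth))
    temp = truth.sites[["site", "ann_min_temp_spatial"]].rename(
        columns={"ann_min_temp_spatial": "ann_min_temp"}
    )
    return recs.merge(temp, on="site"), truth
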