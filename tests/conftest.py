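import numpy as np
import pandas as pd
import pytest

import ctitrack as ct


@pytest.fixture
def rng():
    return np.random.default_rng(20240308)


@pytest.fixture
def small_scenario():
    """One open-basin station, default study conditions, fixed seed."""
    cfg = ct.ScenarioConfig(seed=7)
    niches = ct.sample_niche_pool(cfg)
    abundance, temperature, truth = ct.simulate_community_series(cfg, niches)
    return cfg, niches, abundance, temperature, truth


@pytest.fixture
def toy_abundance_csv(tmp_path):
    path = tmp_path / "abundance.csv"
    path.write_text(
        "site_id,year,species_id,abundance\n"
        "A,2000,sp1,10\n"
        "A,2000,sp2,5\n"
        "A,2001,sp1,12\n"
    )
    return path


@pytest.fixture
def metadata_frame():
    return pd.DataFrame({
        "site_id": ["A", "B", "C", "D"],
        "biological_group": ["fish", "zooplankton", "CSB benthos", "fish"],
        "habitat": ["pelagic", "pelagic", "benthic/demersal", "estuarine"],
        "region": ["NE Atlantic", "Baltic", "Mediterranean", "NE Atlantic"],
        "basin_type": ["non-enclosed", "semi-enclosed", "semi-enclosed",
                       "semi-enclosed"],
    })
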