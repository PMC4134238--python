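import numpy as np
import pandas as pd
import pytest

from divclim import SyntheticConfig, generate_climate, generate_communities


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_plots=400, seed=11)


@pytest.fixture(scope="session")
def small_climate(small_config) -> pd.DataFrame:
    return generate_climate(small_config)


@pytest.fixture(scope="session")
def small_plots(small_config, small_climate):
    return generate_communities(small_climate, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def stems_csv(tmp_path):
    """A small stem table including one malformed row (height 'NA')."""
    path = tmp_path / "stems.csv"
    path.write_text(
        "plot_id,species,height,dbh\n"
        "p1,Pinus durangensis,12.0,25.0\n"
        "p1,Quercus sideroxyla,8.0,7.5\n"
        "p1,Pinus durangensis,NA,10.0\n"
        "p2,Arbutus xalapensis,4.0,7.4\n"
        "p3,Pinus cooperi,2.9,30.0\n"
        "p4,Juniperus deppeana,6.0,9.0\n"
    )
    return path
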