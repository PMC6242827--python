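import pandas as pd
import pytest

import sporesalt as ss


@pytest.fixture(scope="session")
def coarse_table():
    """2000-particle stage-4/5 table from the default coarse-mode mixture."""
    cfg = ss.GeneratorConfig(n_particles=2000, mixture=ss.COARSE_MIXTURE, seed=11)
    return ss.gen_particle_table(cfg)


@pytest.fixture(scope="session")
def coarse_results(coarse_table):
    return ss.classify_table(coarse_table)


@pytest.fixture(scope="session")
def hourly_series():
    """60-day hourly wet-season series with 2x nighttime spore enhancement."""
    cfg = ss.SeriesConfig(n_days=60, seed=3)
    return ss.gen_concentration_series(cfg, hourly=True)


@pytest.fixture
def single_step_series():
    """One step at the worked-example concentrations (1.0 / 0.30 ug m-3)."""
    return pd.DataFrame({"date": ["2015-01-01"], "spore_ugm3": [1.0],
                         "seasalt_ugm3": [0.30]})
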