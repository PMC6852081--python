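import numpy as np
import pytest

from deltagb.chronosequence_rates import fit_growth_model
from deltagb.data_io import Continent, group_proximate_sites
from deltagb.synthetic_data import ChronoSimParams, simulate_chronosequences


@pytest.fixture(scope="session")
def noiseless_stratum():
    """Five deterministic chronosequences on one exact log-linear curve."""
    params = ChronoSimParams(
        n_sites=5, plots_per_site=6, sd_b0=0.0, sd_b1=0.0, sd_resid=0.0, seed=11
    )
    records, truth = simulate_chronosequences(params)
    chronos, _ = group_proximate_sites(records, Continent.AMERICAS)
    return params, chronos, truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_stratum):
    _, chronos, _ = noiseless_stratum
    return fit_growth_model(chronos)


@pytest.fixture(scope="session")
def noisy_fit_with_truth():
    """A realistic stratum (random slopes/intercepts, residual noise)."""
    params = ChronoSimParams(seed=3)
    records, truth = simulate_chronosequences(params)
    chronos, _ = group_proximate_sites(records, Continent.AMERICAS)
    return fit_growth_model(chronos), truth, chronos
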