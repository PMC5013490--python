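import numpy as np
import pandas as pd
import pytest

import forestbeta as fb
from forestbeta.data_io import StemTable


@pytest.fixture(scope="session")
def yule8():
    return fb.simulate_tree(8, seed=11)


@pytest.fixture(scope="session")
def yule64():
    return fb.simulate_tree(64, seed=42)


@pytest.fixture(scope="session")
def traits8(yule8):
    return fb.simulate_traits(yule8, trait_signal_w=0.6, seed=12)


@pytest.fixture(scope="session")
def reduced_neutral():
    """Small neutral chronosequence dataset: 1 regime, 2 plots, 20 species."""
    scenario = fb.AssemblyScenario(
        mode="neutral",
        n_species=20,
        n_regimes=1,
        n_plots_per_regime=2,
        stems_per_plot=600,
        seed=3,
    )
    return fb.simulate_dataset(scenario, grains=(25,))


@pytest.fixture(scope="session")
def three_regime_neutral():
    """Neutral dataset with the full 3-regime layout at reduced size."""
    scenario = fb.AssemblyScenario(
        mode="neutral",
        n_species=40,
        n_regimes=3,
        n_plots_per_regime=2,
        stems_per_plot=800,
        seed=5,
    )
    return fb.simulate_dataset(scenario, grains=(20,))


def make_stems(rows):
    """StemTable from (stem_id, species, plot_id, regime, x, y, dbh) tuples."""
    return StemTable(
        pd.DataFrame(
            rows, columns=["stem_id", "species", "plot_id", "regime", "x", "y", "dbh"]
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
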