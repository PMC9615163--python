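import numpy as np
import pandas as pd
import pytest

from sctam.matrix import CountMatrix
from sctam.simulate import SimConfig, default_panel, simulate_experiment


@pytest.fixture(scope="session")
def small_panel():
    """Small synthetic panel: 3 cell types, 60 discriminating amplicons.

    Keeps the recommended minimum of 50 non-HhaI control amplicons so cell
    calling behaves as in a realistic panel.
    """
    return default_panel(n_discriminating=60, n_non_hha=50, n_const_meth=5,
                        n_const_unmeth=10, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_panel):
    """600 cells of 3 types + 1,500 empty droplets, moderate dropout."""
    profiles, classes = small_panel
    rng = np.random.default_rng(12)
    cfg = SimConfig(
        n_cells={"typeA": 200, "typeB": 200, "typeC": 200},
        cell_type_profiles=profiles,
        amplicon_classes=classes,
        dropout=pd.Series(rng.uniform(0.05, 0.25, len(profiles)), index=profiles.index),
        n_empty_droplets=1500,
        empty_mean_reads=0.2,
        seed=13,
    )
    digested, undigested, truth = simulate_experiment(cfg)
    return cfg, digested, undigested, truth


@pytest.fixture()
def toy_counts():
    """4 barcodes x 3 amplicons with known values."""
    return CountMatrix(
        barcodes=["b1", "b2", "b3", "b4"],
        amplicons=["a1", "a2", "a3"],
        counts=np.array([[7, 0, 1], [0, 0, 0], [3, 2, 0], [1, 1, 1]]),
        condition="digested",
    )
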