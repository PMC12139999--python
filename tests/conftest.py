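import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ebscreen.io_qc import CountsTriplet
from ebscreen.simdata import (
    CountModel,
    LibraryDesign,
    ScreenConfig,
    simulate_monoclonal_screen,
    simulate_mosaic_screen,
)


@pytest.fixture(scope="session")
def small_library():
    return LibraryDesign.build(4, seed=11)


@pytest.fixture(scope="session")
def mono_sim():
    """Small default-noise monoclonal screen shared across tests."""
    lib = LibraryDesign.build(4, seed=11)
    cfg = ScreenConfig(
        n_ebs=40,
        design="monoclonal",
        capture_cells_per_eb=100,
        detection_prob=0.9,
        multi_integrant_prob=0.05,
        seed=3,
    )
    counts, truth = simulate_monoclonal_screen(lib, cfg)
    return lib, cfg, counts, truth


@pytest.fixture(scope="session")
def clean_mosaic_sim():
    """Noise-free mosaic screen: full detection, no ambient, high counts."""
    lib = LibraryDesign.build(4, seed=11)
    cfg = ScreenConfig(
        n_ebs=20,
        design="mosaic",
        founders_per_eb=50,
        cells_per_eb=(2000, 4000),
        clone_concentration=1.0,
        capture_cells_per_eb=150,
        detection_prob=1.0,
        count_model=CountModel(guide_umi_mean=40.0, dispersion=20.0, ambient_rate=0.0),
        seed=5,
    )
    counts, truth = simulate_mosaic_screen(lib, cfg)
    return lib, cfg, counts, truth


def make_counts(umi, reads=None, classes=None, cell_prefix="c", feature_prefix="f"):
    """Build a CountsTriplet from dense arrays for hand-crafted examples."""
    umi = np.asarray(umi)
    n_cells, n_feat = umi.shape
    if classes is None:
        classes = ["guide"] * n_feat
    features = pd.DataFrame(
        {
            "feature_id": [f"{feature_prefix}{j}" for j in range(n_feat)],
            "feature_class": classes,
        }
    )
    return CountsTriplet(
        cell_ids=np.array([f"{cell_prefix}{i}" for i in range(n_cells)], object),
        features=features,
        umi=sp.csr_matrix(umi),
        reads=None if reads is None else sp.csr_matrix(np.asarray(reads)),
    )
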