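import numpy as np
import pytest

from msq.core_io import RunConfig, SlideImage
from msq.pipeline import run_pipeline
from msq.synthetic import render_micsss_panel


@pytest.fixture(scope="session")
def small_panel():
    """3-stain, 150-cell pre-aligned panel with artefacts and RBCs."""
    rasters, truth = render_micsss_panel(
        n_stains=3, n_cells=150, shape=(1200, 1200), artifact_count=10,
        rbc_count=8, dropout_rate=0.1, apply_warps=False, seed=3)
    return rasters, truth


@pytest.fixture(scope="session")
def small_panel_result(small_panel):
    rasters, truth = small_panel
    slides = [SlideImage.from_array(r, mpp=truth.mpp) for r in rasters]
    cfg = RunConfig(stains=("s0", "s1", "s2"), tile_size=500, seed=0)
    return run_pipeline(slides, cfg, register=False), truth, cfg


@pytest.fixture(scope="session")
def consensus_panel():
    """The 5-stain consensus study panel: 500 cells, 20 single-stain
    artefacts, 10% dropout, pre-aligned."""
    rasters, truth = render_micsss_panel(
        n_stains=5, n_cells=500, shape=(2000, 2000), artifact_count=20,
        rbc_count=0, dropout_rate=0.1, apply_warps=False, seed=7)
    return rasters, truth


@pytest.fixture(scope="session")
def consensus_panel_result(consensus_panel):
    rasters, truth = consensus_panel
    slides = [SlideImage.from_array(r, mpp=truth.mpp) for r in rasters]
    cfg = RunConfig(stains=tuple(f"s{i}" for i in range(5)),
                    tile_size=1000, seed=0)
    result = run_pipeline(slides, cfg, register=False, rbc_filtering=False)
    return result, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
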