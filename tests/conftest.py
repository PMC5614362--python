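import numpy as np
import pytest

from srseg import annotation, feature_channels as fc, phantoms, super_regions as sr
from srseg import volume_io as vio


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid(rng):
    """12^3 random grid for dense-oracle comparisons."""
    return rng.normal(size=(12, 12, 12))


@pytest.fixture
def two_phase_ws():
    """Workspace over a two-phase phantom with TV channel and supervoxels."""
    ph = phantoms.make_two_phase(size=32, seed=3)
    ws = vio.Workspace(volume=vio.Volume(ph.volume))
    fc.compute_queue(ws, [{"name": "tv", "operator": "total_variation",
                           "params": {"lambda_tv": 10, "n_iter": 50}}])
    ws.supervoxels = sr.compute_supervoxels(ws.channels["tv"], shape=(8, 8, 8),
                                            compactness=30)
    return ws, ph


@pytest.fixture
def annotated_two_phase(two_phase_ws):
    """Two-phase workspace with sparse background/core scribbles."""
    ws, ph = two_phase_ws
    level = annotation.add_level(ws)
    annotation.add_label(level, "background")
    annotation.add_label(level, "core")
    annotation.annotate(ws, annotation.Stroke(
        level=0, label=0, mode="supervoxel", pen_width=2,
        seeds=[[3, 3, 3], [3, 28, 28], [28, 3, 28], [28, 28, 3]]))
    annotation.annotate(ws, annotation.Stroke(
        level=0, label=1, mode="supervoxel", pen_width=2, seeds=[[16, 16, 16]]))
    return ws, ph
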