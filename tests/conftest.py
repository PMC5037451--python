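import numpy as np
import pytest

from stretchplate import synthetic_data as syn
from stretchplate.layout import PlateLayout


@pytest.fixture(scope="session")
def default_layout() -> PlateLayout:
    return PlateLayout.default()


@pytest.fixture(scope="session")
def calibration_layout(default_layout) -> PlateLayout:
    """Layout for cell-free strain characterization: the full post array
    is present, so no well is an unstretched control."""
    return PlateLayout(
        control_wells=frozenset(), excluded_wells=default_layout.excluded_wells
    )


@pytest.fixture(scope="session")
def control_scene():
    """One uninjured rendered scene with ground truth (session-cached)."""
    spec = syn.SceneSpec(n_cells=6, n_free_nuclei=1, seed=11)
    channels, truth, scene = syn.gen_culture_image(spec, 0.0)
    return spec, channels, truth, scene


@pytest.fixture(scope="session")
def injured_scene():
    spec = syn.SceneSpec(n_cells=6, n_free_nuclei=1, seed=11)
    channels, truth, scene = syn.gen_culture_image(spec, 0.5)
    return spec, channels, truth, scene


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160927)
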