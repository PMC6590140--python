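import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from qmyelin.cohort import (CohortConfig, LesionModel, PhantomGeometry,
                            build_label_volume, default_tissues)
from qmyelin.signals import GraseProtocol, McDespotProtocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grase_protocol():
    return GraseProtocol()


@pytest.fixture(scope="session")
def mcdespot_protocol():
    return McDespotProtocol()


@pytest.fixture(scope="session")
def small_geometry():
    """Compact 24^3 head used by the fast cohort tests."""
    return PhantomGeometry(
        grid_shape=(24, 24, 24), voxel_size=(5.0, 5.0, 5.0),
        brain_radii=(42.0, 46.0, 38.0), wm_radii=(30.0, 34.0, 26.0),
        subcortical_radii=(7.0, 9.0, 7.0),
        subcortical_offsets=((-13.0, 0.0, 0.0), (13.0, 0.0, 0.0)),
        ventricle_radii=(4.0, 10.0, 5.0),
        ventricle_offsets=((-6.0, -2.0, 2.0), (6.0, -2.0, 2.0)))


@pytest.fixture(scope="session")
def small_labels(small_geometry):
    return build_label_volume(small_geometry)


@pytest.fixture(scope="session")
def tissues():
    return default_tissues()


@pytest.fixture
def small_lesion_model():
    return LesionModel(count_mean=6, count_dispersion=6, count_range=(2, 15),
                       radius_log_mean=float(np.log(2.2)), radius_log_sd=0.3)


@pytest.fixture
def tiny_cohort_config(small_geometry, small_lesion_model):
    return CohortConfig(n_controls=5, n_patients=3, seed=7,
                        geometry=small_geometry, lesions=small_lesion_model)
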