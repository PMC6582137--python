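import numpy as np
import pytest

from nanosynapse import (
    AcquisitionModel,
    ClusterShape,
    NeuriteModel,
    SynapseModel,
    generate_neurite_field,
    sample_synapse_population,
)


@pytest.fixture(scope="session")
def point_model():
    """Point clusters: the pure orientation-projection geometry."""
    return SynapseModel(
        true_separation_nm=200.0,
        cluster_shapes=(ClusterShape.disk(0.0), ClusterShape.disk(0.0)),
        localization_precision_nm=10.0,
    )


@pytest.fixture(scope="session")
def small_population(point_model):
    return sample_synapse_population(point_model, 60, seed=42)


@pytest.fixture(scope="session")
def neurite_field():
    model = NeuriteModel(path_nm=((0.0, 0.0), (60000.0, 0.0)), punctae_per_um=0.5)
    return generate_neurite_field(model, seed=7)


@pytest.fixture(scope="session")
def quiet_acquisition():
    """Single-emitter, always-on friendly settings for fitting tests."""
    return AcquisitionModel(
        n_frames=100,
        fov_px=(32, 32),
        photons_per_event=2000.0,
        background_photons_per_pixel=2.0,
        psf_sigma_nm=100.0,
        camera_pixel_nm=100.0,
    )
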