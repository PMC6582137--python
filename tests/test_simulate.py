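"""Synthetic-data generator: geometry, kinetics, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from nanosynapse import (
    AcquisitionModel,
    ClusterShape,
    NeuriteModel,
    SynapseModel,
    generate_neurite_field,
    inject_drift,
    linear_drift,
    sample_orientations,
    sample_synapse_population,
    simulate_acquisition,
)
from nanosynapse.errors import InvalidArgumentError

POINT = (ClusterShape.disk(0.0), ClusterShape.disk(0.0))

# (1/0.4) * integral_0^0.4 sqrt(1-u^2) du with u = cos(theta); frozen from
# the closed form [u*sqrt(1-u^2) + asin(u)]/2 evaluated at 0.4
TOP40_PROJECTION_FACTOR = 0.9726536271

def test_top40_projection_factor_matches_numeric_integration():
    from scipy.integrate import quad
    val, _ = quad(lambda u: np.sqrt(1.0 - u * u), 0.0, 0.4)
    assert val / 0.4 == pytest.approx(TOP40_PROJECTION_FACTOR, abs=1e-9)


def test_zero_separation_gives_coincident_cluster_centers():
    model = SynapseModel(
        true_separation_nm=0.0, cluster_shapes=POINT, localization_precision_nm=0.0,
        labels_per_cluster=1, localizations_per_label=3.0,
    )
    table, truth = sample_synapse_population(model, 5, seed=0)
    assert np.all(truth.synapses["true_projected_nm"].to_numpy() == 0.0)
    for sid, grp in table.groupby("synapse_id"):
        a = grp.loc[grp.channel == "A", ["x_nm", "y_nm"]].mean()
        b = grp.loc[grp.channel == "B", ["x_nm", "y_nm"]].mean()
        assert np.allclose(a, b)


def test_side_view_projects_full_separation():
    model = SynapseModel(
        true_separation_nm=200.0, cluster_shapes=POINT,
        orientation_mode="fixed", fixed_theta_rad=np.pi / 2.0,
    )
    _, truth = sample_synapse_population(model, 20, seed=1)
    assert np.allclose(truth.synapses["true_projected_nm"], 200.0)


def test_projection_never_exceeds_true_separation(small_population):
    truth = small_population[1].synapses
    assert (truth["true_projected_nm"] <= truth["true_separation_nm"] + 1e-9).all()
    assert (truth["true_projected_nm"] >= 0).all()


def test_isotropic_orientation_has_uniform_cos_theta():
    model = SynapseModel(true_separation_nm=150.0)
    theta, _ = sample_orientations(model, 10**4, np.random.default_rng(3))
    stat = sstats.kstest(np.cos(theta), "uniform")
    assert stat.pvalue > 0.01


def test_top40_of_true_projected_matches_integration_oracle():
    model = SynapseModel(true_separation_nm=200.0)
    _, projected = sample_orientations(model, 10**6, np.random.default_rng(5))
    from nanosynapse import top40_summary

    summary = top40_summary(projected)
    assert summary.mean_top40_nm / 200.0 == pytest.approx(TOP40_PROJECTION_FACTOR, rel=2e-3)


def test_identical_seed_reproduces_population(point_model):
    t1, tr1 = sample_synapse_population(point_model, 20, seed=9)
    t2, tr2 = sample_synapse_population(point_model, 20, seed=9)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(tr1.synapses, tr2.synapses)


def test_invalid_population_arguments_raise():
    with pytest.raises(InvalidArgumentError):
        sample_synapse_population(SynapseModel(), 0, seed=0)
    with pytest.raises(InvalidArgumentError):
        SynapseModel(true_separation_nm=-1.0)
    with pytest.raises(InvalidArgumentError):
        ClusterShape.disk(-5.0)


# -- frame-stack simulation -------------------------------------------------


def test_noiseless_single_emitter_stack_is_constant_with_exact_photons():
    acq = AcquisitionModel(
        n_frames=5, fov_px=(16, 16), photons_per_event=500.0,
        background_photons_per_pixel=0.0, shot_noise=False,
    )
    stack, events = simulate_acquisition([[800.0, 800.0]], acq, seed=0, always_on=True)
    assert np.allclose(stack.frames, stack.frames[0])
    assert stack.frames[0].sum() == pytest.approx(500.0, rel=1e-6)
    assert len(events) == 5


def test_photon_conservation_with_background_noiseless():
    acq = AcquisitionModel(
        n_frames=3, fov_px=(24, 24), photons_per_event=800.0,
        background_photons_per_pixel=1.5, shot_noise=False,
    )
    stack, _ = simulate_acquisition(
        [[1200.0, 1200.0], [1000.0, 1400.0]], acq, seed=0, always_on=True
    )
    expected = 1.5 * 24 * 24 + 2 * 800.0
    assert stack.frames[0].sum() == pytest.approx(expected, rel=1e-6)


def test_injected_linear_drift_moves_spot_by_exact_offset():
    acq = AcquisitionModel(
        n_frames=11, fov_px=(24, 24), photons_per_event=1000.0, shot_noise=False,
    )
    drift = linear_drift(11, 50.0, 25.0)
    stack, events = simulate_acquisition([[1000.0, 1000.0]], acq, seed=0,
                                         drift_nm=drift, always_on=True)
    def com(img):
        rows, cols = np.mgrid[0:24, 0:24]
        return np.array([(cols * img).sum(), (rows * img).sum()]) / img.sum()

    delta_px = com(stack.frames[-1]) - com(stack.frames[0])
    assert delta_px * acq.camera_pixel_nm == pytest.approx([50.0, 25.0], abs=0.3)
    assert events.x_nm.iloc[-1] - events.x_nm.iloc[0] == pytest.approx(50.0)


def test_poisson_shot_noise_variance_matches_mean():
    acq = AcquisitionModel(
        n_frames=1000, fov_px=(16, 16), photons_per_event=300.0,
        background_photons_per_pixel=0.0, shot_noise=True,
    )
    stack, _ = simulate_acquisition([[800.0, 800.0]], acq, seed=11, always_on=True)
    counts = stack.frames.sum(axis=(1, 2))
    assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.15)


def test_fiducials_present_in_every_frame():
    acq = AcquisitionModel(
        n_frames=20, fov_px=(24, 24), photons_per_event=500.0,
        on_probability_per_frame=0.0, shot_noise=False,
    )
    stack, _ = simulate_acquisition(
        np.zeros((0, 2)), acq, seed=0, fiducials=[[1200.0, 1200.0]]
    )
    assert np.all(stack.frames.sum(axis=(1, 2)) > 400.0)


def test_emitter_outside_fov_rejected():
    acq = AcquisitionModel(n_frames=1, fov_px=(16, 16))
    with pytest.raises(InvalidArgumentError):
        simulate_acquisition([[10_000.0, 100.0]], acq, seed=0)


# -- neurite fields ----------------------------------------------------------


def test_zero_punctae_rate_gives_empty_truth():
    model = NeuriteModel(path_nm=((0, 0), (20000, 0)), punctae_per_um=0.0)
    field = generate_neurite_field(model, seed=0)
    assert len(field.clusters) == 0
    assert len(field.table) > 0  # diffuse background remains


def test_cluster_count_is_poisson_with_expected_mean():
    model = NeuriteModel(path_nm=((0, 0), (100_000, 0)), punctae_per_um=0.5)
    counts = [len(generate_neurite_field(model, seed=s).clusters) for s in range(60)]
    # mean 50 per 100 um path; 60 seeds -> SE = sqrt(50/60) ~ 0.9
    assert np.mean(counts) == pytest.approx(50.0, abs=3.0)


def test_cluster_area_median_matches_model():
    model = NeuriteModel(path_nm=((0, 0), (100_000, 0)), punctae_per_um=1.0)
    areas = np.concatenate(
        [generate_neurite_field(model, seed=s).clusters["area_um2"] for s in range(5)]
    )
    assert np.median(areas) == pytest.approx(0.008, rel=0.15)


def test_degenerate_neurite_path_rejected():
    with pytest.raises(InvalidArgumentError):
        NeuriteModel(path_nm=((0.0, 0.0),))
    with pytest.raises(InvalidArgumentError):
        NeuriteModel(path_nm=((0.0, 0.0), (0.0, 0.0)))


def test_drift_injection_requires_covering_trajectory(point_model):
    table, _ = sample_synapse_population(point_model, 5, seed=0, n_frames=100)
    with pytest.raises(InvalidArgumentError):
        inject_drift(table, np.zeros((10, 2)))
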