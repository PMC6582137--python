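"""Voronoi density estimation and two-level segmentation."""

import numpy as np
import pytest

from nanosynapse import (
    SynapseModel,
    SynapseROI,
    punctae_per_micron,
    sample_synapse_population,
    segment_clusters,
    segment_objects,
    synapse_cluster_area,
    voronoi_density,
)
from nanosynapse.errors import DegenerateGeometryError, InvalidArgumentError
from nanosynapse.simulate import MATURE_SHAPE


def _grid_points(n_side=20, spacing=100.0):
    i = np.arange(n_side)
    xx, yy = np.meshgrid(i * spacing, i * spacing)
    return np.column_stack([xx.ravel(), yy.ravel()])


def test_square_lattice_interior_cells_have_spacing_squared_area():
    pts = _grid_points(20, 100.0)
    region = (-50.0, -50.0, 1950.0, 1950.0)  # grid bbox padded by half a cell
    field = voronoi_density(pts, region=region)
    # interior cells (away from the border) are exact squares
    interior = (
        (pts[:, 0] > 100) & (pts[:, 0] < 1800) & (pts[:, 1] > 100) & (pts[:, 1] < 1800)
    )
    assert np.allclose(field.cell_areas_nm2[interior], 100.0**2, rtol=1e-9)
    assert np.allclose(field.density_per_nm2[interior], field.avg_density_per_nm2, rtol=1e-9)


def test_clipped_cell_areas_partition_the_region():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 5000, (800, 2))
    region = (0.0, 0.0, 5000.0, 5000.0)
    field = voronoi_density(pts, region=region)
    assert field.cell_areas_nm2.sum() == pytest.approx(5000.0**2, rel=1e-6)


def test_poisson_mean_cell_area_matches_intensity():
    rng = np.random.default_rng(1)
    n = 10**4
    pts = rng.uniform(0, 10_000, (n, 2))
    field = voronoi_density(pts, region=(0, 0, 10_000, 10_000))
    assert field.cell_areas_nm2.mean() == pytest.approx(10_000.0**2 / n, rel=0.02)


def test_collinear_points_degenerate():
    pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
    with pytest.raises(DegenerateGeometryError):
        voronoi_density(pts)
    with pytest.raises(DegenerateGeometryError):
        voronoi_density(pts[:3])


def test_zero_area_region_rejected():
    with pytest.raises(InvalidArgumentError):
        voronoi_density(_grid_points(5), region=(0.0, 0.0, 0.0, 0.0))


def test_uniform_lattice_yields_no_objects():
    field = voronoi_density(_grid_points(15, 100.0), region=(-50, -50, 1450, 1450))
    assert segment_objects(field) == []


def _disk_on_background(rng, center, n_disk, radius, n_bg, extent):
    r = radius * np.sqrt(rng.random(n_disk))
    phi = rng.uniform(0, 2 * np.pi, n_disk)
    disk = center + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    bg = rng.uniform(0, extent, (n_bg, 2))
    return np.vstack([disk, bg])


def test_single_dense_disk_forms_one_object_covering_it():
    rng = np.random.default_rng(2)
    pts = _disk_on_background(rng, [5000.0, 5000.0], 300, 400.0, 300, 10_000.0)
    field = voronoi_density(pts, region=(0, 0, 10_000, 10_000))
    objects = segment_objects(field)
    big = [o for o in objects if o.n_locs >= 50]
    assert len(big) == 1
    assert big[0].n_locs >= 270  # nearly all disk members
    assert (big[0].indices < 300).mean() > 0.95


def test_two_separated_disks_form_two_objects():
    rng = np.random.default_rng(3)
    d1 = _disk_on_background(rng, [2500.0, 2500.0], 300, 400.0, 0, 1.0)[:300]
    d2 = d1 + [5000.0, 5000.0]
    bg = rng.uniform(0, 10_000, (300, 2))
    field = voronoi_density(np.vstack([d1, d2, bg]), region=(0, 0, 10_000, 10_000))
    objects = [o for o in segment_objects(field) if o.n_locs >= 50]
    assert len(objects) == 2


def test_object_of_uniform_density_has_no_clusters():
    field = voronoi_density(_grid_points(15, 100.0), region=(-50, -50, 1450, 1450))
    # force the whole lattice into one object to probe the cluster level
    from nanosynapse.tessellate import VoronoiObject

    obj = VoronoiObject(
        indices=np.arange(field.n), n_locs=field.n,
        area_nm2=float(field.cell_areas_nm2.sum()),
    )
    assert len(segment_clusters(field, [obj])) == 0


def test_min_area_discards_tiny_components(neurite_field):
    table, region = neurite_field.table, neurite_field.region_nm
    pts = table[["x_nm", "y_nm"]].to_numpy()
    field = voronoi_density(pts, region=region)
    objects = segment_objects(field)
    kept = segment_clusters(field, objects, min_area_um2=0.0005, min_locs=3)
    huge_floor = segment_clusters(field, objects, min_area_um2=0.05, min_locs=3)
    assert all(c.area_um2 >= 0.0005 for c in kept.clusters)
    assert len(huge_floor) < len(kept)


def test_cluster_count_and_areas_recover_neurite_truth(neurite_field):
    truth = neurite_field.clusters
    pts = neurite_field.table[["x_nm", "y_nm"]].to_numpy()
    field = voronoi_density(pts, region=neurite_field.region_nm)
    clusters = segment_clusters(field, segment_objects(field))
    assert len(clusters) == pytest.approx(len(truth), rel=0.15)
    from scipy.spatial import cKDTree

    cents = np.array([c.centroid_nm for c in clusters.clusters])
    d, i = cKDTree(np.c_[truth.center_x_nm, truth.center_y_nm]).query(cents)
    matched = d < 100.0
    ratio = clusters.areas_um2[matched] / truth.area_um2.to_numpy()[i[matched]]
    assert np.median(ratio) == pytest.approx(1.0, abs=0.2)


def test_raising_cluster_factor_shrinks_cluster_membership(neurite_field):
    # a higher threshold keeps a subset of localizations, so every cluster at
    # the stricter factor is contained in (and no larger than) one at the
    # looser factor; counts alone may go either way when components split
    pts = neurite_field.table[["x_nm", "y_nm"]].to_numpy()
    field = voronoi_density(pts, region=neurite_field.region_nm)
    objects = segment_objects(field)
    loose = segment_clusters(field, objects, cluster_factor=3.0, min_locs=3,
                             min_area_um2=0.0)
    strict = segment_clusters(field, objects, cluster_factor=6.0, min_locs=3,
                              min_area_um2=0.0)
    loose_members = [set(c.indices.tolist()) for c in loose.clusters]
    for c in strict.clusters:
        members = set(c.indices.tolist())
        parents = [i for i, lm in enumerate(loose_members) if members <= lm]
        assert len(parents) == 1
        assert c.area_um2 <= loose.clusters[parents[0]].area_um2 + 1e-12


def test_coordinate_scaling_scales_areas_and_keeps_membership():
    rng = np.random.default_rng(4)
    pts = _disk_on_background(rng, [5000.0, 5000.0], 200, 300.0, 400, 10_000.0)
    f1 = voronoi_density(pts, region=(0, 0, 10_000, 10_000))
    f2 = voronoi_density(pts * 2.0, region=(0, 0, 20_000, 20_000))
    assert np.allclose(f2.cell_areas_nm2, 4.0 * f1.cell_areas_nm2, rtol=1e-9)
    o1 = segment_objects(f1)
    o2 = segment_objects(f2)
    assert [set(o.indices) for o in o1] == [set(o.indices) for o in o2]


def test_punctae_rate_arithmetic():
    assert punctae_per_micron(0, 10.0) == 0.0
    assert punctae_per_micron(54, 100.0) == pytest.approx(0.54)
    assert punctae_per_micron(54, 200.0) == pytest.approx(0.27)
    with pytest.raises(InvalidArgumentError):
        punctae_per_micron(5, 0.0)


def test_synapse_roi_cluster_area_recovers_disk(  ):
    model = SynapseModel(true_separation_nm=180.0)
    table, truth = sample_synapse_population(model, 25, seed=31)
    areas = []
    for row in truth.synapses.itertuples():
        roi = SynapseROI(row.center_x_nm, row.center_y_nm, np.degrees(row.azimuth_rad))
        areas.append(synapse_cluster_area(table, roi, "B"))
    assert np.median(areas) == pytest.approx(0.008, rel=0.25)


def test_mature_bar_cluster_larger_than_immature_disk():
    disk_model = SynapseModel(true_separation_nm=180.0)
    bar_model = SynapseModel(
        true_separation_nm=180.0, cluster_shapes=(MATURE_SHAPE, MATURE_SHAPE)
    )
    wins = 0
    total = 0
    for seed in range(3):
        td, trd = sample_synapse_population(disk_model, 15, seed=100 + seed)
        tb, trb = sample_synapse_population(bar_model, 15, seed=200 + seed)
        for rd, rb in zip(trd.synapses.itertuples(), trb.synapses.itertuples()):
            roi_d = SynapseROI(rd.center_x_nm, rd.center_y_nm, np.degrees(rd.azimuth_rad))
            roi_b = SynapseROI(rb.center_x_nm, rb.center_y_nm, np.degrees(rb.azimuth_rad))
            a_d = synapse_cluster_area(td, roi_d, "B")
            a_b = synapse_cluster_area(tb, roi_b, "B")
            total += 1
            wins += a_b > a_d
    assert wins / total >= 0.95
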