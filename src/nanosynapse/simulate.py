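"""Synthetic SMLM data with full ground truth.

Three generators emulate the imaging experiments the analysis pipeline is
built for:

* :func:`sample_synapse_population` — two-color synapse populations in which
  each synapse is a pair of protein clusters separated by a known 3D distance
  D along a randomly oriented trans-synaptic axis. Only the projection
  D*sin(theta) onto the image plane is observable, which is exactly the
  geometry the top-40% distance statistic corrects for.
* :func:`simulate_acquisition` — raw camera frame stacks (Gaussian PSF spots,
  blinking/binding kinetics, Poisson shot noise, read noise, drift,
  fiducials) for exercising spot detection and centroid fitting.
* :func:`generate_neurite_field` — neurite-like point fields: a diffuse
  localization background along a curvilinear ribbon containing discrete
  dense protein clusters, for exercising tessellation segmentation.

All coordinates are in nm with the origin at the lower-left corner of the
field of view; frame indices are 0-based. Identical seeds give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import InvalidArgumentError
from .tables import make_table

# --------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class ClusterShape:
    """Planar footprint over which the labels of one protein cluster spread.

    ``disk`` places labels uniformly in a disk of ``radius_nm`` (0 = point
    cluster); ``bar`` places them uniformly in a rectangle of
    ``length_nm`` x ``thickness_nm`` whose long axis lies perpendicular to
    the (in-plane) trans-synaptic axis, mimicking the bar-like scaffolds of
    mature synapses.
    """

    kind: str = "disk"  # "disk" | "bar"
    radius_nm: float = 0.0
    length_nm: float = 400.0
    thickness_nm: float = 60.0

    def __post_init__(self):
        if self.kind not in ("disk", "bar"):
            raise InvalidArgumentError(f"unknown cluster shape '{self.kind}'")
        if self.radius_nm < 0 or self.length_nm < 0 or self.thickness_nm < 0:
            raise InvalidArgumentError("cluster dimensions must be non-negative")

    @classmethod
    def disk(cls, radius_nm: float) -> "ClusterShape":
        return cls(kind="disk", radius_nm=radius_nm)

    @classmethod
    def disk_of_area(cls, area_um2: float) -> "ClusterShape":
        return cls(kind="disk", radius_nm=1000.0 * math.sqrt(area_um2 / math.pi))

    @classmethod
    def bar(cls, length_nm: float, thickness_nm: float) -> "ClusterShape":
        return cls(kind="bar", length_nm=length_nm, thickness_nm=thickness_nm)

    def sample_offsets(self, n: int, axis_rad: float, rng: np.random.Generator) -> np.ndarray:
        """Draw n label offsets (nm) around the cluster center.

        ``axis_rad`` is the in-plane azimuth of the trans-synaptic axis; bar
        clusters extend perpendicular to it.
        """
        if self.kind == "disk":
            r = self.radius_nm * np.sqrt(rng.random(n))
            phi = rng.uniform(0.0, 2.0 * np.pi, n)
            return np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        u = rng.uniform(-0.5, 0.5, n) * self.length_nm   # along the bar
        v = rng.uniform(-0.5, 0.5, n) * self.thickness_nm
        perp = axis_rad + np.pi / 2.0
        ex = np.array([np.cos(perp), np.sin(perp)])
        ey = np.array([np.cos(axis_rad), np.sin(axis_rad)])
        return np.outer(u, ex) + np.outer(v, ey)


#: mature scaffold: bar 400 x 60 nm; immature cluster: disk of area 0.008 um^2
MATURE_SHAPE = ClusterShape.bar(400.0, 60.0)
IMMATURE_SHAPE = ClusterShape.disk_of_area(0.008)


@dataclass(frozen=True)
class SynapseModel:
    """Geometry and labeling statistics of a simulated synapse population.

    ``true_separation_nm`` is the 3D distance D between the two
    protein-cluster centers; the observable in-plane separation of a synapse
    is D*sin(theta) where theta is the angle between its trans-synaptic axis
    and the optical axis. Under ``orientation_mode="isotropic_3d"`` the axis
    is uniform on the hemisphere, i.e. cos(theta) ~ U[0, 1].
    """

    true_separation_nm: float = 180.0
    cluster_shapes: tuple[ClusterShape, ClusterShape] = (IMMATURE_SHAPE, IMMATURE_SHAPE)
    labels_per_cluster: int = 25
    localizations_per_label: float = 4.0
    localization_precision_nm: float = 10.0
    orientation_mode: str = "isotropic_3d"  # "isotropic_3d" | "fixed"
    fixed_theta_rad: float = math.pi / 2.0
    mean_photons: float = 1000.0
    psf_sigma_nm: float = 100.0

    def __post_init__(self):
        if self.true_separation_nm < 0:
            raise InvalidArgumentError("true_separation_nm must be >= 0")
        if self.localization_precision_nm < 0:
            raise InvalidArgumentError("localization_precision_nm must be >= 0")
        if self.labels_per_cluster < 1:
            raise InvalidArgumentError("labels_per_cluster must be >= 1")
        if self.orientation_mode not in ("isotropic_3d", "fixed"):
            raise InvalidArgumentError(f"unknown orientation_mode '{self.orientation_mode}'")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic dataset.

    ``synapses`` has one row per synapse (true_separation_nm, theta_rad,
    true_projected_nm = D*sin(theta), in-plane center and azimuth);
    ``emitters`` has one row per label with its true coordinates;
    ``drift_nm`` is the injected per-frame drift, ``transform`` the injected
    channel transform, when present.
    """

    synapses: Optional[pd.DataFrame] = None
    emitters: Optional[pd.DataFrame] = None
    drift_nm: Optional[np.ndarray] = None
    transform: Optional[object] = None

    def to_json(self, path) -> None:
        payload = {}
        if self.synapses is not None:
            payload["synapses"] = self.synapses.to_dict(orient="list")
        if self.emitters is not None:
            payload["emitters"] = self.emitters.to_dict(orient="list")
        if self.drift_nm is not None:
            payload["drift_nm"] = np.asarray(self.drift_nm).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera/photophysics settings for frame-stack simulation.

    Defaults follow typical dSTORM acquisition (20 ms exposure); PAINT-style
    binding uses 200 ms exposure and the binding-rate parameters. Noise is
    Poisson shot noise on the expected image plus Gaussian read noise;
    ``shot_noise=False`` gives the deterministic expected image (useful for
    photon-conservation checks).
    """

    n_frames: int = 100
    exposure_ms: float = 20.0
    mode: str = "dstorm_blinking"  # "dstorm_blinking" | "paint_binding"
    photons_per_event: float = 1000.0
    background_photons_per_pixel: float = 0.0
    psf_sigma_nm: float = 100.0
    camera_pixel_nm: float = 100.0
    fov_px: tuple[int, int] = (64, 64)  # (rows, cols) = (y, x)
    on_probability_per_frame: float = 0.005
    binding_rate_per_site_per_frame: float = 0.002
    mean_bound_frames: float = 2.0
    shot_noise: bool = True
    read_noise_sigma: float = 0.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InvalidArgumentError("n_frames must be >= 1")
        if self.camera_pixel_nm <= 0:
            raise InvalidArgumentError("camera_pixel_nm must be > 0")
        if self.psf_sigma_nm <= 0:
            raise InvalidArgumentError("psf_sigma_nm must be > 0")
        if self.mode not in ("dstorm_blinking", "paint_binding"):
            raise InvalidArgumentError(f"unknown acquisition mode '{self.mode}'")


@dataclass
class FrameStack:
    """Time-ordered grayscale stack with pixel-size metadata.

    ``frames`` is (n_frames, rows, cols); row r covers y in
    [r*px, (r+1)*px) nm, column c covers x likewise.
    """

    frames: np.ndarray
    pixel_size_nm: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def write_tiff(self, path) -> None:
        import tifffile

        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        res = 1e7 / self.pixel_size_nm  # pixels per cm
        tifffile.imwrite(
            path,
            data,
            resolution=(res, res),
            resolutionunit="CENTIMETER",
            metadata={"pixel_size_nm": self.pixel_size_nm},
        )


@dataclass(frozen=True)
class NeuriteModel:
    """A curvilinear neurite ribbon carrying discrete protein clusters.

    The centerline is a polyline in nm; clusters are dropped along it as a
    Poisson process at ``punctae_per_um``, each a uniformly filled disk whose
    area is log-normal with the given median; a diffuse localization
    background fills the ribbon. ``fov_pad_nm`` of empty field surrounds the
    ribbon so that the image-average density is far below the neurite
    density, as in a real field of view where neurites occupy a small
    fraction of the image.
    """

    path_nm: tuple = ((0.0, 0.0), (50000.0, 0.0))
    punctae_per_um: float = 0.5
    cluster_area_um2_median: float = 0.008
    cluster_area_sigma_ln: float = 0.3
    background_density_per_um2: float = 25.0
    cluster_density_per_um2: float = 12500.0
    width_nm: float = 1000.0
    localization_precision_nm: float = 10.0
    fov_pad_nm: float = 5000.0

    def __post_init__(self):
        if len(self.path_nm) < 2:
            raise InvalidArgumentError("neurite path needs >= 2 vertices")
        if self.length_um <= 0:
            raise InvalidArgumentError("neurite path has zero length")
        if self.punctae_per_um < 0:
            raise InvalidArgumentError("punctae_per_um must be >= 0")

    @property
    def length_um(self) -> float:
        pts = np.asarray(self.path_nm, dtype=float)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)) / 1000.0)


@dataclass
class NeuriteField:
    """Output of :func:`generate_neurite_field`."""

    table: pd.DataFrame
    clusters: pd.DataFrame  # truth: center_x_nm, center_y_nm, area_um2, n_locs
    length_um: float
    region_nm: tuple  # (xmin, ymin, xmax, ymax) analysis rectangle


# --------------------------------------------------------------------------
# synapse populations


def sample_orientations(model: SynapseModel, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw n trans-synaptic axis polar angles and their projected separations.

    Under ``isotropic_3d`` the axis is uniform on the hemisphere, i.e.
    cos(theta) ~ U[0, 1]; the in-plane (observable) separation of a synapse
    is ``true_separation_nm * sin(theta)``. Accepts a Generator or a seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if model.orientation_mode == "isotropic_3d":
        theta = np.arccos(rng.random(n))
    else:
        theta = np.full(n, model.fixed_theta_rad)
    return theta, model.true_separation_nm * np.sin(theta)


def sample_synapse_population(
    model: SynapseModel,
    n_synapses: int,
    seed: int,
    channels: Sequence[str] = ("A", "B"),
    n_frames: int = 1000,
    spacing_nm: float = 2000.0,
):
    """Simulate a two-color synapse population with known projection geometry.

    Synapses are laid out on a jittered grid (spacing ``spacing_nm``) so that
    neighboring synapses never contaminate each other's 400 nm ROI. For each
    synapse the trans-synaptic axis orientation is drawn (cos(theta) uniform
    on [0,1] for ``isotropic_3d``), the two cluster centers are placed
    ``D*sin(theta)`` apart along a uniform in-plane azimuth, labels are
    scattered over each cluster's footprint, and every label emits a
    Poisson number of localizations, each displaced by isotropic Gaussian
    localization error.

    Returns ``(table, truth)``.
    """
    if n_synapses < 1:
        raise InvalidArgumentError("n_synapses must be >= 1")
    if len(channels) != 2:
        raise InvalidArgumentError("exactly two channels required")
    rng = np.random.default_rng(seed)

    # grid layout with jitter
    ncols = int(math.ceil(math.sqrt(n_synapses)))
    idx = np.arange(n_synapses)
    gx = (idx % ncols + 0.5) * spacing_nm
    gy = (idx // ncols + 0.5) * spacing_nm
    jitter = rng.uniform(-0.1, 0.1, (n_synapses, 2)) * spacing_nm
    centers = np.column_stack([gx, gy]) + jitter

    theta, projected = sample_orientations(model, n_synapses, rng)
    azimuth = rng.uniform(0.0, 2.0 * np.pi, n_synapses)

    rows_x, rows_y, rows_ch, rows_id, rows_frame = [], [], [], [], []
    em_x, em_y, em_ch, em_id = [], [], [], []
    half = 0.5 * projected
    ex, ey = np.cos(azimuth), np.sin(azimuth)
    for i in range(n_synapses):
        for side, ch in zip((-1.0, 1.0), channels):
            shape = model.cluster_shapes[0 if side < 0 else 1]
            c = centers[i] + side * half[i] * np.array([ex[i], ey[i]])
            offs = shape.sample_offsets(model.labels_per_cluster, azimuth[i], rng)
            labels = c + offs
            em_x.append(labels[:, 0]); em_y.append(labels[:, 1])
            em_ch.extend([ch] * len(labels)); em_id.extend([i] * len(labels))
            nloc = rng.poisson(model.localizations_per_label, model.labels_per_cluster)
            pos = np.repeat(labels, nloc, axis=0)
            pos = pos + rng.normal(0.0, model.localization_precision_nm, pos.shape)
            rows_x.append(pos[:, 0]); rows_y.append(pos[:, 1])
            rows_ch.extend([ch] * len(pos)); rows_id.extend([i] * len(pos))
            rows_frame.append(rng.integers(0, n_frames, len(pos)))

    x = np.concatenate(rows_x); y = np.concatenate(rows_y)
    n = len(x)
    table = make_table(
        x,
        y,
        frame=np.concatenate(rows_frame),
        intensity_photons=rng.gamma(4.0, model.mean_photons / 4.0, n),
        sigma_nm=model.psf_sigma_nm * np.sqrt(2.0) * rng.normal(1.0, 0.03, n),
        asymmetry=1.0 + np.abs(rng.normal(0.0, 0.08, n)),
        channel=np.asarray(rows_ch, dtype=object),
        synapse_id=np.asarray(rows_id),
    )
    truth = SyntheticTruth(
        synapses=pd.DataFrame(
            {
                "synapse_id": idx,
                "true_separation_nm": model.true_separation_nm,
                "theta_rad": theta,
                "true_projected_nm": projected,
                "center_x_nm": centers[:, 0],
                "center_y_nm": centers[:, 1],
                "azimuth_rad": azimuth,
            }
        ),
        emitters=pd.DataFrame(
            {
                "synapse_id": np.asarray(em_id),
                "x_nm": np.concatenate(em_x),
                "y_nm": np.concatenate(em_y),
                "channel": np.asarray(em_ch, dtype=object),
            }
        ),
    )
    return table, truth


def inject_drift(table: pd.DataFrame, drift_nm: np.ndarray) -> pd.DataFrame:
    """Return a copy of ``table`` with per-frame drift added to x/y."""
    drift_nm = np.asarray(drift_nm, dtype=float)
    frames = table["frame"].to_numpy(dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= len(drift_nm)):
        raise InvalidArgumentError("drift trajectory does not cover all frames")
    out = table.copy()
    out["x_nm"] = out["x_nm"].to_numpy() + drift_nm[frames, 0]
    out["y_nm"] = out["y_nm"].to_numpy() + drift_nm[frames, 1]
    return out


def linear_drift(n_frames: int, total_dx_nm: float, total_dy_nm: float) -> np.ndarray:
    """Per-frame drift ramping linearly from (0,0) to the given endpoint."""
    t = np.linspace(0.0, 1.0, n_frames)
    return np.column_stack([t * total_dx_nm, t * total_dy_nm])


def random_walk_drift(n_frames: int, step_nm: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_nm, (n_frames, 2))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


# --------------------------------------------------------------------------
# frame-stack simulation


def _pixel_integrated_gaussian(shape, x_px, y_px, sigma_px, photons, halfwidth=6.0):
    """Accumulate pixel-integrated 2D Gaussians onto an image.

    Integration uses the error function so that (up to a ~1e-9 truncation at
    ``halfwidth`` sigmas) each spot deposits exactly ``photons`` counts.
    """
    img = np.zeros(shape, dtype=float)
    h, w = shape
    r = max(2, int(math.ceil(halfwidth * sigma_px)))
    inv = 1.0 / (math.sqrt(2.0) * sigma_px)
    for x0, y0, n in zip(x_px, y_px, photons):
        c0 = max(0, int(math.floor(x0)) - r)
        c1 = min(w, int(math.floor(x0)) + r + 1)
        r0 = max(0, int(math.floor(y0)) - r)
        r1 = min(h, int(math.floor(y0)) + r + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xe = np.arange(c0, c1 + 1, dtype=float)
        ye = np.arange(r0, r1 + 1, dtype=float)
        fx = 0.5 * (1.0 + erf((xe - x0) * inv))
        fy = 0.5 * (1.0 + erf((ye - y0) * inv))
        img[r0:r1, c0:c1] += n * np.outer(np.diff(fy), np.diff(fx))
    return img


def _event_schedule(n_emitters: int, acq: AcquisitionModel, rng: np.random.Generator):
    """Per-frame activation matrix (n_frames, n_emitters) of booleans."""
    if acq.mode == "dstorm_blinking":
        return rng.random((acq.n_frames, n_emitters)) < acq.on_probability_per_frame
    active = np.zeros((acq.n_frames, n_emitters), dtype=bool)
    p_bind = acq.binding_rate_per_site_per_frame
    p_off = 1.0 / max(acq.mean_bound_frames, 1e-9)
    for j in range(n_emitters):
        t = int(rng.geometric(p_bind)) - 1 if p_bind > 0 else acq.n_frames
        while t < acq.n_frames:
            dur = int(rng.geometric(p_off))
            active[t : min(t + dur, acq.n_frames), j] = True
            t += dur + int(rng.geometric(p_bind))
    return active


def simulate_acquisition(
    truth_emitters,
    acq: AcquisitionModel,
    seed: int,
    drift_nm: Optional[np.ndarray] = None,
    fiducials=None,
    always_on: bool = False,
):
    """Render a synthetic camera stack from true emitter positions.

    ``truth_emitters`` is an (N, 2) array of nm coordinates (or a DataFrame
    with x_nm/y_nm). Fiducials appear in every frame. Returns
    ``(FrameStack, events)`` where ``events`` is a ground-truth table linking
    every rendered spot (frame, emitter index, drifted true position in nm,
    photons) to its emitter.
    """
    if isinstance(truth_emitters, pd.DataFrame):
        emitters = truth_emitters[["x_nm", "y_nm"]].to_numpy(dtype=float)
    else:
        emitters = np.atleast_2d(np.asarray(truth_emitters, dtype=float))
    h, w = acq.fov_px
    fov_x = w * acq.camera_pixel_nm
    fov_y = h * acq.camera_pixel_nm
    if emitters.size and (
        emitters[:, 0].min() < 0
        or emitters[:, 1].min() < 0
        or emitters[:, 0].max() > fov_x
        or emitters[:, 1].max() > fov_y
    ):
        raise InvalidArgumentError("emitters fall outside the field of view")
    rng = np.random.default_rng(seed)
    if drift_nm is None:
        drift_nm = np.zeros((acq.n_frames, 2))
    drift_nm = np.asarray(drift_nm, dtype=float)
    if drift_nm.shape[0] != acq.n_frames:
        raise InvalidArgumentError("drift trajectory length != n_frames")
    fid = (
        np.atleast_2d(np.asarray(fiducials, dtype=float))
        if fiducials is not None and len(fiducials)
        else np.zeros((0, 2))
    )

    if always_on:
        active = np.ones((acq.n_frames, len(emitters)), dtype=bool)
    else:
        active = _event_schedule(len(emitters), acq, rng)

    sigma_px = acq.psf_sigma_nm / acq.camera_pixel_nm
    frames = np.empty((acq.n_frames, h, w), dtype=float)
    ev_frame, ev_id, ev_x, ev_y, ev_photons = [], [], [], [], []
    for f in range(acq.n_frames):
        ids = np.flatnonzero(active[f])
        pos = np.vstack([emitters[ids] + drift_nm[f], fid + drift_nm[f]]) if len(fid) else emitters[ids] + drift_nm[f]
        nspots = len(pos)
        photons = np.full(nspots, acq.photons_per_event)
        img = acq.background_photons_per_pixel + _pixel_integrated_gaussian(
            (h, w),
            pos[:, 0] / acq.camera_pixel_nm,
            pos[:, 1] / acq.camera_pixel_nm,
            sigma_px,
            photons,
        )
        if acq.shot_noise:
            img = rng.poisson(img).astype(float)
        if acq.read_noise_sigma > 0:
            img = img + rng.normal(0.0, acq.read_noise_sigma, img.shape)
        frames[f] = img
        ev_frame.extend([f] * len(ids))
        ev_id.extend(ids.tolist())
        ev_x.extend((emitters[ids, 0] + drift_nm[f, 0]).tolist())
        ev_y.extend((emitters[ids, 1] + drift_nm[f, 1]).tolist())
        ev_photons.extend([acq.photons_per_event] * len(ids))
    events = pd.DataFrame(
        {
            "frame": np.asarray(ev_frame, dtype=int),
            "emitter_id": np.asarray(ev_id, dtype=int),
            "x_nm": np.asarray(ev_x, dtype=float),
            "y_nm": np.asarray(ev_y, dtype=float),
            "photons": np.asarray(ev_photons, dtype=float),
        }
    )
    return FrameStack(frames=frames, pixel_size_nm=acq.camera_pixel_nm), events


# --------------------------------------------------------------------------
# neurite fields


def _sample_along_path(path: np.ndarray, arclens: np.ndarray):
    """Positions and unit tangents at given arclengths along a polyline."""
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    arclens = np.clip(arclens, 0.0, cum[-1])
    i = np.clip(np.searchsorted(cum, arclens, side="right") - 1, 0, len(seg) - 1)
    frac = (arclens - cum[i]) / np.where(seglen[i] > 0, seglen[i], 1.0)
    pos = path[i] + seg[i] * frac[:, None]
    tang = seg[i] / np.where(seglen[i] > 0, seglen[i], 1.0)[:, None]
    return pos, tang


def generate_neurite_field(model: NeuriteModel, seed: int) -> NeuriteField:
    """Simulate a neurite localization field with ground-truth clusters.

    Cluster count is Poisson(length * punctae_per_um); cluster centers sit
    uniformly along the centerline with a small lateral offset inside the
    ribbon; each cluster is a uniform disk of log-normal area filled at
    ``cluster_density_per_um2``, blurred by the localization precision.
    Diffuse background fills the ribbon at ``background_density_per_um2``.
    """
    rng = np.random.default_rng(seed)
    path = np.asarray(model.path_nm, dtype=float)
    total_nm = model.length_um * 1000.0

    n_clusters = rng.poisson(model.length_um * model.punctae_per_um)
    s = np.sort(rng.uniform(0.0, total_nm, n_clusters))
    pos, tang = _sample_along_path(path, s)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    lateral = rng.uniform(-0.25, 0.25, n_clusters) * model.width_nm
    centers = pos + normal * lateral[:, None]
    areas_um2 = model.cluster_area_um2_median * np.exp(
        rng.normal(0.0, model.cluster_area_sigma_ln, n_clusters)
    )

    xs, ys = [], []
    n_locs = np.zeros(n_clusters, dtype=int)
    for i in range(n_clusters):
        n = max(3, int(rng.poisson(areas_um2[i] * model.cluster_density_per_um2)))
        n_locs[i] = n
        radius = 1000.0 * math.sqrt(areas_um2[i] / math.pi)
        r = radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        p = centers[i] + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        p += rng.normal(0.0, model.localization_precision_nm, p.shape)
        xs.append(p[:, 0]); ys.append(p[:, 1])

    ribbon_area_um2 = model.length_um * (model.width_nm / 1000.0)
    n_bg = rng.poisson(model.background_density_per_um2 * ribbon_area_um2)
    s_bg = rng.uniform(0.0, total_nm, n_bg)
    pos_bg, tang_bg = _sample_along_path(path, s_bg)
    normal_bg = np.column_stack([-tang_bg[:, 1], tang_bg[:, 0]])
    lat_bg = rng.uniform(-0.5, 0.5, n_bg) * model.width_nm
    bg = pos_bg + normal_bg * lat_bg[:, None]
    xs.append(bg[:, 0]); ys.append(bg[:, 1])

    x = np.concatenate(xs) if xs else np.zeros(0)
    y = np.concatenate(ys) if ys else np.zeros(0)
    is_cluster = np.concatenate(
        [np.ones(int(k), dtype=int) for k in n_locs] + [np.zeros(n_bg, dtype=int)]
    ) if len(x) else np.zeros(0, dtype=int)
    order = rng.permutation(len(x))
    table = make_table(
        x[order],
        y[order],
        frame=rng.integers(0, 10000, len(x)),
        channel="FUS",
        in_cluster=is_cluster[order],
    )
    pad = model.fov_pad_nm
    xmin = min(path[:, 0].min(), x.min() if len(x) else 0.0) - pad
    xmax = max(path[:, 0].max(), x.max() if len(x) else 0.0) + pad
    ymin = min(path[:, 1].min(), y.min() if len(x) else 0.0) - pad
    ymax = max(path[:, 1].max(), y.max() if len(x) else 0.0) + pad
    clusters = pd.DataFrame(
        {
            "cluster_id": np.arange(n_clusters),
            "center_x_nm": centers[:, 0] if n_clusters else np.zeros(0),
            "center_y_nm": centers[:, 1] if n_clusters else np.zeros(0),
            "area_um2": areas_um2,
            "n_locs": n_locs,
        }
    )
    return NeuriteField(
        table=table,
        clusters=clusters,
        length_um=model.length_um,
        region_nm=(xmin, ymin, xmax, ymax),
    )
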