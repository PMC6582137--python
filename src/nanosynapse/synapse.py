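"""Trans-synaptic distance analysis.

Each synapse is an oriented rectangular ROI (long side 400 nm along the
trans-synaptic axis). The center of mass of each protein channel's
localizations inside the ROI is computed, and the per-synapse distance is
the Euclidean distance between the two channel COMs. Because 3D synapses are
projected into the 2D image plane, a randomly oriented synapse shows only
D*sin(theta) of its true separation D; the population statistic therefore
averages only the top 40% of measured distances ("side-view" synapses),
bins the distances in a 10 nm histogram, and rounds the mean up to the next
multiple of 10 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError, ROIRejectedError

#: colocalizing protein clusters below this area are developing synapses
SMALL_SYNAPSE_CUTOFF_UM2 = 0.03
#: mean of the largest TOP_FRACTION of distances corrects projection error
TOP_FRACTION = 0.4
HISTOGRAM_BIN_NM = 10.0
ROI_LONG_SIDE_NM = 400.0


@dataclass(frozen=True)
class SynapseROI:
    """Oriented rectangle marking one synapse.

    The long side (default 400 nm) lies along the trans-synaptic axis;
    ``angle_deg`` is the angle of that axis in the image plane.
    """

    center_x_nm: float
    center_y_nm: float
    angle_deg: float = 0.0
    long_nm: float = ROI_LONG_SIDE_NM
    short_nm: float = 250.0

    def __post_init__(self):
        if self.long_nm <= 0 or self.short_nm <= 0:
            raise InvalidArgumentError("ROI side lengths must be > 0")

    def contains(self, x_nm, y_nm) -> np.ndarray:
        """Boolean mask of points inside the rectangle."""
        a = math.radians(self.angle_deg)
        dx = np.asarray(x_nm, dtype=float) - self.center_x_nm
        dy = np.asarray(y_nm, dtype=float) - self.center_y_nm
        u = dx * math.cos(a) + dy * math.sin(a)      # along the long axis
        v = -dx * math.sin(a) + dy * math.cos(a)
        return (np.abs(u) <= self.long_nm / 2.0) & (np.abs(v) <= self.short_nm / 2.0)

    def polygon_nm(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        e1 = np.array([math.cos(a), math.sin(a)]) * self.long_nm / 2.0
        e2 = np.array([-math.sin(a), math.cos(a)]) * self.short_nm / 2.0
        c = np.array([self.center_x_nm, self.center_y_nm])
        return np.array([c - e1 - e2, c + e1 - e2, c + e1 + e2, c - e1 + e2])


def read_rois(path) -> list:
    """Read ROI rectangles from CSV (center_x_nm, center_y_nm, angle_deg, long_nm, short_nm)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SynapseROI(
                center_x_nm=float(row["center_x_nm"]),
                center_y_nm=float(row["center_y_nm"]),
                angle_deg=float(row.get("angle_deg", 0.0)),
                long_nm=float(row.get("long_nm", ROI_LONG_SIDE_NM)),
                short_nm=float(row.get("short_nm", 250.0)),
            )
        )
    return out


def write_rois(rois: Sequence[SynapseROI], path) -> None:
    pd.DataFrame(
        {
            "center_x_nm": [r.center_x_nm for r in rois],
            "center_y_nm": [r.center_y_nm for r in rois],
            "angle_deg": [r.angle_deg for r in rois],
            "long_nm": [r.long_nm for r in rois],
            "short_nm": [r.short_nm for r in rois],
        }
    ).to_csv(path, index=False)


def cluster_com(
    table: pd.DataFrame,
    roi: SynapseROI,
    channel: str,
    min_locs: int = 10,
) -> np.ndarray:
    """Unweighted COM of one channel's localizations inside the ROI.

    The COM deliberately ignores photon weights so that photometry never
    couples into geometry. Raises :class:`ROIRejectedError` when fewer than
    ``min_locs`` localizations of the channel fall inside the ROI.
    """
    ch = table.loc[table["channel"] == channel]
    if len(ch) == 0:
        raise ROIRejectedError(f"channel '{channel}' absent in ROI")
    inside = ch.loc[roi.contains(ch["x_nm"], ch["y_nm"])]
    if len(inside) < min_locs:
        raise ROIRejectedError(
            f"channel '{channel}': {len(inside)} < {min_locs} localizations in ROI"
        )
    return inside[["x_nm", "y_nm"]].to_numpy(dtype=float).mean(axis=0)


def synapse_distance(
    table: pd.DataFrame,
    roi: SynapseROI,
    channels: Sequence[str],
    min_locs: int = 10,
) -> float:
    """Euclidean distance between the two channel COMs in one ROI."""
    if len(channels) != 2:
        raise InvalidArgumentError("exactly two channels required")
    a = cluster_com(table, roi, channels[0], min_locs)
    b = cluster_com(table, roi, channels[1], min_locs)
    return float(np.linalg.norm(a - b))


@dataclass
class DistanceSet:
    """Per-synapse COM distances plus bookkeeping of rejected ROIs."""

    distances_nm: np.ndarray
    coms: pd.DataFrame            # roi_index, channel, com_x_nm, com_y_nm, n_locs
    rejected: list = field(default_factory=list)  # (roi_index, reason)

    @property
    def n(self) -> int:
        return len(self.distances_nm)


def measure_distances(
    table: pd.DataFrame,
    rois: Sequence[SynapseROI],
    channels: Sequence[str],
    min_locs: int = 10,
) -> DistanceSet:
    """COM distance for every ROI; rejected ROIs are recorded, not dropped silently."""
    dists, rows, rejected = [], [], []
    for i, roi in enumerate(rois):
        try:
            coms = {}
            for ch in channels:
                ch_tab = table.loc[table["channel"] == ch]
                if len(ch_tab) == 0:
                    raise ROIRejectedError(f"channel '{ch}' absent in ROI")
                inside = ch_tab.loc[roi.contains(ch_tab["x_nm"], ch_tab["y_nm"])]
                if len(inside) < min_locs:
                    raise ROIRejectedError(
                        f"channel '{ch}': {len(inside)} < {min_locs} localizations in ROI"
                    )
                coms[ch] = inside[["x_nm", "y_nm"]].to_numpy(dtype=float).mean(axis=0)
                rows.append(
                    {
                        "roi_index": i,
                        "channel": ch,
                        "com_x_nm": coms[ch][0],
                        "com_y_nm": coms[ch][1],
                        "n_locs": len(inside),
                    }
                )
        except ROIRejectedError as exc:
            rejected.append((i, exc.reason))
            continue
        dists.append(float(np.linalg.norm(coms[channels[0]] - coms[channels[1]])))
    return DistanceSet(
        distances_nm=np.asarray(dists, dtype=float),
        coms=pd.DataFrame(rows, columns=["roi_index", "channel", "com_x_nm", "com_y_nm", "n_locs"]),
        rejected=rejected,
    )


def round_up_to_bin(value_nm: float, bin_nm: float = HISTOGRAM_BIN_NM) -> float:
    """Round up to the next multiple of ``bin_nm``; exact multiples unchanged."""
    q = value_nm / bin_nm
    # tolerate float representation of exact multiples
    if abs(q - round(q)) < 1e-9:
        return round(q) * bin_nm
    return math.ceil(q) * bin_nm


@dataclass
class Top40Summary:
    n_synapses: int
    k: int
    mean_top40_nm: float           # pre-rounding
    mean_top40_rounded_nm: float   # rounded up to the next 10 nm
    sem_top40_nm: float
    bin_edges_nm: np.ndarray
    counts: np.ndarray
    counts_top40: np.ndarray       # the top-40% subset, flagged separately

    def to_dict(self) -> dict:
        return {
            "n_synapses": self.n_synapses,
            "k": self.k,
            "mean_top40_nm": self.mean_top40_nm,
            "mean_top40_rounded_nm": self.mean_top40_rounded_nm,
            "sem_top40_nm": self.sem_top40_nm,
        }


def top40_summary(
    distances_nm,
    top_fraction: float = TOP_FRACTION,
    bin_nm: float = HISTOGRAM_BIN_NM,
) -> Top40Summary:
    """Projection-corrected population distance.

    Sorts descending, keeps the k = ceil(top_fraction * n) largest distances,
    reports their mean (and the mean rounded up to the next multiple of
    ``bin_nm``), SEM, and the 10 nm histogram with the top subset flagged.
    """
    if isinstance(distances_nm, DistanceSet):
        distances_nm = distances_nm.distances_nm
    d = np.sort(np.asarray(distances_nm, dtype=float))[::-1]
    n = len(d)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 distances, got {n}")
    k = math.ceil(top_fraction * n)
    top = d[:k]
    mean = float(top.mean())
    sem = float(top.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    edges = np.arange(0.0, (math.floor(d[0] / bin_nm) + 2) * bin_nm, bin_nm)
    counts, _ = np.histogram(d, bins=edges)
    counts_top, _ = np.histogram(top, bins=edges)
    return Top40Summary(
        n_synapses=n,
        k=k,
        mean_top40_nm=mean,
        mean_top40_rounded_nm=round_up_to_bin(mean, bin_nm),
        sem_top40_nm=sem,
        bin_edges_nm=edges,
        counts=counts,
        counts_top40=counts_top,
    )


def classify_synapse_size(cluster_area_um2: float) -> str:
    """'small' (developing) below 0.03 um^2, else 'large' (mature); strict <."""
    if cluster_area_um2 < 0:
        raise InvalidArgumentError("area must be >= 0")
    return "small" if cluster_area_um2 < SMALL_SYNAPSE_CUTOFF_UM2 else "large"


def propose_rois(
    table: pd.DataFrame,
    channels: Sequence[str],
    max_gap_nm: float = 400.0,
    long_nm: float = ROI_LONG_SIDE_NM,
    short_nm: float = 250.0,
    neighborhood_nm: float = 600.0,
    min_locs: int = 10,
) -> list:
    """Reproducible surrogate for manual synapse picking.

    Candidate synapses are mutual-nearest pairs of cross-channel tessellation
    clusters whose centroid gap is below ``max_gap_nm``; each ROI is centered
    between the two provisional channel COMs, its long axis along the line
    joining them, refined once after restricting to the ROI.
    """
    from .tessellate import segment_clusters, segment_objects, voronoi_density

    cents = {}
    for ch in channels:
        sub = table.loc[table["channel"] == ch]
        if len(sub) < 4:
            return []
        field_ = voronoi_density(sub[["x_nm", "y_nm"]].to_numpy(dtype=float))
        clusters = segment_clusters(field_, segment_objects(field_))
        if not clusters.clusters:
            return []
        cents[ch] = np.array([c.centroid_nm for c in clusters.clusters])
    a, b = cents[channels[0]], cents[channels[1]]
    # mutual nearest neighbors across channels
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    nn_a = d.argmin(axis=1)
    nn_b = d.argmin(axis=0)
    rois = []
    for i, j in enumerate(nn_a):
        if nn_b[j] != i or d[i, j] > max_gap_nm:
            continue
        center = 0.5 * (a[i] + b[j])
        axis = b[j] - a[i]
        angle = math.degrees(math.atan2(axis[1], axis[0])) if np.linalg.norm(axis) > 0 else 0.0
        roi = SynapseROI(center[0], center[1], angle, long_nm, short_nm)
        # one refinement: recompute channel COMs inside the ROI, re-orient
        try:
            ca = cluster_com(table, roi, channels[0], min_locs)
            cb = cluster_com(table, roi, channels[1], min_locs)
        except ROIRejectedError:
            continue
        center = 0.5 * (ca + cb)
        axis = cb - ca
        if np.linalg.norm(axis) > 0:
            angle = math.degrees(math.atan2(axis[1], axis[0]))
        rois.append(SynapseROI(center[0], center[1], angle, long_nm, short_nm))
    return rois
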