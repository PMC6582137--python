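"""Configuration and the end-to-end pipeline driver.

``PipelineConfig`` collects every tunable parameter of every stage, with
defaults equal to the analysis constants the method prescribes (400 nm ROI
long side, 10 nm raster and histogram bins, top-40% fraction, 0.03 um^2
size cutoff, object factor 2, cluster factor 3, 0.0005 um^2 minimum cluster
area, ROUT Q = 0.5%). ``run_pipeline`` wires
simulation -> drift correction -> distance analysis -> tessellation ->
statistics and emits a machine-readable JSON report with a provenance block
(parameter echo, seed, package version), so any run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .correct import apply_correction, estimate_drift_rcc
from .errors import PipelineStageError
from .simulate import (
    ClusterShape,
    NeuriteModel,
    SynapseModel,
    generate_neurite_field,
    inject_drift,
    linear_drift,
    sample_synapse_population,
)
from .stats import rout_outliers, summarize
from .synapse import SynapseROI, measure_distances, top40_summary
from .tessellate import punctae_per_micron, segment_clusters, segment_objects, voronoi_density

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0

    # simulation stage
    simulate: bool = True
    n_synapses: int = 272
    true_separation_nm: float = 180.0
    cluster_shape: str = "disk"          # "disk" | "bar" | "point"
    cluster_area_um2: float = 0.008
    labels_per_cluster: int = 25
    localizations_per_label: float = 4.0
    localization_precision_nm: float = 10.0
    n_frames: int = 1000
    drift_endpoint_nm: tuple = (0.0, 0.0)

    # correction stage
    correct_drift: bool = True
    rcc_segments: int = 10
    rcc_bin_nm: float = 10.0

    # distance stage (analysis constants)
    roi_long_nm: float = 400.0
    roi_short_nm: float = 250.0
    render_pixel_nm: float = 10.0
    histogram_bin_nm: float = 10.0
    top_fraction: float = 0.4
    size_cutoff_um2: float = 0.03
    min_roi_locs: int = 10

    # tessellation stage
    tessellate: bool = True
    punctae_per_um: float = 0.5
    neurite_length_um: float = 60.0
    object_factor: float = 2.0
    cluster_factor: float = 3.0
    min_cluster_area_um2: float = 0.0005

    # statistics stage
    rout_q_percent: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drift_endpoint_nm" in raw:
            raw["drift_endpoint_nm"] = tuple(raw["drift_endpoint_nm"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift_endpoint_nm"] = list(d["drift_endpoint_nm"])
        return d


def _shape(config: PipelineConfig) -> ClusterShape:
    if config.cluster_shape == "bar":
        return ClusterShape.bar(400.0, 60.0)
    if config.cluster_shape == "point":
        return ClusterShape.disk(0.0)
    return ClusterShape.disk_of_area(config.cluster_area_um2)


def _provenance(config: PipelineConfig) -> dict:
    params = config.to_dict()
    blob = json.dumps(params, sort_keys=True).encode()
    return {
        "software": "nanosynapse",
        "version": __version__,
        "parameters": params,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the enabled stages in order and return the JSON-able report."""
    report = {"provenance": _provenance(config), "stages": {}}
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    # --- simulate ---------------------------------------------------------
    try:
        shape = _shape(config)
        model = SynapseModel(
            true_separation_nm=config.true_separation_nm,
            cluster_shapes=(shape, shape),
            labels_per_cluster=config.labels_per_cluster,
            localizations_per_label=config.localizations_per_label,
            localization_precision_nm=config.localization_precision_nm,
        )
        table, truth = sample_synapse_population(
            model, config.n_synapses, seed=int(seeds[0]), n_frames=config.n_frames
        )
        drift = linear_drift(config.n_frames, *config.drift_endpoint_nm)
        table = inject_drift(table, drift)
        truth.drift_nm = drift
        report["stages"]["simulate"] = {
            "n_synapses": config.n_synapses,
            "n_localizations": int(len(table)),
            "true_separation_nm": config.true_separation_nm,
            "injected_drift_endpoint_nm": list(config.drift_endpoint_nm),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate", exc) from exc

    # --- drift correction -------------------------------------------------
    if config.correct_drift:
        try:
            traj = estimate_drift_rcc(
                table,
                n_frames=config.n_frames,
                n_segments=config.rcc_segments,
                bin_nm=config.rcc_bin_nm,
            )
            table = apply_correction(table, drift=traj)
            endpoint = traj.displacement_nm[-1]
            err = endpoint - (drift[-1] - drift[0])
            report["stages"]["drift"] = {
                "estimated_endpoint_nm": [round(float(v), 6) for v in endpoint],
                "endpoint_error_nm": round(float(np.hypot(*err)), 6),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("drift", exc) from exc

    # --- distance analysis ------------------------------------------------
    try:
        rois = [
            SynapseROI(
                row.center_x_nm,
                row.center_y_nm,
                np.degrees(row.azimuth_rad),
                config.roi_long_nm,
                config.roi_short_nm,
            )
            for row in truth.synapses.itertuples()
        ]
        dset = measure_distances(table, rois, ("A", "B"), min_locs=config.min_roi_locs)
        summary = top40_summary(
            dset, top_fraction=config.top_fraction, bin_nm=config.histogram_bin_nm
        )
        report["stages"]["distance"] = {
            "n_rois": len(rois),
            "n_accepted": int(dset.n),
            "n_rejected": len(dset.rejected),
            **{k: (round(v, 6) if isinstance(v, float) else v) for k, v in summary.to_dict().items()},
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("distance", exc) from exc

    # --- tessellation -----------------------------------------------------
    if config.tessellate:
        try:
            nmodel = NeuriteModel(
                path_nm=((0.0, 0.0), (config.neurite_length_um * 1000.0, 0.0)),
                punctae_per_um=config.punctae_per_um,
            )
            fieldset = generate_neurite_field(nmodel, seed=int(seeds[1]))
            dfield = voronoi_density(
                fieldset.table[["x_nm", "y_nm"]].to_numpy(dtype=float),
                region=fieldset.region_nm,
            )
            objects = segment_objects(dfield, config.object_factor)
            clusters = segment_clusters(
                dfield,
                objects,
                cluster_factor=config.cluster_factor,
                min_area_um2=config.min_cluster_area_um2,
            )
            areas = clusters.areas_um2
            stage = {
                "n_localizations": int(len(fieldset.table)),
                "n_objects": len(objects),
                "n_clusters": len(clusters),
                "n_true_clusters": int(len(fieldset.clusters)),
                "punctae_per_um": round(punctae_per_micron(clusters, fieldset.length_um), 6),
            }
            if len(areas) >= 2:
                mean, sem, n = summarize(areas)
                stage["cluster_area_um2_mean"] = round(mean, 8)
                stage["cluster_area_um2_sem"] = round(sem, 8)
                if n >= 10:
                    rep = rout_outliers(areas, config.rout_q_percent)
                    stage["rout_n_flagged"] = rep.n_flagged
            report["stages"]["tessellation"] = stage
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("tessellation", exc) from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .tables import write_localizations

        write_localizations(table, out_dir / "localizations.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def report_json(report: dict) -> str:
    """Canonical serialization used for bit-identical reproducibility checks."""
    return json.dumps(report, sort_keys=True)
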