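# nanosynapse

Single-molecule localization microscopy (SMLM) resolves synaptic proteins —
presynaptic scaffolds such as Bassoon, postsynaptic densities marked by
Homer1 or PSD95, and RNA-binding proteins such as FUS — at tens-of-nanometer
scale, which is enough to ask *on which side of the synaptic cleft a protein
sits* and *how large its clusters are*. `nanosynapse` is a tested,
end-to-end re-implementation of that analysis chain for dSTORM / DNA-PAINT
data, together with a synthetic-data generator that produces localization
tables and raw camera stacks with complete ground truth, so that every stage
of the chain is quantitatively verifiable without access to microscope data.

It is aimed at microscopists and image-analysis developers who want an
auditable, scriptable version of this pipeline: every stage is a plain
function over a pandas localization table (`frame, x_nm, y_nm,
intensity_photons, sigma_nm, asymmetry, channel`), and every stage can be
fed simulated data whose truth is known.

## What it implements

- **Simulation** (`nanosynapse.simulate`) — two-/three-color synapse
  populations with a known 3D trans-synaptic separation D projected to 2D
  under random orientation; raw blinking/binding frame stacks (pixel-
  integrated Gaussian PSF, Poisson shot noise, read noise, drift,
  fiducials); neurite-like fields of protein punctae on a diffuse
  background.
- **Localization** (`nanosynapse.localize`) — difference-of-Gaussians spot
  detection, background-subtracted center-of-mass (COM) fitting with
  second-moment width `sqrt(l1+l2)` and asymmetry `sqrt(l1/l2)`, and
  intensity/asymmetry/width threshold filtering.
- **Correction** (`nanosynapse.correct`) — redundant cross-correlation
  (RCC) drift estimation (all segment pairs, least-squares combination),
  fiducial-bead drift tracking for PAINT, and bead-based affine channel
  registration.
- **Reconstruction** (`nanosynapse.render`) — intensity-weighted 10 nm
  histogram rendering; Gaussian blur for display only.
- **Synapse geometry** (`nanosynapse.synapse`) — per-synapse COM distances
  inside oriented 400 nm ROIs, the 10 nm distance histogram, the top-40%
  mean statistic, and the 0.03 µm² small/large synapse classifier.
- **Tessellation** (`nanosynapse.tessellate`) — SR-Tesseler-style Voronoï
  density segmentation: objects at 2× average density, clusters at 3× the
  object-local density with a 0.0005 µm² minimum area, cluster areas and
  punctae-per-µm rates.
- **Statistics** (`nanosynapse.stats`) — two-tailed unpaired t-test,
  one-way ANOVA with Tukey HSD, ROUT outlier flagging at Q = 0.5 %, and
  mean ± SEM summaries.
- **Pipeline** (`nanosynapse.pipeline`, `nanosynapse` CLI) — a seeded,
  YAML-configurable driver producing a bit-reproducible JSON report.

## The statistic at the core

A synapse is modeled as two protein clusters whose centers are a distance
*D* apart along the trans-synaptic axis. Imaging projects this 3D geometry
into the focal plane: a synapse whose axis makes polar angle θ with the
optical axis shows only *D*·sin θ. With random orientation (cos θ ~ U[0,1]),
"face-view" synapses (θ ≈ 0) show overlapping clusters while "side-view"
synapses (θ ≈ π/2) show the full separation. The pipeline therefore measures
the Euclidean distance between the two channels' localization COMs for each
synapse ROI, histograms them in 10 nm bins, and reports the mean of the
**top 40 %** of distances, rounded up to the next 10 nm. For an isotropic
population the expectation of that statistic is

    E[top-40% mean] = D · (1/0.4) ∫₀^0.4 √(1−u²) du = 0.97265·D,

so it recovers *D* to within ~3 % before noise — this closed form is the
package's primary acceptance oracle.

## Worked example

```python
import numpy as np
import nanosynapse as ns

# 272 synapses with a true 3D separation of 180 nm, isotropic orientation,
# ~100 localizations per cluster at 10 nm precision
model = ns.SynapseModel(true_separation_nm=180.0)
table, truth = ns.sample_synapse_population(model, 272, seed=1)

rois = [ns.SynapseROI(r.center_x_nm, r.center_y_nm, np.degrees(r.azimuth_rad))
        for r in truth.synapses.itertuples()]
dset = ns.measure_distances(table, rois, ("A", "B"))
s = ns.top40_summary(dset)
print(f"n = {s.n_synapses} synapses, k = {s.k} in the top 40%")
print(f"top-40% mean = {s.mean_top40_nm:.1f} nm -> reported "
      f"{s.mean_top40_rounded_nm:.0f} +/- {s.sem_top40_nm:.1f} nm (SEM)")
```

prints

```
n = 272 synapses, k = 109 in the top 40%
top-40% mean = 176.6 nm -> reported 180 +/- 0.8 nm (SEM)
```

The pre-rounding mean sits slightly below 0.97265·180 = 175.1 nm plus COM
noise; rounding up to the next 10 nm bin reports 180 nm — the injected
separation. Cluster analysis works the same way on a simulated neurite:

```python
field = ns.generate_neurite_field(ns.NeuriteModel(punctae_per_um=0.5), seed=1)
dens = ns.voronoi_density(field.table[["x_nm", "y_nm"]].to_numpy(),
                          region=field.region_nm)
clusters = ns.segment_clusters(dens, ns.segment_objects(dens))
mean, sem, n = ns.summarize(clusters.areas_um2)
```

which detects 19 of 22 true clusters (close pairs merge) with mean area
0.0116 ± 0.0020 µm² and 0.38 punctae/µm on this 50 µm neurite.

The same operations are available from the shell:

```
nanosynapse simulate --kind synapses --seed 1 --out sim/
nanosynapse localize --in stack.tif --pixel-nm 100 --out locs.csv
nanosynapse drift rcc --locs locs.csv --out corrected.csv
nanosynapse register --ref beads_red.csv --mov beads_green.csv --out tf.json
nanosynapse synapse-dist --locs corrected.csv --rois rois.csv --channels A,B
nanosynapse tesselate --locs locs.csv --out clusters.csv
nanosynapse stats --groups control.csv --groups patient.csv
nanosynapse run --config pipeline.yaml --seed 1 --out out/
```

## Scope

The package analyzes 2D localization data; axial drift, astigmatic 3D
fitting, maximum-likelihood PSF fitting, and fluorophore photophysics beyond
simple per-frame blinking/binding models are out of scope. See
`docs/methods.md` for the model assumptions, parameter defaults, and known
limitations.
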