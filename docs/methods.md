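# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `nanosynapse`, and what the synthetic-data verification does
and does not demonstrate about real microscope data.

## Coordinate and data conventions

All coordinates are in nanometers, origin at the lower-left corner of the
field of view, x to the right and y up; frame indices are 0-based. The
central container is a pandas DataFrame with columns `frame, x_nm, y_nm,
intensity_photons, sigma_nm, asymmetry, channel`; extra columns (e.g. the
simulator's `synapse_id`) ride along unchanged through I/O and corrections.
Every stochastic function takes an explicit seed (or Generator) and is
bit-reproducible.

## Synapse population model

A synapse is a pair of protein clusters whose centers sit a 3D distance
`D = true_separation_nm` apart along the trans-synaptic axis. The axis
orientation is drawn uniformly on the hemisphere — `cos(theta) ~ U[0,1]`,
azimuth uniform — so the observable in-plane separation is `D*sin(theta)`.
Each cluster scatters `labels_per_cluster` labels over its footprint:

- *immature* synapses: a uniform disk of area 0.008 µm² (radius ≈ 50 nm),
  the measured scale of developing human-motoneuron Homer1 clusters;
- *mature* synapses: a 400 × 60 nm bar perpendicular to the trans-synaptic
  axis, mimicking the bar-like scaffolds (Bassoon/Homer1/PSD95) of mature
  synapses;
- point clusters (disk radius 0) isolate the pure projection geometry for
  oracle tests.

Each label emits `Poisson(localizations_per_label)` localizations, each
displaced by isotropic Gaussian error of `localization_precision_nm`
(default 10 nm, typical of dSTORM). Defaults of 25 labels × mean 4
re-activations give ≈100 localizations per cluster; labeling stoichiometry
is not measurable from the data this emulates, so the default was chosen
once for statistical stability (COM error ≈ 1 nm/axis) and is not a fitted
quantity. Synapses are laid out on a jittered 2 µm grid so that
neighboring synapses cannot contaminate each other's 400 nm ROI — a stand-in
for the manual selection of isolated synapses an analyst performs.

Per-synapse truth (theta, `D*sin(theta)`, center, azimuth, label positions)
is returned alongside the table; the invariant
`0 <= true_projected_nm <= D` and uniformity of `cos(theta)` are tested.

## Frame-stack simulation

Active emitters are rendered as pixel-integrated Gaussians (error-function
quadrature, truncated at 6σ, so photon totals are conserved to ~1e-9),
on top of a constant photon background; Poisson shot noise is applied to the
expected image, then Gaussian read noise. dSTORM blinking is simplified to
independent per-frame activation (no dark-state memory); PAINT binding is a
geometric inter-arrival / geometric dwell process per docking site. These
kinetics are deliberately minimal: they exercise detection, fitting and
drift correction, not photophysics. Defaults follow the acquisition they
emulate: 20 ms exposure dSTORM, 200 ms exposure PAINT, 100 nm camera
pixels, PSF σ = 100 nm (≈ 0.21·λ/NA for a 1.49 NA objective at ~670 nm).
Fiducial beads, when supplied, appear in every frame and follow the
injected drift.

## Localization

Detection band-passes each frame with a difference of Gaussians (σ = 1 and
3 pixels) and keeps local maxima above `median + 5 × (1.4826·MAD)` of the
filtered frame, merging maxima closer than one fitting window (7 camera
pixels) to the brighter one. Each window is fit by COM: background = mean
of the window border, residuals clipped at zero, centroid and second-moment
matrix of the residual; RMS width `sqrt(l1+l2)` and asymmetry `sqrt(l1/l2)`
come from the principal moments. Against simulated truth the per-axis RMSE
stays within 1.5× the ideal `psf_sigma/sqrt(N_photons)` across peak-SNR 10
to 100, and detection precision/recall exceed 0.95 for isolated spots at
peak-SNR ≥ 10 (SNR defined as peak signal over photon noise at the peak).
COM is not an ML estimator; at very high photon counts it saturates at a
small pixelation-bias floor (sub-nm at σ = 1 px) rather than the
Cramér–Rao bound, a known property of centroid fitting.

Filter defaults — minimum 100 photons, asymmetry ≤ 1.5, RMS width within
[0.5, 2]× the nominal PSF-derived width — are conservative single-emitter
criteria; the exact thresholds used by the original MATLAB reconstruction
software are not published, so these are exposed in the config rather than
claimed as reproductions. Overlapping emitters are rejected by the
asymmetry/width filters; multi-emitter fitting is out of scope.

## Drift correction and registration

**RCC.** The stack is split into 10 equal temporal segments (configurable);
each segment is rendered at the 10 nm raster with unit weights on a common
grid and lightly smoothed (σ = 1 bin). Every pair (i < j) of segment images
is cross-correlated via cached FFTs; the correlation peak is refined by
quadratic interpolation along each axis. The `S(S−1)/2` pairwise shifts are
combined by least squares for the segment positions (anchored at segment
0) — the redundancy averages down individual correlation errors. Per-frame
drift interpolates linearly between segment midpoints, continues the end
slopes to the stack boundaries, and is re-zeroed to frame 0. On synthetic
stacks a 100 nm linear drift is recovered with ≤ 5 nm endpoint error and
≤ 10 nm per-frame RMS; random-walk drift is tracked to the within-segment
wander limit (piecewise-linear interpolation cannot follow Brownian motion
inside a segment — use more segments for fast wander).

**Bead tracking** (PAINT): per frame, each fiducial contributes its offset
from its own mean position; the bead average is median-smoothed over an
11-frame window and gaps are linearly interpolated. Beads seen in fewer
than half the frames are dropped. Three beads with 2 nm localization noise
track drift to ≤ 2 nm RMS.

**Channel registration**: a global affine `A·p + t` is fit to ≥ 3 matched
bead pairs by linear least squares; collinear or short bead lists raise a
degenerate-geometry error. The reported residual RMS is per coordinate, so
it is directly comparable to the beads' per-axis localization noise.
Field-dependent (non-affine) chromatic maps are out of scope.

## Rendering

Localizations are binned into half-open 10 nm pixels, weighted by photon
intensity (or unit weights for RCC); the image origin is the data bounding
box snapped to whole pixels, or caller-supplied bounds for common grids.
The 0.7-pixel Gaussian blur exists for display only: its output is flagged
`display_only` and no quantitative routine accepts it — areas and distances
are always computed from tables.

## Distance analysis

A synapse ROI is a rectangle with its 400 nm long side along the
trans-synaptic axis (short side default 250 nm). The COM of each channel is
the unweighted mean of its in-ROI localization coordinates — photon weights
are deliberately not reused here so photometry cannot couple into geometry.
ROIs with fewer than 10 localizations of either channel are rejected with a
recorded reason, never silently dropped. The population statistic sorts the
per-synapse distances, keeps the `k = ceil(0.4·n)` largest (ties at the
cutoff count toward k by sort order), and reports their mean rounded **up**
to the next multiple of 10 nm (exact multiples unchanged — all reported
values are then multiples of 10, matching the convention of reporting on
the histogram's bin grid), with SEM over the k values and the 10 nm
histogram with the top subset flagged. For isotropic orientation the
statistic's noiseless expectation is `0.9726536·D` (closed form
`(1/0.4)∫₀^0.4 √(1−u²) du`), the package's primary oracle; with 100
localizations/cluster at 10 nm precision the simulated estimate agrees with
a 10⁶-sample Monte-Carlo oracle (projection convolved with COM error) to
well under 5 % at D ∈ {120, 180, 260} nm. Whether the 40 % fraction is
taken pooled or per replicate is a pipeline choice; the driver pools, and
`top40_summary` can be applied per replicate by the caller.

ROIs are normally supplied (the experimental procedure selects synapses
manually); `propose_rois` is a clearly-flagged reproducible surrogate that
pairs mutually nearest cross-channel tessellation clusters with a COM gap
below 400 nm and orients the ROI along the joining line with one refinement
iteration.

Colocalizing clusters below 0.03 µm² are classified "small" (developing),
all others "large" (mature); the inequality is strict at the boundary.

## Voronoï tessellation

Each localization's density is the inverse of its Voronoï cell area
(`density_mode="rank1"` averages over first-rank neighbors instead; both
SR-Tesseler variants are provided, own-cell is the default as the simpler
one). A ring of distant ghost points makes all real cells finite; cells are
then clipped to the analysis region (default: data bounding box padded by
the median nearest-neighbor distance), so clipped cell areas partition the
region exactly — a tested invariant. Collinear inputs are rejected.

Segmentation is two-level: **objects** are connected components (under
Voronoï-cell adjacency) of localizations at ≥ 2× the region-average
density — in a neurite image the image average is diluted by empty field,
so the neurites themselves become the objects; **clusters** are components
within an object at ≥ 3× the object-local average density, with minimum
area 0.0005 µm² and (a package addition) a minimum of 5 localizations. The
minimum count is needed because at realistic background densities a single
Voronoï cell that is small by chance already exceeds the area floor; without
it, homogeneous Poisson noise would generate isolated one-cell "clusters"
and the method's own false-positive control (median 0 clusters on Poisson
fields) would fail. The cluster threshold can alternatively reference the
global average (`reference="global"`).

**Cluster area** defaults to the convex hull of the member localizations.
Summing the member Voronoï cells (`area_mode="cells"`) is also provided but
systematically overestimates compact clusters on sparse backgrounds,
because boundary cells bulge halfway to the nearest background point —
for a 0.008 µm² disk on a 25 /µm² background that bulge roughly triples
the summed area, while the hull is unbiased (median ratio ≈ 1.0 against
truth). Hull areas slightly exceed the nominal disk area through
localization-precision blur (+~4 %) and slightly undershoot through finite
sampling; both effects are within the tested 20 % envelope.

Inside a synapse ROI (`synapse_cluster_area`), only the cluster step runs,
thresholded against the channel's image-average density rather than the
ROI average: the ROI is drawn tightly around the cluster, so its own
average approaches the cluster density and a threshold relative to it would
be self-referential (it would erase the very cluster being measured). The
object level is skipped inside ROIs for the same reason.

Known limitations: clusters closer than the Voronoï adjacency reach across
the sparse gap between them merge into one component (in the synthetic
neurite fields this loses ~5 % of clusters as merges, visible in both the
count ratio and the punctae rate); raising the cluster threshold can split
a component and thereby *increase* the cluster count, so the monotonicity
guarantee is on membership and per-cluster area, not on the count.

## Neurite fields

Cluster count along the centerline is Poisson(`length_um ×
punctae_per_um`); cluster positions are uniform in arclength with a small
lateral offset inside the 1 µm ribbon; areas are log-normal (median
0.008 µm², σ_ln 0.3); clusters are uniform disks filled at 12 500
localizations/µm², blurred by 10 nm precision; the ribbon carries a diffuse
25 /µm² background and is surrounded by 5 µm of empty field. The padding is
what makes the image-average density ≈ 6× lower than the ribbon density, so
the 2× object threshold isolates the neurite — mirroring real fields of
view where neurites occupy a small fraction of the image. The generator
does not emulate repeated blinking of single labels (background points are
independent), filament branching, or spatially varying background.

## Statistics

The t-test is the classic equal-variance two-tailed unpaired test (Welch
available via `equal_var=False`); its type-I error on null simulations is
verified to sit in [0.035, 0.065] at α = 0.05. ANOVA uses `scipy`'s one-way
F and Tukey HSD (studentized range). ROUT is defined for regression; on a
one-sample scatter the model degenerates to a constant, so the
implementation uses median as the robust center, RSDR = 68.27th percentile
of |residuals| × n/(n−1) (floored at machine epsilon so a constant sample
with one deviant still resolves), two-tailed t tail probabilities of
residual/RSDR (df = n−1), and Benjamini–Hochberg at rate Q = 0.5 %.
Flagged values are reported, never removed; re-running after removal flags
nothing new (tested). On clean normal samples it flags ≤ 1 % of values and
it catches a 10σ outlier in ≥ 99 % of seeds.

## Pipeline and reproducibility

`PipelineConfig` defaults are exactly the analysis constants: 400 nm ROI,
10 nm raster and bins, 40 % fraction, 0.03 µm² cutoff, factors 2 and 3,
0.0005 µm² minimum area, Q = 0.5 %. The driver seeds each stage from a
`SeedSequence` spawn of the master seed, and the JSON report embeds a
provenance block (parameter echo, config hash, version); two runs with the
same config byte-match, which is itself an acceptance test.

## What the verification shows — and does not

All quantitative guarantees are measured against the synthetic generator's
ground truth, under its stated conditions (isolated synapses, isotropic
orientation, ~100 localizations/cluster, 10 nm precision, modest uniform
background). They demonstrate that the *algorithms* are implemented
correctly and are well-calibrated at realistic parameter scales. They do
not certify performance on real data, where labeling stoichiometry,
repeated blinking, sample-dependent background, overlapping synapses and
non-affine chromatic aberration can all be less benign. Problem sizes in
the test suite (e.g. 12 seeds for estimator recovery, 5 neurite fields,
50–100 Poisson fields) are the package's chosen defaults for a fast,
deterministic suite; `scripts/acceptance.py` runs the fuller 50-seed
protocol.
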