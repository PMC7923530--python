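# Methods

`hippoquant` quantifies three readouts of hippocampal demyelination and
remyelination — in-vivo neuronal activity by manganese-enhanced MRI (MEMRI),
dendritic-spine and tripartite-synapse ultrastructure from labeled 3D-EM
stacks, and CA1 field-potential function — together with the group
statistics used to compare the myelinated (control), demyelinated and
remyelinated conditions.  Because the original measurements come from live
mice and serial-section microscopes, the package ships seeded phantom
generators whose ground-truth parameters encode the study's printed group
contrasts; every pipeline stage is validated by parameter recovery on those
phantoms.  This note records the models, the parameter choices, the
numerical decisions, and what the synthetic validation does and does not
demonstrate.

## MEMRI enhancement mapping (eVol)

Mn²⁺ enters active neurons through voltage-gated Ca²⁺ channels and brightens
T1-weighted signal, so voxels whose post-injection (PostMn) intensity
exceeds their pre-injection (PreMn) surroundings mark active tissue.  For
each hippocampal voxel *v* the statistic is

    d(v) = PostMn(v) − mean of the 6 face-adjacent PreMn neighbors
    z(v) = d(v) / σ̂,

where σ̂ is a robust global noise scale: 1.4826 × MAD of d over the
reference region brain ∖ hippocampus.  One-sided upper-tail normal p-values
(enhancement only — Mn²⁺ uptake cannot darken the signal) are corrected by
the Benjamini–Hochberg (BH) step-up at q = 0.05, treating voxels as
exchangeable under the null.  eVol is the surviving voxel count times the
voxel volume (0.140 mm isotropic).  Neighbors outside the grid or brain
mask are dropped; voxels with fewer than 3 valid neighbors are untestable.
A degenerate noise estimate (σ̂ < 10⁻¹²) is floored and flagged rather than
divided by.

**Statistical power and a known red result.**  Because the neighborhood
mean averages six independent noisy voxels, Var d = (7/6)σ² under the null,
so an enhancement of 3 noise-SD shifts z by only 3/√(7/6) ≈ 2.78.  A
self-consistent analysis of the BH step-up (threshold τ solving
Φ̄(z_τ) = q·R(τ), with R the rejected fraction) gives per-voxel power
≈ 0.79 when 60 % of voxels are enhanced (control preset) but ≈ 0.67 when
27.6 % are (demyelinated preset): BH is adaptive, and dense signal buys a
more liberal threshold.  Two consequences, both reproduced by the code:

* the ground-truth recovery (Jaccard overlap of rejected vs truly enhanced
  voxels) is expected at ≈ 0.78 for the control preset — the recovery test
  asserts ≥ 0.70;
* the recovered eVol contrast between demyelinated and control cohorts is
  ≈ −64 to −65 %, not the printed −54 %: the preset enhanced fractions
  (0.276 vs 0.60) encode the −54 % ratio directly, but detection power is
  asymmetric between the groups and the demyelinated hippocampus is also
  11.1 % smaller.  The presets are the study conditions and are not tuned
  to compensate; the eVol-contrast acceptance test is left failing, with
  this analysis as the explanation.

**Phantom.**  A brain ellipsoid contains two mirrored hippocampal
ellipsoids (~4,800 voxels at 64³; mild seeded center/axis jitter models
between-subject anatomy).  The demyelinated/remyelinated hippocampus is
isotropically rescaled to 0.889× control volume (the printed −11.1 %).  The
baseline field is planar (zero Laplacian), so the 6-neighbor mean is exactly
unbiased in the interior; noise is additive Gaussian (Rician noise at these
SNRs is near-Gaussian, and a Gaussian null keeps the z-test exact).
Enhancement (3σ) is added to a Bernoulli-selected fraction of hippocampal
voxels in PostMn only.  The control-side absolute enhanced fraction (0.60)
is not printed anywhere and is a documented free choice; only the
between-condition ratios are anchored.

## Spine morphometry

Input is an integer-labeled stack (background / shaft / spine / PSD /
bouton / astrocyte) with anisotropic voxels — 20 nm in-plane and the
study's 75 nm section thickness.  (The original 5–7 nm pixels are reduced
to 20 nm to keep stacks around 20 M voxels; anisotropy handling is still
fully exercised since z remains 3.75× coarser than x/y.)

* **Segmentation.**  Spine voxels are split into 26-connected components;
  each must touch the shaft by face adjacency at its base (non-touching
  components are logged and excluded as orphans).  The shaft centerline is
  the chain of per-slice centroids plus half a voxel at each end; spine
  density is count / centerline length.
* **Geodesics.**  Per-spine base-to-tip length is the anisotropy-weighted
  26-neighbor shortest path (Dijkstra from a virtual source wired to the
  base voxels).  The chamfer metric overestimates Euclidean length by a few
  percent, which is inside all class margins.
* **Head diameter** is twice the maximal inscribed-ball radius (anisotropic
  EDT) within the distal 40 % of the geodesic span.
* **Neck diameter** is the equivalent diameter of the tightest transverse
  cross-section, estimated per geodesic-distance bin (bin width = the
  largest voxel dimension) as twice the bin's maximal EDT value — the
  inscribed radius at the bin's medial center — minimized over bins fully
  inside the proximal 60 %.  Bins within one local radius of the base
  (floor 0.08 µm) are skipped: the EDT is computed on the spine set alone,
  so closer to the open base it is truncated by the base plane, and the
  shaft-junction flare would otherwise fake a constriction.  (A
  bin-volume/thickness area estimator was rejected: bin spreading under the
  chamfer metric biases it ~25–30 % low.)
* **Classification** uses a configurable rule table in the Harris style
  (thresholds are not printed in the source study; these are the package's
  documented choices): filamentous if length ≥ 2 µm and head/neck < 1.2;
  stubby if neck ≥ 0.5 × length, or head/neck < 1.2 with length < 2 necks;
  mushroom if head/neck ≥ 1.5; thin otherwise.  The rules are total and
  deterministic; boundaries are closed as written.
* **PSD.**  Area is the anisotropy-weighted area of PSD voxel faces that
  open toward the cleft (bouton or extracellular space).  A PSD is
  *perforated* when its face-adjacency graph has more than one component or
  its patch encloses a hole — Euler characteristic ≤ 0, computed exactly on
  the cubical complex (χ = V − E + F − C; cross-checked against
  `skimage.measure.euler_number` and constructed topologies).  Multi-patch
  PSDs are called perforated rather than counted as two synapses.
* **Astrocyte contact.**  The cleft is the set of spine/PSD voxels
  face-adjacent to the bouton within the one-voxel-dilated PSD footprint;
  its border ring is the cleft voxels with fewer than four face neighbors
  in the cleft.  A border position is astrocyte-contacted when an astrocyte
  voxel lies within 50 nm *surface-to-surface* (so face-adjacent voxels
  touch at 0 nm regardless of the 75 nm section spacing); the distance and
  the "covered synapse" definition (contact > 0 %) are configurable.  The
  reported percentage is relative to the entire border ring, including the
  inner rim of perforations.
* **Summaries.**  Shape percentages are computed among the three
  non-filamentous classes (filamentous spines are measured and reported in
  the class fractions but excluded from the three-class percentages, which
  is how the source figures present them).  An all-macular dendrite flags
  the macular:perforated ratio as infinite rather than erroring.

**Phantom.**  A 0.35 µm-radius shaft along y carries spines of four
well-separated archetypes (thin: narrow neck, head/neck ≈ 1.3; mushroom:
head/neck ≥ 2.6; stubby: squat cylinder; filamentous: > 2.3 µm headless),
so classification is threshold-robust at the phantom resolution.  Spine
counts are Poisson(density × length) truncated at the hard-rod packing
capacity; positions follow the exact hard-rod conditional distribution with
0.19 µm minimum axial spacing, and azimuths cycle through +x, +z, −x, −z —
together this guarantees ≥ 0.49 µm 3-D base separation and ≥ 4 spacings
between same-azimuth neighbors, so distinct spines never merge.  Class
counts per dendrite use balanced largest-remainder allocation (randomized
residual) rather than i.i.d. draws: each phantom cohort is representative
of its condition's mixture, as the study's dendrite sampling was designed
to be, and recovery of the printed class contrasts is then limited by the
pipeline rather than by multinomial noise.  Non-filamentous spines carry a
flat PSD disc (annulus when perforated) one-to-three sections thick, an
apposed bouton, and — for the preset fraction of synapses — an astrocyte
arc whose angular coverage increases with head size (the tripartite
coupling).  Ground truth records every spine's class, geometry, PSD type
and astrocyte coverage.

## Field-potential features

Each sweep is modeled as a one-sample stimulus artifact, a biphasic
afferent volley (difference of two 0.25 ms Gaussians 0.6 ms apart, fixed
peak-to-peak amplitude, 2 ms latency) and a negative-going alpha-function
EPSP A·(t/τ)·e^{1−t/τ} with τ = 5 ms starting 5 ms post-stimulus, plus
Gaussian noise (0.05 mV default, a typical interface-chamber floor), at
10 kHz.

Extraction: baseline is the 10 ms pre-stimulus mean and the noise floor its
1.4826 × MAD; AV amplitude is max − min in a 1–4 ms window on a 0.2 ms
boxcar-smoothed trace; the EPSP peak is the magnitude of the extremum of a
1 ms-smoothed, baseline-subtracted trace in a 4–50 ms window.  Smoothing is
what keeps the extremum statistic from riding single noise samples — with
raw samples, the maximum of ~500 noise points exceeds 3σ most of the time
and the sub-threshold rule below would never fire.  A peak below 3× the
noise floor is set to exactly zero (with slope and area), which renders the
demyelinated "0 ± 0" EPSP while the afferent volley is untouched.  The
slope is the least-squares line through the 20–80 % rising phase; the area
is the trapezoidal integral of |deflection| (reported in mV·ms — the
printed mV·s unit is dimensionally inconsistent with a ~2 mV, tens-of-ms
EPSP and is not targeted).  In paired-pulse sweeps, windows clip 0.5 ms
before the next stimulus.  PPF ratios are slope-based (configurable to
peak); input–output curves are normalized to the maximal stimulus and its
response before the Y = A + B·X fit (comparing raw gains between curves
requires `normalize=False`, since per-curve normalization maps every
proportional curve to unit slope); LTP magnitude is the mean
baseline-normalized slope over the last 15 min, with a zero baseline
flagged undefined (the demyelinated case) rather than raised.

**Cohort sampling.**  `single`-protocol cohorts draw EPSP amplitudes from
the preset normal (mean 1.96, SD 0.96 mV for control — the printed
1.96 ± 0.24 SEM at n = 16) by jittered stratified quantiles truncated at
zero, so a 16-sweep cohort is representative of the condition (its mean
sits at the preset mean rather than fluctuating with SE = 0.24 mV).
PPF/LTP protocols model repeated trials in *one* slice: a single slice
amplitude (5 % jitter) with 3 % trial-to-trial variation.  The PPF ratio
table (1.30/1.60/1.45/1.25/1.10 at 10/50/100/200/400 ms) is a standard CA1
facilitation profile; the printed data do not tabulate it.  The LTP
protocol is three 100 Hz tetani 15 min apart with stepwise saturation to
the preset 1.57× slope factor.

## Group statistics

One-way ANOVA (explicit SSB/SSW decomposition, F tail from scipy) with
Bonferroni-corrected pooled-variance post hoc t tests; two-tailed unpaired
Student t tests with Bonferroni multiplication capped at 1; two-tailed
variance F tests.  Degenerate inputs (identical groups, zero pooled
variance) return F = 0 / p = 1 rather than erroring.  MRI group comparisons
run on control-normalized percent differences, matching the source
normalization; all inferential routines are oracle-checked against
independent implementations to 10⁻¹⁰.  `run_study` is a pure function of
(config, seed): it regenerates all cohorts, runs the three arms and writes
byte-reproducible CSV tables.  Spines pooled across dendrites and animals
are treated as independent observations (no mixed-effects modeling), a
deliberate simplification shared with the source analyses.

## Problem sizes and reproducibility

Default study-scale runs — 10 MRI subjects per group at 64³, nine 12 µm
dendrites per condition (~450 spines each), 16–20 sweeps per cohort — match
the source study's cohort sizes and complete in about a minute on one core.
All randomness flows through explicit integer seeds; identical
(preset, seed) pairs are bit-reproducible.

## What the phantoms do not show

The generators emulate geometry, topology and noise levels, not biology or
instrumentation: no scanner physics (bias fields, Rician tails, motion), no
registration error (PreMn/PostMn are perfectly aligned by construction), no
EM section loss, charging, tracing ambiguity or membrane noise, and spine
shapes are idealized solids rather than traced membranes.  Passing recovery
tests therefore demonstrates that the quantification machinery is correct
and well-calibrated on known ground truth — not that it would be robust to
the full failure modes of acquired data.  Classification accuracy in
particular is near-perfect on phantoms because the archetypes are
well-separated by design; on real tissue the classes form a continuum.

## Known limitations

* The eVol contrast inherits BH power asymmetry (see above): recovered
  group contrasts are steeper than the encoded enhanced-fraction ratio
  whenever power differs between groups.
* PSD "area" is the exposed voxel-face area, an overestimate of the
  en-face patch area by the rim contribution; only ratios and topology are
  interpreted.
* Geodesic lengths carry the 26-neighbor chamfer overestimate (≤ ~8 %) and
  axial quantization of one 75 nm section, which dominates for sub-micron
  stubby spines.
* The remyelinated eVol preset encodes the abstract's "7 % lower"; the
  results text says "7 % higher".  No recovery target depends on it.
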