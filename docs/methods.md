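# Methods

`neurohcs` re-implements, as a tested pipeline with synthetic ground
truth, the image- and signal-analysis layer of a high-content screening
workflow for primary neuronal cultures: per-field morphology metrics,
calcium network-activity metrics, EB3 comet velocimetry, and the
per-well nonparametric statistics that compare treatment groups.

## Data model

A well is imaged at several stage positions ("fields", default 16 in a
4×4 grid), each field as a multi-channel confocal z-stack, giving a 5-D
dataset per well (XYZCF). All 2-D analysis runs on maximum-intensity
projections. Fields are never stitched or pooled across wells before
statistics: metrics are computed per field, averaged per well, and the
well mean is the statistical unit.

Physical parameters are given in micrometres and converted with the
pixel calibration. The microscopes' pixel size is not fixed by the
acquisition description, so the package declares a default of
0.325 µm/px (40× objective class), always overridable; every
µm-parameterized operation logs the pixel value it actually used.
Coordinates are 0-based and pixel-centered; areas are pixel counts ×
pixel_size².

## Fixed-image pipelines

All pipelines start with rolling-ball background subtraction
(default radius 25 px — the radius is not specified by the source
workflow and is exposed in config). For radii above 8 px the background
is estimated on a downscaled copy and resized back, the same shortcut
the original ImageJ implementation uses for large balls; the change is
below the noise floor and ~100× faster.

**Cytotoxicity.** Nuclei: Gaussian blur (sigma 1.75 µm) → fixed
intensity threshold → distance-transform watershed (markers at smoothed
distance maxima, minimum marker separation 0.65 of the minimum-nucleus
radius) → size filter at 90 µm². The watershed labels tile the
thresholded foreground exactly, so object splitting conserves area.
Dead cells are labels whose mean intensity in the PI channel exceeds a
fixed threshold; the readout is % PI-positive of all nuclei, undefined
(not zero) when a field has no nuclei. The fixed thresholds are
required config (defaults 250 for nuclei and 150 for PI on the
synthetic rendering scale of background ~100, nuclei ~480–720); they
are never auto-chosen.

**Neurite mask.** Two tiers, then union: (1) Isodata threshold of the
image (bright network); (2) local contrast enhancement — tile-based
adaptive histogram equalization with tile ≈ 1.8 µm and clip factor 3 —
followed by Laplacian edge enhancement (image + α·|LoG|, α = 1) and
Isodata again (faint branches). A 1 px Gaussian prefilter keeps the
contrast enhancement from amplifying single-pixel noise. The mask area
in µm² is the neurite-density readout, and the mask is the ROI for the
acetylated/β-III-tubulin and AT8/total-Tau intensity ratios and for
Pearson colocalization.

**Synaptic puncta.** Laplacian-of-Gaussian at 0.35 µm (negated so
puncta are maxima) → Triangle threshold → particle size filter at
0.75 µm² → count; density = count per µm² of neurite area. Particle
*size* is measured as the full-width-at-half-maximum support of the
particle's response, with the peak estimated robustly as the mean of
the top-5 response pixels. Rationale: the suprathreshold support of a
triangle-thresholded LoG response inflates every detectable punctum by
the filter's own footprint (~2πσ² ≈ 0.9 µm² at this scale), which would
make a sub-µm² size filter inoperative; the half-maximum support tracks
the physical punctum size. The plain suprathreshold area remains
available (`size_measure="support"`).

**Fibrillar-Tau load.** Hessian-eigenvalue ridge ("tubeness") filter at
sigma 3 px → Triangle threshold → fill holes → particle analysis with
area ≥ 15 µm² and circularity 0.00–0.30 (circularity = 4π·area/
perimeter², Crofton perimeter, clipped to [0, 1]; 8-connectivity).
Hole filling matters: without it the ridge filter turns bright discs
into rings whose spuriously low circularity defeats the shape filter.
Each detected particle is refined to its half-maximum dye footprint
before measurement (same rationale and robust peak as for puncta: the
ridge response spreads ~2σ beyond the structure, which would otherwise
inflate the load ~2.4×). The load is the total area of kept-particle
pixels inside the microtubule mask; an alternative centroid-in-mask
gating is available by flag, and tubeness sigma can be given in µm.

## Calcium network metrics

Traces are per-frame ROI means, normalized to ΔF/F₀ against a rolling
10th-percentile baseline (30 s window). Recordings last 260 s at 2 fps
(520 frames) with glutamate applied in the last 20 s (frames 480–519);
the stimulation epoch is excluded from all spontaneous-activity
metrics. Cells are gated into neurons vs non-neuronal cells by the
glutamate response: mean ΔF/F₀ in the stimulation window above 5× the
robust SD of the pre-stimulus ΔF/F₀. Recordings without a stimulation
window (neuron-restricted genetically encoded indicator) skip gating,
retain all cells, and are flagged.

Peaks are local maxima of ΔF/F₀ exceeding the median plus `k_mad`
robust SDs with ≥ 0.05 ΔF/F₀ prominence. These parameters are
reconstructions, exposed in config. The default `k_mad` is 4.0: at 3.5
the expected false-positive rate over 480 spontaneous frames is ~12%
per silent cell, which biases the %-active readout by about +6
percentage points on simulated recordings; at 4.0 the bias is ~+1
point while transients of ordinary amplitude (≈ 25 noise SDs) are
never missed.

Network metrics: % active = neurons with ≥ 1 peak; network bursts =
intervals where ≥ 50% of *active* neurons fire within a 1 s window —
the window slides at the frame step so a synchronized volley is never
split across a fixed bin edge (fixed bins undercounted planted burst
rates by ~35%) — reported as bursts/min of spontaneous recording;
burst correlation = mean off-diagonal of the pairwise Pearson matrix
of neuron ΔF/F₀ traces (all gated neurons by default, active-only by
flag). Fields with fewer than 5 active neurons are "not determined"
(ND): burst metrics are NaN and ND wells are excluded from statistics
with a notice. Subpopulations (e.g. aggregate-positive vs -negative
neurons) are analyzed simultaneously within a field with the same
machinery.

All metrics are invariant to affine rescaling of the raw traces
(ΔF/F₀ plus Pearson invariance); an exact negation of one trace's
fluctuation maps to a correlation near, but not exactly, −1 because the
ΔF/F₀ normalization is mildly nonlinear.

## Comet velocimetry

A kymograph is built along a user polyline resampled at 1 px steps;
each kymograph pixel is the mean of 3 bilinear samples perpendicular to
the path (averaging, not maximum — the plugin behaviour is not
specified). Velocity readout is either manual — two endpoints, v =
|Δposition|·pixel_size / (Δframes·frame_interval), orientation-
independent — or automatic: per-frame peaks are linked greedily to the
nearest peak within 4 px/frame (1-frame dropouts tolerated), and chains
of ≥ 5 points are fit by least squares, the slope giving the velocity.
The automatic tracker is an extension for testing at scale; the manual
mode reproduces the classic kymograph-plus-macro workflow. Movies are
1 min at one frame per 2 s; paths shorter than 20 µm are flagged.

## Statistics

Field metrics are averaged per well (undefined fields excluded, counts
reported). Normality is checked with Shapiro–Wilk; the omnibus test is
tie-corrected Kruskal–Wallis; post-hoc tests run only when the omnibus
p ≤ 0.05 (the gatekeeping α is assumed from the significance
convention; tiers are * p < 0.05, ** p < 0.005). Mid-ranks are used
throughout, and rank-statistic variances are computed from the realized
rank population, which is exact under ties. No normalization across
biological replicates and no mixed models.

*Steel test* (many-to-one vs control): each treatment is rank-summed
jointly with the control; the family-wise adjusted p accounts for the
shared control via the permutation distribution of the maximum
standardized statistic (default, 10⁴ permutations, seeded; exact in the
limit) or a multivariate-normal approximation with the known comparison
correlation √(nᵢnⱼ/((nᵢ+n₀)(nⱼ+n₀))). With two groups the permutation
p reproduces the two-sided Wilcoxon rank-sum p. Note that with n = 6
per group and three groups the smallest attainable family-wise p is
≈ 4/C(12,6) ≈ 0.0043, so resolving the 0.005 tier reliably needs ~10⁵
permutations.

*Dunn all-pairs*: z statistics from joint mean ranks with tie-corrected
variance, two-sided normal p, Bonferroni-adjusted over all pairs. The
Bonferroni family-wise error is conservative by construction (~3.3% at
k = 3, n = 6); the per-pair unadjusted level calibrates to ~4.3% at
nominal 5%.

## Synthetic data

The generator renders every input the pipeline consumes, with ground
truth, and is deterministic per seed. Objects are hard shapes smoothed
with a small Gaussian standing in for the PSF (0.35 px ≈ 0.11 µm for
puncta, from 0.21·λ/NA), then corrupted with per-pixel Poisson shot
noise plus Gaussian read noise on a constant background. Defaults are
1024×1024 px at 0.325 µm/px.

- *Nuclei*: ellipses of 102–150 µm² (mean 120), amplitude 480–720 on
  background 100, read noise 8. A crowding fraction places pairs at
  0.85× the sum of their radii — touching, slightly overlapping — as
  watershed test cases. Exactly round(dead_fraction·n) nuclei carry PI
  signal.
- *Neurites*: persistent random-walk tubes in two tiers — bright trunks
  (5 px wide, intensity 180) and faint branches (2 px, intensity 45) on
  background 20 — to exercise the dual-mask design; default total
  length 6000 µm (~6% area fraction). The acetylated channel mixes the
  standardized tubulin signal with independent noise inside the truth
  mask so the within-mask sample correlation approaches the requested
  ρ. Puncta (~1.3 µm² disks) are placed on the mask at the requested
  density with a minimum separation; optional 0.5 µm² puncta act as
  negative controls for the size filter.
- *Fibrils*: gently curved rods 1.6 µm wide and 20–28 µm long (area
  ≥ 15 µm², circularity 0.14–0.26 by construction) and discs of radius
  2.6–3.3 µm (circularity > 0.95) as shape-filter negative controls;
  truth lists each particle's area and Crofton circularity measured on
  its own noiseless render.
- *Calcium*: population burst times are a Poisson process at the given
  rate over the spontaneous epoch; each active neuron joins each burst
  with probability `sync_prob` (timing jitter SD 0.15 s). Transients
  rise instantaneously and decay exponentially with τ = 1.5 s (~3
  frames at 2 fps), amplitude 0.5 ΔF/F on baseline 1 with Gaussian
  noise SD 0.02. Neurons — and only neurons — get a sustained step of
  3× the transient amplitude during the final 20 s. Cell baselines vary
  ±20%.
- *Comets*: Gaussian spots (σ 1.3 px) advancing at constant velocity
  along a gently curved path (default 40 µm), with start offsets
  staggered so every comet stays on the path for the whole movie
  (31 frames, 2 s interval).

What the generator does not emulate — realistic PSFs and optical
aberrations, photobleaching, stage drift, z-dependent blur, intensity
heterogeneity within objects, overlapping puncta, bursting rate
adaptation, or comet catastrophes — bounds what passing tests show:
they demonstrate that the analysis chain recovers known truth under
idealized imaging, not that it is robust to every artifact of real
acquisitions.

## Problem sizes used in the shipped checks

The acceptance checks run cytotoxicity on 8 fields per dead fraction
(60 nuclei each), splitting on 6 crowded fields, masks/synapses/
colocalization/fibrils on 3–4 fields of 1024² px, calcium on 20
recordings of 50 cells (plus 18 for the synchrony sweep), velocimetry
on 5 movies of 10 comets, and statistics calibration on 10⁴ null
simulations (Steel with 300 permutations each; the 5-SD power check
uses 10⁵ permutations per simulation for the tier resolution discussed
above). These sizes give Monte-Carlo error comfortably inside each
tolerance while keeping a full run in minutes on one CPU.

## Known limitations

- Fixed nucleus/PI thresholds must match the data's intensity scale;
  there is deliberately no auto-calibration.
- The CLAHE-based second neurite mask trades precision for recall
  (precision ~0.77 on synthetic fields); the area readout is therefore
  comparative, not an absolute neurite surface.
- Half-maximum particle sizing assumes roughly flat-topped objects;
  strongly graded intensity profiles would be undersized.
- The automatic comet tracker assumes quasi-linear tracks and fails on
  crossing trajectories; the manual mode is authoritative.
- Steel/Dunn p-values at n ≤ 6 are strongly discrete; tier boundaries
  near the attainable minimum need large permutation counts.
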