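# Methods

## Scope

`dtwconnect` estimates region-pair BOLD similarity two ways — Fisher-z
Pearson correlation and window-constrained dynamic time warping (DTW)
— and implements the analyses used to compare them: ROI-level
denoising, robustness to simulated motion and to global signal
regression (GSR), test-retest reliability, a 2×3 repeated-measures
ANOVA for task sensitivity, edgewise group inference with p-value
enrichment, PCA + linear-SVM classification, and partial-correlation
brain-behavior screens.  The package consumes region-averaged
timeseries and rigid-body motion-parameter tables; volumetric
preprocessing (realignment estimation, distortion correction, spatial
normalisation) is out of scope, with only a minimal NIfTI ROI
extractor provided for convenience.

## DTW estimator

The local cost is the absolute difference of scalar samples, combined
with the symmetric three-way step pattern and no slope weighting; the
warping path is confined to the Sakoe-Chiba band `|i − j| ≤ w`.  The
window is specified in seconds (default 100 s, the published optimum
for BOLD data) and converted to samples by rounding, so TR = 2 s gives
`w = 50`.  Distances are not normalised by path length; comparisons
across scans therefore require equal numbers of volumes, which the
data model enforces.  Inputs are percent-signal-change timecourses and
deliberately *not* z-scored: regional BOLD amplitude is information
the estimator is meant to retain.  Within one scan, the distances of
all unordered pairs are negated and demeaned (similarity = mean
distance − pair distance), so each matrix is centred on zero; the
demeaning scope is per scan, not across subjects, which also makes the
edge values insensitive to scan-level global shifts in distance.  The
dynamic program runs in a numba-compiled kernel with two rolling rows;
a brute-force path-enumeration oracle (n ≤ 10) is kept in the package
for verification.

Fisher z values are clipped at `|r| = 1 − 1e−7` so degenerate perfect
correlations stay finite; zero-variance regions produce NaN edges with
a warning rather than an error.

## Synthetic BOLD generator

The generator emulates a SimTB-style simulation at desk scale.  Its
defaults are the study conditions: 20 subjects, 25 regions, 180
volumes at TR = 2 s, Rician noise at a per-subject contrast-to-noise
ratio (CNR) drawn uniformly from [0.65, 2], head motion bounded by
0.02 mm translation and 5° rotation, and 300 voxels arranged as a
20 × 15 grid with Gaussian-blob component maps (the printed voxel
count read as a 2-D grid).

Per subject: latent event trains (Bernoulli per TR at 0.25 events/TR,
amplitudes ~ N(1, 0.3)) are mixed through a region × source coupling
matrix — by default five equal communities with within-community
weight 0.45, giving block-structured true connectivity — plus
region-unique events at 0.05 events/TR.  Each region's activation is
convolved with a canonical double-gamma HRF and circularly shifted by
its regional BOLD lag, the ensemble is scaled to unit global SD,
multiplied by per-region amplitude factors drawn from U(0.5, 1.5)
(regional heterogeneity of BOLD fluctuation magnitude), offset by a
baseline of 100, and passed through the Rician magnitude channel
(`sqrt((s + g1)² + g2²)`, σ = 1/CNR).

**HRF variability.**  A regional delay shift δ is modelled as an
area-conserving time dilation of the canonical kernel:
`h_δ(t) = s·h0(s·t)` with `s = 5/(5 + δ)`.  The peak moves from 5 s to
5 + δ s, the response widens by 1/s, and its peak amplitude falls by
s.  This couples timing to dispersion and amplitude, reflecting that
empirically late-peaking hemodynamic responses are broader and
shallower; a pure time shift would make "HRF variability" invisible
to any amplitude- or shape-sensitive estimator and reduce it to lag.
Regional delays default to U(−0.5, +0.5) s jitter.

**Motion model.**  Traces are smoothed, reflected random walks per
rigid-body parameter; the configured maxima are caps, with a
per-subject severity factor on [0.3, 1] so motion varies across
participants without exceeding the stated bounds.  Corruption of the
spatially mixed data has two components: (1) the composite fluctuation
image is rigidly displaced per volume (translations in mm through a
3 mm/voxel scale, in-plane rotation from the third rotation
parameter, linear interpolation, constant padding), which mixes and
modulates regional signals; (2) a spin-history-like whole-volume
intensity modulation scales the total image (including the spatially
uniform tissue baseline) by `1 − 0.005 × displacement(t)` mm⁻¹, where
displacement is the composite excursion from the reference position
(translations plus 50 mm-sphere rotation arcs).  The second component
is the textbook reason head motion couples to the global signal:
moving spins change whole-volume intensity, producing a shared
additive artifact.  ROI read-out averages over each component's
original support mask, so a zero trace reproduces the unmoved data
exactly; thermal (Rician) noise is added at the voxel level with the
same realisation for motion-free and motion-corrupted runs, since
scanner noise does not depend on head position.

**Global (respiration-like) component.**  One band-limited unit-SD
timecourse (0.01–0.05 Hz drift plus 0.2–0.35 Hz respiration band,
truncated at Nyquist) scaled by a configurable amplitude is added to
every region, optionally with per-region lags.  Its in-band (drift)
part survives band-pass denoising and is what GSR removes.

**Rest-vs-task scans** for the task-sensitivity analysis share the
cohort ground truth; the task condition reduces the coupling of a
designated homotopic pair by 60% of its weight and scales the driven
region's fluctuation amplitude by 1.5 — frequent unilateral responses
both decouple the pair and raise the responding region's BOLD
amplitude.  Two control pairs are untouched.

**Two-group cohorts** share all cohort-level draws (coupling, lags,
delays, amplitudes) and differ only through the configured effects:
`coupling-delta` changes a mixing weight symmetrically, `lag-delta`
shifts the source region's BOLD in time, `hrf-delta` changes that
region's HRF delay (with the dilation semantics above).  Empty effects
give a null cohort whose edgewise p-values are uniform.

## Denoising

All steps act at the ROI level.  Percent signal change maps each
region to `100·(x − mean)/mean` (mean-centring only, with a warning,
when the mean is numerically zero).  Framewise displacement is the
Power convention: sum of absolute parameter differences with rotations
as 50 mm arc length; RMSD is the root-mean-square of the same
composite volume-to-volume displacement.  Outlier volumes exceed
FD > 0.5 mm or a 3 SD z-scored change of the global mean intensity.
The nuisance regression is a single OLS per region whose design holds
an intercept, the six motion parameters and their backward-difference
derivatives, five aCompCor principal-component timecourses from a
noise-voxel block, one one-hot spike regressor per flagged volume, a
discrete-cosine basis covering every frequency *outside* 0.008–0.08 Hz
(band-pass by regression, so filtering and scrubbing happen in the
same model), and optionally the region-mean timecourse (GSR; a
region-level proxy for the whole-brain voxel mean).  Scrubbed volumes
are retained in the series (DTW needs contiguous input) with residuals
exactly zero; spike columns take priority when collinearity forces
column drops, and the highest-frequency cosine columns are trimmed if
the design would otherwise leave fewer than 10 residual degrees of
freedom.  At T = 180 and TR = 2 s the full design has ~145 columns;
shorter runs are usable only because of that trimming, and the 180
volume default is the intended operating point.

## Downstream statistics

Robustness and reliability are summarised by the Pearson correlation
of vectorised upper triangles (pattern similarity) and by per-edge
absolute percent change with the reference condition as denominator;
edges whose baseline magnitude is below 1e−6 are excluded and counted.
The median across edges is the headline summary because near-zero
baselines make the distribution heavily right-skewed.  Group inference
uses pooled-variance two-sample t-tests (Welch by flag), paired t, or
partial correlations (residualising edge and behavior on
[1, covariate], t-transform at df = n − 3).  Enrichment is Storey's
fixed-λ estimator, `π0 = #{p > λ}/((1−λ)m)` with λ = 0.5 and a 20-bin
histogram; the reported quantity is the fraction of false nulls
1 − π0.  No per-edge multiple-comparison correction is applied
anywhere: the inference is enrichment across the family of edges, with
uncorrected α = .05 ROI involvement counts for localisation only.  The
2×3 repeated-measures ANOVA is the classical within-subject
decomposition with subject-by-factor error terms and no sphericity
correction; degenerate all-equal cells report F = 0.

Classification vectorises upper triangles (row-major, i < j), reduces
to 5 principal components and classifies with a linear SVM (C = 1)
under stratified 15-fold cross-validation repeated with per-iteration
seeds (`base_seed + iteration`); PCA is fit inside each training fold
by default — fitting it on all subjects leaks test information — with
the permissive variant available behind `pca_global` for comparison.
Iteration accuracy pools held-out predictions across folds.  Accuracy
distributions are compared with a two-sided Wilcoxon signed-rank test,
zero differences dropped; an all-zero difference vector reports
(0, 1) rather than an error.

## What the synthetic cohorts show, and what they do not

The generator reproduces the *mechanisms* the estimator comparison
turns on — shared latent sources, regional lag and HRF heterogeneity,
amplitude heterogeneity, a shared physiological component, bounded
rigid motion with its global intensity footprint, magnitude noise at
realistic CNR — with known ground truth, so directional claims
(which estimator is more robust, more reliable, more enriched) can be
tested against truth.  They do not emulate spatial autocorrelation,
vascular topography, non-stationary arousal, multi-echo signal
formation, or realistic atlas geometry; absolute effect sizes and
accuracies on these cohorts therefore do not transfer to real data,
only the contrasts between estimators computed under identical
conditions.  Test problem sizes are the package's chosen desk scale:
the motion analysis runs at the full stated conditions (20 × 25 × 180),
while replicate-based directional checks use 8–48 subjects and 12–25
regions per cohort over 25 replicates.

## Numerical and design choices

- Window conversion rounds seconds/TR and floors at 1 sample.
- DTW demeaning is exact (upper-triangle mean is 0 to 1e−9 by
  construction); the similarity matrix is filled symmetrically with a
  zero diagonal that is excluded from all summaries.
- Volume indices in outlier sets are 0-based throughout the API.
- The Rician channel takes the noise-free signal as the in-phase
  component; signals are kept on a +100 baseline so the magnitude
  operation does not rectify them.
- Motion-trace reflection uses triangle-wave folding, preserving
  smoothness at the bounds.
- Group-difference scenarios that inject only hemodynamic effects
  (HRF dilation deltas, BOLD lag deltas) are the regime where DTW's
  enrichment advantage over Pearson appears; injected coupling deltas
  are detected by both estimators.  Pure lag deltas on raw
  (un-band-passed) signals are primarily a Pearson-visible phase
  effect — DTW, being lag-robust by design, is close to blind to
  them, which is the point of the estimator.
- All randomness flows from explicit integer seeds; cohorts are
  bit-identical under identical configuration and seed.

## Limitations

DTW cost is O(T·w) per pair and the pairwise matrix O(R²·T·w); the
numba kernel keeps the default scale under a second per scan, but
dense atlases (R > 100) at high temporal resolution warrant
parallelisation.  The fixed-λ π0 estimator has sampling SD ≈
`1/(2·sqrt(m)·(1−λ))` and is noisy below a few hundred edges.  The
band-pass-by-regression design consumes most degrees of freedom at
T = 180; runs much shorter than 6 minutes at TR 2 s leave little
residual signal.  Pre-whitening of temporal autocorrelation is not
implemented.
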