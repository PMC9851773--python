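# dtwconnect

Functional connectivity (FC) from resting-state fMRI is almost always
estimated with Pearson correlation, which assumes the BOLD signals of
two coupled brain regions are synchronous.  Hemodynamics are not: the
shape and timing of the hemodynamic response vary across the brain and
between people, so even identical underlying activity can produce low
or negative correlations when one region's BOLD signal lags or its
response is broader.  `dtwconnect` implements the alternative of
quantifying BOLD timeseries similarity with window-constrained
**dynamic time warping (DTW)** and provides the full comparison harness
between the two estimators: denoising, motion and global-signal
robustness, test-retest reliability, edgewise group inference with
p-value enrichment, connectome-based classification, and
brain-behavior partial-correlation screens — exercised end-to-end on a
synthetic BOLD generator with known ground truth.

It is written for methods researchers in functional connectomics who
want a tested, reproducible implementation of the DTW estimator and of
the analyses used to benchmark it against Pearson correlation.

## The estimators

For two equal-length region timecourses `x, y` (in percent signal
change, not z-scored), the constrained DTW distance is the dynamic
program

```
D(i, j) = |x_i − y_j| + min{ D(i−1, j), D(i, j−1), D(i−1, j−1) },
```

restricted to the Sakoe-Chiba band `|i − j| ≤ w`, with the window `w`
given in seconds (default 100 s) and converted to samples by rounding.
Distances for all region pairs of a scan are multiplied by −1 and
demeaned, so the resulting similarity is 0 for an average pair,
positive for above-average similarity.  The conventional estimator is
the Pearson correlation of each pair with Fisher z transform,
`z = atanh(r)`.  DTW absorbs inter-regional lag and shape differences
(a pure one-sample shift of an impulse has DTW distance 0 but Pearson
r = −0.25) while remaining sensitive to BOLD amplitude; Pearson is
amplitude-blind and synchronicity-bound.

## Worked example

```python
from dtwconnect import (SimConfig, DtwConfig, generate_cohort, percent_signal_change,
                        pearson_fc_matrix, dtw_similarity_matrix)
from dtwconnect.pipeline import run_motion_analysis

cfg = SimConfig(n_subjects=1, n_regions=8, lag_range_seconds=(-3.0, 3.0), seed=5)
cohort = generate_cohort(cfg)
ts = percent_signal_change(cohort.scans[0].timeseries)
z = pearson_fc_matrix(ts)
s = dtw_similarity_matrix(ts, DtwConfig(window_seconds=100))
print(z.values[0, 5], s.values[0, 5])

res = run_motion_analysis(SimConfig(seed=1))
```

Regions 0 and 5 share a ground-truth latent source but were generated
with a 2.5 s BOLD lag between them; with 180 volumes at TR = 2 s the
example prints

```
true lag difference: -2.5 s
Pearson z[0,5]       = +0.317
DTW similarity[0,5]  = +20.363
DTW similarity range = [-28.96, +23.64]
```

— the lag attenuates the correlation toward the middle of its range,
while the warping-based similarity places the pair near the top of the
scan's distribution.  The motion analysis then simulates 20 subjects
(25 regions, 180 volumes, TR 2 s, contrast-to-noise uniform on
[0.65, 2]) whose spatially mixed data are corrupted by bounded rigid
head motion (≤ 0.02 mm translation, ≤ 5° rotation), and compares each
estimator's FC before and after the corruption:

```
median |%change| under motion: Pearson 176.5%, DTW 38.5%
paired t(19) = 5.77, p = 1.5e-05
```

Motion changes the Pearson estimates several-fold more than the DTW
estimates, because the dominant motion artifact is a shared
whole-volume intensity modulation that inflates correlations but
largely cancels in DTW's pairwise differences.

The same analyses are scriptable from the shell:

```bash
dtwconnect simulate --out data/ --seed 1
dtwconnect denoise --in data/ --out denoised/ --no-gsr
dtwconnect fc --in denoised/ --estimator both --out fc/
dtwconnect group --fc fc/ --manifest data/manifest.csv --estimator dtw \
    --test two_sample --out group/
dtwconnect reproduce-synthetic --seed 1 --out report/
```

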