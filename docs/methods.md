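# Methods

This note documents the models implemented in `ordtune`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user analyzing real data should know about.

## Ordinality pRF model

The forward model assumes the aggregate response of the neural population
at a recording site is a Gaussian in the natural logarithm of ordinal rank.
Two parameters describe it: the preferred ordinality μ (rank units, the
peak) and the tuning width σ (dimensionless, the standard deviation in log
units).  Log-domain tuning implies multiplicative symmetry — the response
at rank 2μ equals the response at μ/2 — and a constant σ corresponds to a
constant Weber fraction.  Width is *reported* in linear rank units as

FWHM = μ·(e^{σ√(2 ln 2)} − e^{−σ√(2 ln 2)}) = 2μ·sinh(σ√(2 ln 2)).

A consequence worth keeping in mind: because FWHM carries a factor of μ,
linear width grows with preferred rank even when the log-width σ is flat
across the population.  The trend statistics below operate on FWHM, so a
σ-flat population is *not* a null for them (see "Synthetic populations").

### Run design

The default run design encodes the marker sweep used in the functional
runs: TR 1.5 s; each of ranks 1–7 held for 2 volumes ascending, a 12 s
baseline epoch, the descending sweep, a second baseline; 4 such cycles
preceded by 8 discarded volumes — 184 volumes, 276 s, 176 analyzed.
Design decisions at TR resolution:

* The sub-second flicker of the marker within a position is not modeled;
  the design carries one presented ordinality per volume.
* Baseline epochs are *encoded as rank 15* (the middle compartment of a
  30-compartment snake), not as stimulus-off: the baseline position is a
  presented ordinality and enters the forward model like any other rank.
  This is why the fitting grid must extend beyond rank 7 — a site tuned to
  the baseline position needs to be representable so it can be excluded,
  rather than masquerading as an in-range preference.
* The occasional catch events (marker stepping forward during the
  descending sweep) do not change the encoded rank sequence and are not
  represented.
* Discarded frames precede cycle 1 and are encoded as baseline.  The
  neural time course is built over the full run and convolved before the
  discard, so hemodynamic carry-over into the analyzed window is modeled.

### HRF

The HRF is a difference of two gamma densities with five parameters
(seconds unless noted): response delay 6, undershoot delay 16, response
dispersion 1, undershoot dispersion 1, undershoot ratio 1/6 — the standard
canonical shape, peaking near 5 s.  `two_gamma_hrf` returns a peak-
normalized kernel; inside the forward model the TR-sampled kernel is
renormalized to unit area so that a sustained unit neural input settles at
gain + offset, making the gain interpretable in signal units.

Subject-level HRF estimation (`estimate_hrf_and_refit`) holds each site's
tuning fixed, re-solves gain/offset by OLS inside the objective, and
optimizes the five parameters by bounded nonlinear least squares over the
pooled residual of the top-quartile sites (by within-set R², among those
above a 0.2 floor).  One estimate–refit iteration is performed.  Bounds
(delay 3–9 s, undershoot 8–24 s, dispersions 0.2–3 s, ratio 0–1) keep the
kernel physiological.  If no site qualifies or the optimizer fails to
reduce the pooled residual, the initial HRF is returned with a warning —
the procedure can only help, never hurt, the pooled fit.

### Fitting

The fit is an exhaustive search over a candidate grid: μ log-spaced over
[0.9, 40] (80 points, ≈ 5% spacing) and σ log-spaced over [0.05, 3]
(40 points, ≈ 11% spacing).  The μ range strictly contains both the
presented ranks and the baseline position.  The winning candidate
maximizes the Pearson correlation between its predicted time course and
the data; gain and offset then follow by ordinary least squares.
Decisions:

* "Best fitting" is Pearson correlation rather than residual sum of
  squares; with a free gain and offset the two select the same candidate,
  and correlation makes R² = r² immediate.
* Gain is constrained nonnegative (tuned responses are modeled as positive
  BOLD modulations), implemented by discarding candidates whose best OLS
  gain would be negative (r < 0).
* Ties break toward smaller σ, then smaller μ, by evaluating candidates in
  σ-major order and keeping the first maximum.  This makes results
  reproducible when several candidates are exactly equivalent (e.g., very
  broad tunings that flatten to near-identical predictions).
* A zero-variance series is flagged degenerate: R² = 0, excluded.
* An optional continuous refinement (Nelder–Mead on (ln μ, ln σ) seeded at
  the grid winner) is off by default and only accepted when it strictly
  improves the correlation.

Input series are consumed as given: percent-signal conversion, detrending
and any averaging across runs are the caller's responsibility, and no
spatial or temporal smoothing is applied anywhere.

### Cross-validation and inclusion

Cross-condition validation freezes the tuning fit on one stimulus
configuration and evaluates its prediction on the matched site's series
from the other configuration.  Variance explained is the squared Pearson
correlation, floored at zero for negative correlations (with a nonnegative
gain an anticorrelated prediction explains nothing; squaring it would
reward sign errors).  The two directions are averaged before applying the
inclusion threshold of 0.20.  A site is included iff its preferred
ordinality lies in the presented range [1, 7] *and* its averaged
cross-validated variance explained reaches the threshold.

## Group statistics

`width_trend_test` computes the site-level Spearman correlation of FWHM
against preferred ordinality and a one-tailed permutation p-value (widths
increasing with rank), with p = (1 + #{ρ* ≥ ρ}) / (n_perm + 1), n_perm
defaulting to 10,000.  Because functional voxels are interpolated onto a
finer anatomical grid, several sites can descend from one acquired voxel
and are not exchangeable individually.  The permutation therefore moves
*upsampling groups* as blocks; groups of unequal size (typical after
exclusion) shuffle within same-size strata, which preserves exchangeability
exactly.  Without group labels the test falls back to site-level
permutation and warns, since that is anticonservative under upsampling
(the test suite demonstrates the inflation at 5× replication).

`coverage_by_rank` bins preferred ordinality with half-open intervals
[k, k+1) for k = 1..6 and [7, 7] closed — a convention that must be fixed
for reproducibility; sites count equally by default, with optional
per-site area weights.  `condition_agreement` computes per-cluster Pearson
correlations of preferred ordinality between stimulus configurations and
controls the FDR across clusters by Benjamini–Hochberg at 0.05; clusters
with fewer than 3 matched sites are skipped.  Cluster identity is an input
label, not computed.

## CNN arm

The network is the eight-block hierarchy (feature maps 32, 48, 96, 192,
384, 768, 768, 768; kernels 9, 9, 7, 5, 5, 5, 5, 5; same-padding
convolutions; batch normalization and ReLU per block; 2×2 max-pooling
after the first five blocks; adaptive average pooling; 1,000-way linear
head), implemented directly in NumPy with im2col convolutions and
inference-mode batch normalization.  Weights initialize randomly
(He-scaled, seeded) or load from an `.npz` checkpoint that must match the
architecture exactly.  The analysis layer is the last block's post-ReLU
activation map, 768 × 7 × 7 = 37,632 units; pre-ReLU analysis is available
by naming `bn8` instead.  The pipeline is weight-agnostic — every stage
runs identically on random or trained weights; training infrastructure is
out of scope.

Snake stimuli are generated factorially at 224×224 on a gray background:
white compartments (circles or rectangles) with one red marker.  Without a
direction cue an image's ordinality is counted from the nearer end,
min(position, n+1−position).  Straight snakes cross repetitions × shapes ×
orientations × spacings × positions; irregular snakes (a seeded
self-avoiding chain on a jittered grid) cross repetitions × shapes ×
positions; the variable-length control draws per-compartment sizes from
U(0.45, 1) so along-chain distance to the marker decorrelates from rank,
and records that distance in the label table.  Counts are pure functions
of the configuration.  The default screening set combines straight
(5 reps, 400 images) and irregular (20 reps, 400 images) 10-compartment
snakes; straight repetitions contribute 4× the images per ordinality that
irregular ones do, so the 1:4 repetition ratio keeps every
(ordinality × set) ANOVA cell balanced.  Preprocessing resizes/center-crops
to 224 and applies the classification training set's channel normalization
(means 0.485/0.456/0.406, stds 0.229/0.224/0.225).

The selectivity screen is a balanced two-way fixed-effects ANOVA with
interaction, computed from sums of squares and vectorized across all
units — orders of magnitude faster than a per-unit linear-model call at
37,632 units, and exact because the generator guarantees balance (an
unbalanced table is rejected, naming the offending cells).  The
stimulus-set factor is straight vs irregular, with shape, orientation and
spacing variants treated as replicates.  A unit is selected iff
p_ordinality < 0.05 and p_set ≥ 0.05 and p_interaction ≥ 0.05; under
independence the null selection rate is α(1−α)² ≈ 0.045, slightly below α.
Zero-variance units report p = 1.  Preferred ordinality is the argmax of
the per-ordinality mean response.

Pooled tuning curves min-max scale each selected unit's per-ordinality
mean response to [0, 1] before averaging within preferred-rank groups
(mean ± SE over units).  Curve widths come from a four-parameter
least-squares Gaussian on the linear rank axis (baseline, amplitude,
center, spread; FWHM = 2√(2 ln 2)·spread ≈ 2.355·spread); flat or
non-converging curves are flagged and excluded from the downstream
Kendall-τ test of widths increasing with preferred rank (one-tailed).
Rank decoding trains a linear SVM (C = 1) on "first" vs all other
ordinalities with the rest class subsampled to balance (chance 0.5),
stratified 5-fold cross-validation, and a one-tailed Wilcoxon signed-rank
test of the fold accuracies against chance — whose exact floor at 5 folds
is 1/32 ≈ 0.031.

## Synthetic ground truth

`synth` exists because no scan data accompanies the study this package
models; it generates data *through the same forward model the fitter
assumes*, which is the right tool for verifying the estimation machinery
and the wrong one for claiming robustness to model misspecification.

* `simulate_site` draws one BOLD series from known (μ, σ, gain, offset)
  plus white or AR(1) noise (AR coefficient 0.4 by default; innovations
  scaled to the requested marginal variance).  Noise level is given either
  as a standard deviation or as a target SNR (signal variance over noise
  variance) — SNR 1 puts the median within-set R² near 0.5, the regime
  used for the recovery experiments.
* `simulate_population` draws preferred ordinalities either log-uniformly
  on [1, 7] (density ∝ 1/μ, mirroring the empirical preponderance of
  low-rank preferences) or uniformly, and widths from one of two laws:
  `log_affine` (σ = intercept + slope·ln μ; defaults 0.35 and 0.15, a
  plausible positive width trend) or `fwhm_independent`, which draws the
  linear FWHM independent of μ and inverts it to σ.  The latter is the
  genuine null for the FWHM trend test — as noted above, a flat σ is not.
  Upsampling k replicates each source site with shared signal and
  independent noise, labeled by group for the permutation test.
* `plant_cnn_units` builds unit responses from known tuning applied to a
  label table's ordinalities, with optional stimulus-set nuisance offsets
  for negative controls and pure-noise units for calibration.
* `null_region_table` produces group-level exchangeable region tables
  (rank and width independent) for fast permutation calibration.

What the generators do not emulate: physiological noise spectra, spatial
correlation between sites, run-to-run drifts, nonlinear BOLD effects, and
— on the CNN side — the fact that real units respond to images through
shared features rather than to the ordinality label directly.  Passing
recovery and calibration tests therefore validates the estimation and
inference machinery under the stated model, not its adequacy for any
particular dataset.

## Verification scales

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: 50 sites for the brute-force oracle comparison, 100 sites at
SNR 1 for parameter recovery, 500 table-level repeats (199 permutations
each) for trend-test calibration, 2,000 noise units for screen
calibration, 50 full-pipeline repeats (300 sites, SNR 4, slope 0.25,
999 permutations) for power, and one screening repetition (320 images) for
the end-to-end network run.  Calibration assertions compare empirical
rejection rates against nominal plus three binomial standard errors, the
Monte-Carlo tolerance appropriate to those repeat counts.

## Known limitations

* The fitter assumes the caller provides preprocessed, condition-averaged
  series; no motion, drift or nuisance regression is included.
* Cross-validation directions share the run design; designs of different
  lengths across conditions are supported, but the two conditions must
  present the same rank range.
* The ANOVA requires exact balance; datasets with dropped images must be
  rebalanced upstream.
* Gaussian curve fits on 4–5 point curves are weakly constrained; widths
  from edge-peaked curves (preferred rank 1 or the maximum) should be
  treated with caution, and the τ statistic over few curves has coarse
  p-value resolution.
* NumPy inference is single-threaded per convolution and processes a few
  images per second at 224×224; screening very large image sets is
  feasible but not fast.
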