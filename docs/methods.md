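# Methods

`fsfcd` implements a frequency-specific functional connectivity density
(FCD) analysis of resting-state BOLD signals, end to end: a synthetic-cohort
generator, the in-scope tail of preprocessing, CEEMDAN decomposition with
Hilbert-weighted-frequency (HWF) summaries, frequency-of-interest (FOI)
band selection, short-/long-range FCD mapping, cluster-corrected group
inference, and leave-one-out SVM classification.  This note records the
model assumptions, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## Synthetic cohorts

The generator emulates a two-group resting-state acquisition: TR = 3 s, 190
retained volumes, frequencies of interest below 0.08 Hz, group sizes 31
patients / 28 controls by default, on a ~700-voxel ellipsoidal gray-matter
mask inside a 12x12x12 grid of 3-mm voxels.  Each voxel series is

* a sum of sinusoidal **oscillators** — each has a center frequency,
  amplitude and spatial support; all voxels in the support share the same
  subject-specific random phase, so an oscillator is simultaneously a
  spectral feature and a connectivity feature over its support;
* zero or more **effect-region latents** — unit-variance white noise
  band-passed to a stated band, added with a mixing weight ("correlation
  gain") to every region voxel of one group only.  Because the latent is
  band-limited, the planted correlation difference is confined to that band:
  filtering to a disjoint band removes it (tested by simulation);
* additive white noise (SD 1 by default).

The same random draws are made whether or not an effect applies, so patient
and control subjects generated from the same seed differ only by the planted
effects.  Synthetic covariates (age, sex, state/trait anxiety, depression
and worry scores) are drawn from per-group normal/Bernoulli distributions
whose parameters default to the demographic table of a typical adolescent
anxiety cohort.  They exist purely so the demographic-test code runs end to
end; they are labeled stand-ins, not data, and the generator makes no claim
of physiological realism — no hemodynamic convolution, physiological noise,
head motion or distortion is modeled.  Consequently, passing tests show that
the *pipeline* recovers what was planted under its stated assumptions; they
say nothing about effect sizes in real cohorts.

The `planted_effect_spec()` benchmark adds three contiguous "network"
oscillators (amplitude 1.2, ~40 voxels each) so both groups have spatially
structured short-range connectivity — without them control FCD maps are
identically zero and cannot be z-scored — plus one central ~60-voxel region
whose patients-only latent (gain 1.5, band 0.02–0.04 Hz) raises within-region
correlation from ~0.2 to ~0.7, i.e. across the 0.6 connection threshold.
That produces a regional FCD group difference of several between-subject
standard deviations, comfortably above the 2-SD planting the recovery
benchmarks call for.

## Preprocessing

Linear detrending and nuisance regression are ordinary least-squares
projections (hence idempotent, which is tested).  Temporal filtering is a
zero-phase forward-backward Butterworth (order 4 by default; order is
config-exposed): zero phase matters because FCD is correlation-based and
phase shifts would distort inter-voxel covariance.  Framewise displacement
follows the Power convention — the sum of absolute backward differences of
the six realignment parameters, rotations converted to arc length on a
50-mm sphere — because "mean FD" without a formula almost always means this.
The step order defaults to detrend → filter → regress and is configurable;
each output carries a provenance list of the steps applied.  Discarding
initial dummy volumes is the caller's choice (CLI option), since synthetic
cohorts are generated as already-retained volumes.

## EMD, CEEMDAN and HWF

The sifting algorithm uses cubic-spline envelopes through local extrema
with mirror-symmetric boundary extension (two mirrored extrema per end) —
boundary handling dominates the error budget on 190-sample series.  Sifting
stops on a Cauchy-type criterion (energy of the mean-envelope correction
below 0.2 of the component energy) once the candidate satisfies the IMF
criterion (extrema and zero-crossing counts differ by at most one), with a
hard cap of 50 sifts.  Decomposition terminates when the residue has fewer
than two interior extrema or a stage extracts nothing; the terminal residue
may retain up to two interior extrema when a final half-oscillation cannot
be enveloped stably on a short series — a numerical reality the tests
acknowledge.  Mode count is additionally bounded by ~log2(n), the dyadic
filter-bank capacity of EMD.

CEEMDAN extracts modes stage-wise: mode k+1 is the ensemble mean of the
first EMD mode of (current residue + beta_k × k-th EMD mode of a noise
realization), beta_k = noise_amplitude × SD(residue).  Defaults:
noise_amplitude 0.2, ensemble size 100, at most 4 modes — conventional
values, all config-exposed, since no canonical setting exists for fMRI
series.  The final residue is computed as input minus the sum of modes, so
the reconstruction identity is exact by construction (tested to 1e-8 of the
signal SD; in practice it holds to machine precision).  One noise bank (the
realizations and their EMD modes) is built per subject from the master seed
and shared across that subject's voxels; this dominates runtime and makes
results independent of voxel execution order.

HWF is the amplitude-weighted mean instantaneous frequency of the analytic
signal: unwrap the Hilbert phase, differentiate (central differences) and
divide by 2·pi·TR, then average with squared-amplitude (energy) weights.
Plain-amplitude weighting is available by option; the two agree on
constant-amplitude tones.  The first and last two samples are excluded —
the Hilbert transform of a finite series is unreliable at its edges, and
the exclusion measurably improves low-frequency tone recovery.  Pure tones
at 0.01–0.05 Hz are recovered within 5% (within 0.4% at these defaults),
and a linear chirp's HWF matches the time average of its known
instantaneous-frequency ramp within 10%.

## FOI bands

For each IMF order, HWF values are pooled over all voxels and all subjects
within a group, and the "95% interval" is read as the empirical 2.5th–97.5th
percentile range (linear interpolation).  A standard-error interval at
~10^5 pooled voxel values would be vanishingly narrow and could never
produce bands of usable width, so the distributional reading is the only
workable one.  The group-consistent band per order is [max of the two lower
limits, min of the two upper limits]; empty intersections are dropped with
a warning.  Bands are labeled FOI-1… by descending frequency (mode 1
oscillates fastest); adjacent bands that still overlap (a tiny-cohort edge
case) are trimmed at the midpoint of the overlap, and a band swallowed
entirely by its neighbors is dropped.  The conventional 0.01–0.08 Hz band is
FOI-N.

A voxel's band signal for derived FOI-k is mode k's series directly
(order-indexed mapping); an HWF-gated alternative — use mode k only where
its HWF lies inside the band — is available behind a flag.  FOI-N uses the
prepared series band-passed to 0.01–0.08 Hz (band-pass, not low-pass, so
that drifts below 0.01 Hz never enter the conventional-band analysis).

## FCD mapping

Two voxels are connected when their Pearson correlation strictly exceeds
0.6 (ties excluded).  Global FCD counts a voxel's connections to all other
mask voxels.  Short-range FCD grows the seed's local cluster: starting from
the seed, absorb any voxel that is a spatial neighbor (26-connectivity by
default; 6 and 18 available and recorded in outputs) of a cluster member
and correlated with the *seed* above threshold; the count is cluster size
minus one — seed-to-member connections only, not member-to-member edges.
Long-range FCD is global minus short-range, an exact integer identity that
is asserted everywhere.  Zero-variance voxels are rejected before any
correlation is computed and reported by index.

Maps are z-scored within the mask per subject (population-SD convention;
sample-SD differs only by a uniform scale and is selectable) and smoothed
with a 6-mm-FWHM Gaussian computed on the full grid with zeros outside the
mask, then renormalized by the identically smoothed mask — so constant maps
stay constant inside the mask and edge voxels are not biased toward zero.

## Group inference

Voxelwise comparisons are pooled-variance two-sample t-tests with the fixed
sign convention patients minus controls; zero-variance voxels propagate as
NaN and are excluded from cluster labeling.  Map smoothness is estimated
per axis from standardized residual maps by the variance-of-derivative
estimator: lag-one autocorrelation rho = 1 − var(diff)/2, and since white
noise smoothed with a Gaussian of width sigma has autocorrelation
exp(−d²/(4·sigma²)), sigma² = −1/(4·ln rho) in voxel units (the factor 4,
not 2, matters: the 2 would inflate FWHM by √2, which the
generate-and-recover test catches).  A user-supplied FWHM triple bypasses
estimation.

Cluster correction is Monte-Carlo: simulate null white-noise volumes on the
mask grid, smooth to the map FWHM, standardize within the mask (so the
voxel-level p maps exactly to a z cutoff), threshold two-tailed at
p < 0.001, label positive and negative clusters separately with the shared
connectivity, and record each simulation's maximum extent.  The reported
minimum extent is the smallest k whose null exceedance is ≤ alpha = 0.05.
Calibration on 200 null cohorts (12³ grid, 6-mm smoothness, 15/group) puts
the family-wise false-positive rate inside the 95% binomial interval of
0.05.  Known limitation: the null is Gaussian while the statistic is a
t-map; at low df and high smoothness (≳3 voxels FWHM) this grows mildly
anticonservative, which is the classic behavior of this correction family.
Scalar inference (demographic t-tests, the 2×2 chi-square without
continuity correction, partial correlation with covariates residualized out
and p from the t transform, Benjamini–Hochberg FDR) delegates to
scipy/statsmodels.  Note that a label-permutation null for the 2×2 table
conditions on its margins and therefore converges to the exact conditional
p (0.44 for the gender table), not the asymptotic chi-square p (0.36); the
tests document both.

## Classification

One leave-one-out fold per subject.  Within each fold, inter-group
difference clusters are re-detected from the training subjects only, and
each feature is the mean map value over one cluster's voxels per
(band, kind); the identical cluster geometry is applied to the held-out
subject.  Features are z-scored with training-fold statistics before a
linear-kernel SVM (C = 1, no in-fold hyperparameter search), and decision
scores from all folds are pooled into one ROC.  The patient group is the
positive class; score ≥ 0 predicts patient.

A fold with no surviving cluster carries no evidence.  It gets decision
score 0 and, by the sign convention, the patient label.  We deliberately do
*not* fall back to the training-set majority class: in balanced
leave-one-out the training majority is always the class opposite to the
held-out subject, so a majority rule scores ~0% on null data — an
anti-learning artifact, not chance.  The zero-score convention keeps
permuted-label accuracy at 50% on balanced cohorts, where it belongs.

Reported accuracy is fold-count based; balanced (per-class mean) accuracy
is reported alongside because the two differ on unbalanced cohorts, and a
fold-fraction accuracy over n folds can only take multiples of 100/n.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which each property is meaningfully exercised: decomposition-heavy
cohort tests use ~70–300-voxel masks, 64–96 timepoints and ensemble sizes
of 5–30 (completeness is an exact identity at any ensemble size); FCD
oracle checks use ≤ 300-voxel lattices against independently coded
brute-force implementations; calibration uses 200 null cohorts of 15+15 on
a 1000-voxel mask; recovery and classification benchmarks use the
planted-effect cohort (15/group, ~700-voxel mask, 190 volumes).  All
randomness flows from explicit seeds; reruns are bit-identical, and the
pipeline writes a manifest (config hash, seed, per-stage wall time and QC
counts) next to every run's artifacts.
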