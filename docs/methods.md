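# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pulvicon`, and what the synthetic test bed does and does not
establish about real data.

## The coupling model

Functional coupling between a pulvinar voxel and a cortical area is defined
as the similarity of their *cortical correlation profiles*: the vectors of
Pearson correlations with a fixed set of cortical areas.  The profile of a
voxel is compared against a leave-one-subject-out pseudo-group profile of
each area, so the reference never contains the held-out subject's own data
(no circularity).  Three choices in this second-order correlation were
genuinely open and are fixed as follows:

* **Seed self-entry.**  The seed area's own entry (r = 1 on the area side)
  is excluded from both vectors by default; including it inflates every
  match toward the seed.  `include_self=True` restores it.
* **Averaging space.**  Pseudo-group profiles and group maps are averaged in
  Fisher-z space and back-transformed; group tests are run on the z values.
* **Hemisphere scoping.**  Profiles are ipsilateral by default.  Map
  similarity, Dice, and peak analyses are computed per hemisphere and then
  averaged (peaks: left reflected across the mid-line before averaging).
  A cross-hemisphere mode exists but is off by default.

Voxels whose profile contains any undefined entry (zero-variance series) are
masked from all areas' maps rather than imputed.

## Preprocessing

The conditioning pipeline is fixed in the order despike → band-pass →
detrend → nuisance regression; rest runs first lose their initial 21.6 s
(12 samples at TR 1.8 s, floored and logged for non-integer ratios), and
pulvinar voxel data are smoothed spatially (4 mm FWHM, mask-normalised)
after the temporal steps.

* Despiking clips at 2.5 SD around an iteratively sigma-clipped mean, so a
  spike cannot inflate its own envelope.  Zero-spread series pass through
  with a log note.
* The band-pass (0.01–0.1 Hz) is a 4th-order Butterworth applied
  forward–backward (zero phase).  The filter family/order is a documented
  choice, not a claim of equivalence to any particular tool.
* Detrending removes Legendre polynomials up to order 2.
* Nuisance regressors are the six motion estimates, their first-difference
  temporal derivatives (zero-padded first sample), and ventricle- and
  white-matter-like signals.  The global mean signal is deliberately **not**
  removed.

Downstream correlations are insensitive to these steps on clean synthetic
data (the sign of every planted network contrast survives preprocessing — a
tested invariant).

## Task GLM and d-prime

Conditions are square waves convolved with a canonical double-gamma HRF
(positive lobe peaking at 6 s, undershoot at 16 s, 1:6 amplitude ratio;
gamma scale 1 s).  Per-condition response means and SDs for the d-prime
index are computed from per-block mean responses in a window of the block's
duration lagged 6 s (the HRF peak) after onset — the estimation window is a
declared choice.  The leave-one-out category ROI uses an inverse-variance-
weighted one-sample z across the remaining subjects as the pseudo-group
contrast (a closed-form stand-in for a mixed-effects meta-analysis), BH-FDR
at q = 0.05 within the anatomical search region, restricted to the largest
connected cluster when lattice indices are supplied.

## ISC and the timescale contrast

Repetitions are averaged within subject; leave-one-out ISC correlates each
subject with the mean of the others, and the reported map is the arithmetic
mean of the per-subject r values (mean-of-r, not r-of-mean).  The
intact-minus-scrambled difference is thresholded voxel-wise at 0.15, the
same threshold used for the consistency label on the intact condition.
All subjects share a single segment permutation, mirroring a single
scrambled stimulus shown to every subject.

## Network structure

* **Classical MDS** is Torgerson double-centring with top-eigenvector
  projection; negative eigenvalues are truncated at zero and logged.  Axis
  signs are fixed deterministically (largest-magnitude coordinate positive);
  the first axis always carries the most variance.
* **Spectral clustering** is Newman's leading-eigenvector modularity with
  recursive bisection, including the Kernighan–Lin-style fine-tuning pass of
  the original algorithm; without fine-tuning the greedy bisection
  demonstrably stalls in two-cluster local optima on three-group geometries
  whose 3-way partition has strictly higher modularity.  Splitting stops
  when the leading eigenvector is sign-uniform or the split's modularity
  contribution is non-positive, so cluster count is automatic.  Negative
  weights are zeroed by default (a signed variant is available).
* **Procrustes** is the full transform class (translation, rotation,
  reflection, isotropic scale); SSE is normalised by the target
  configuration's total variance.  Permutation tests scramble area labels
  globally or within provided clusters; the reported percentile is the rank
  p-value (1 + #{null ≤ observed}) / (n + 1), which is uniform under the
  null (a tested calibration).
* **Peak clustering** builds a Gaussian affinity exp(−d²/2σ²) with σ set to
  the median pairwise peak distance — a documented choice where no standard
  exists — then applies the same modularity clustering.
* The Fisher z test for the difference of two correlations assumes
  independent samples; applied to strata that share areas it is an
  approximation, and the docstring flags this caveat.

## The synthetic test bed

The generator's defaults are the study conditions of the analyses: 13
subjects, 39 areas (23 occipito-temporal, 16 fronto-parietal) in both
hemispheres, TR 1.8 s with 312 timepoints; movie runs with 11 subjects, TR
1.5 s, 230 timepoints, two repetitions per condition, segments of 0.5–1.6 s;
block designs with 16 s blocks at TR 2.0 s (5 subjects for laterality /
attention, 16 for the category localizer).

**Areas.**  Area signals are unit-variance mixtures of a global latent
(between-network correlation 0.10), a flat network latent, and a graded
component drawn from a Gaussian process over the ordered area index
(length 3 index units).  Neighbouring same-network areas correlate at 0.45;
the graded share (0.30) makes the correlation decay smoothly with index
distance.  The graded part is essential, not cosmetic: under flat
equicorrelation every area of a network has the same expected fingerprint,
so per-area connectivity peaks carry no positional information and no
pipeline could recover a topography.  The split between flat and graded
shares was chosen once so that the planted structure simultaneously
supports two-network separation, graded map overlap, and topography
recovery, and was not revisited afterwards.

**Voxels.**  Each hemisphere's voxel block (4×6×8 lattice, 2 mm spacing) is
split into a ventral slab mixing occipito-temporal areas and a dorsal slab
mixing fronto-parietal areas; within a slab the y index sets the preferred
area along the network's ordered list, with Gaussian falloff of width 1.5
index units.  White noise (SD 0.8 relative to unit-variance area signals),
quadratic drifts, and motion-like smooth random-walk confounds (plus
ventricle/white-matter-like components) are added; the confound series are
recorded so nuisance regression has real structure to remove.

**Movie.**  The stimulus feature course is Gaussian-filtered white noise
(autocorrelation 2.5 s) on a 0.25 s grid — a stand-in for the drift of
low-level visual statistics, with no claim to emulate any particular film.
A short-window region responds point-wise (sampled at TR resolution — a
readout that averaged within TR bins would itself integrate across segment
boundaries and spuriously penalise scrambling); a long-window region takes
a trailing 21 s moving average.  Scrambling reorders 0.5–1.6 s segments.
The mechanism of the timescale contrast is variance collapse: a moving
average over many short, incoherently ordered segments retains little
stimulus-locked variance, so with fixed additive noise (SD 0.8) the
long-window region's inter-subject correlation drops in the scrambled
condition while the instantaneous region's does not.

**Dorsal peaks.**  The finer organisation of dorsal coupling is emulated as
three planted peak groups (attention-, tool-, and default-mode-like) with
comparably separated centres (16–18 mm apart) and 1.5 mm within-group
spread.

**What passing tests show — and don't.**  The generator plants exactly the
covariance structure the analyses assume: linear mixing, Gaussian noise,
stationary signals, perfect inter-subject alignment, and a one-dimensional
topography.  Recovery on these data validates the pipeline's correctness
and calibration, not its performance on real fMRI, which adds registration
error, physiological noise, spatially varying SNR, and non-stationarity.
Absolute values (ISC levels, reliability near 0.99, d-prime magnitudes) are
consequences of the chosen SNR and should not be read as empirical claims.

## Problem sizes and determinism

All simulation-based tests use 20 seeds with the default problem sizes
above (a full resting pipeline run takes well under a second); calibration
tests use 200 null runs with 99 permutations each.  Every generator and
every randomised analysis (split-half, permutation tests) is a pure
function of its explicit seed; the pipeline derives per-stage substreams
from the single configured seed by hashing the stage name, so stages are
reproducible independently.  Degenerate inputs follow fixed rules: constant
series fail loudly where a correlation would be undefined, are excluded and
logged where a summary can proceed without them (ISC, voxel profiles), and
ties in peak localisation break to the lexicographically smallest
coordinate.

## Known limitations

* Real-data ingestion expects pre-aligned, pre-masked NIfTI volumes;
  registration, motion estimation, and surface work are out of scope.
* Cortical distances are consumed as a provided matrix (the synthetic ones
  are Euclidean distances between planted centroids, not geodesics).
* The pseudo-group mixed-effects map is a precision-weighted z, not a full
  mixed-effects meta-analysis.
* Signed-modularity clustering is available but untested against a planted
  truth; the default zeroes negative weights.
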