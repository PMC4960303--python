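# Methods

## Estimators

**ISFC.** All region time courses are z-scored within subject (sample
standard deviation, `ddof=1`; Pearson correlation is invariant to the
denominator, but stored z-scored values follow this convention).  For each
subject `i`, the leave-one-out reference is the plain arithmetic mean of the
*z-scored* matrices of the other `k−1` subjects; it is not re-standardised
(correlation is scale-invariant, so the estimate is unaffected — documented
for reproducibility).  The subject-level matrix `C_i(a,b)` is the Pearson
correlation of subject `i`'s region `a` with the reference's region `b`;
it is not symmetric.  Entries are Fisher z-transformed with the correlation
clipped to ±(1−1e−7) so `atanh` stays finite at |r| = 1, averaged across
subjects, inverse-transformed, and symmetrised once as `(C + Cᵀ)/2` —
symmetrisation is applied to the group matrix, not per subject.  The
diagonal is the per-region inter-subject correlation (ISC).

**FC.** The same machinery within subject: per-subject correlation
matrices, Fisher-averaged across the group, diagonal forced to 1.

**Degenerate rows.** A time course is degenerate when its standard
deviation is at numerical-rounding level relative to its mean
(`sd ≤ 1e−12·(|mean|+1)`).  Degenerate rows are flagged, z-scored to zeros,
and propagate NaN into any correlation that touches them; NaNs are excluded
from the Fisher average entrywise, and a subject that is degenerate in every
region is dropped (with a warning) and the subject count adjusted.  Nothing
is silently zero-filled into statistics.

**Block-wise path.** `group_isfc_blocked` computes the p×p matrix in
tiles for voxel-scale problems and is contract-tested to equal the naive
computation exactly.

## Preprocessing

High-pass filtering regresses each row onto a discrete-cosine drift basis
(DC plus all cosines with frequency below 1/cutoff; default cutoff 140 s),
which removes ≥95% of drift power below the cutoff and leaves the passband
intact.  Nuisance regression projects each row onto the orthogonal
complement of [intercept, regressors] by least squares and errors on
rank-deficient regressor sets, naming the collinear columns.  The order is
configurable; the default pipeline applies high-pass before nuisance
regression.  For parcellated inputs the caller supplies the nuisance
regressors (the classic choices — high-variance out-of-brain voxels, CSF
and white-matter means — require volumetric data, for which the nibabel
adapter `extract_roi_timeseries` provides ROI and sphere-seed extraction).

## Surrogate inference

Surrogates are built in the Fourier domain: the rFFT of each series is
multiplied by `e^{iφ}` with φ i.i.d. Uniform(0, 2π) per frequency bin; the
DC bin, and the Nyquist bin for even length, are left untouched (their
phases must be 0/π for a real signal), so the surrogate is exactly real
with exactly the original amplitude spectrum — hence the original mean,
variance and autocorrelation.  For ISFC nulls every series of every subject
is randomised independently; for FC nulls, every series within each
subject.  Each iteration recomputes the full statistic map and records its
maximum (ISFC maps include the diagonal, since ISC is part of the tested
map; FC maps exclude their constant diagonal).  The FWER threshold R\* is
the (1−q)·100th percentile of the maxima with linear interpolation between
order statistics (continuous in q).  Iterations are evaluated in vectorised
batches from a single seeded generator whose draws are identical to a
sequential loop, so results are bitwise reproducible and independent of the
batch size.  Permutation p-values for series correlations use the
(b+1)/(m+1) estimator, so p is never exactly 0.

## Sliding windows, fingerprints, reliability

Windows are half-open `[t, t + w)` in TR units, labelled by start TR, step
1 TR by default; a window equal to the full series reproduces the global
estimate exactly.  A window's **fingerprint** is the vector of
`p(p−1)/2` lower off-diagonal edges in fixed row-major lower-triangle
order, serialised with `regionA-regionB` labels; the mean of those edges is
the scalar network-coupling strength.  Split-half reliability repeatedly
partitions the group into random halves and correlates the halves'
fingerprints per window (odd group sizes error by default; a flag drops the
last-listed subject).  Behaviour coupling smooths the rating series by
local linear regression with a tricube kernel (span expressed in TRs; the
local window is floored at four points for a stable fit), resamples it onto
the window grid, and tests the correlation with the mean-ISFC series
against phase-randomised surrogates, two-sided.  Graph export follows the
standard display conventions: node diameter proportional to ISC, edge width
60·r, small negative edges (−0.1 < r < 0) width-zeroed, stronger negative
edges kept with negative width for separate styling.

## Decoding and clustering

Decoding is leave-one-subject-out nearest-template matching with Pearson
similarity on Fisher-z fingerprints, ties to the lowest class index — the
simplest scheme consistent with full-fingerprint classification.  A
subtlety matters here: the held-out subject's ISFC fingerprint is computed
against the remaining subjects, so the per-class templates are computed
from those remaining subjects *alone* (their mutual group ISFC).  Building
templates from per-subject fingerprints computed on the full group leaks
the test subject into its own templates and inflates accuracy far above
chance on stimulus-free data.  Even with that fold design, the matched
template and the test fingerprint still share the held-out group's
realisation, which leaves a small optimism under the global null (a few
percentage points above nominal chance on white noise) — a property of
matched-template ISFC decoding itself, not of the implementation; chance
controls in the test suite therefore assert clear dissociations rather than
exact chance.  Note also that with any shared stimulus, interval decoding
succeeds even under a stationary covariance: the realisation's sampling
fluctuations are themselves stimulus-locked and interval-specific, so the
proper chance control is a no-stimulus simulation.

k-means uses the squared-Euclidean objective with k-means++ seeding and
best-of-`n_restarts` selection (scikit-learn behind the module surface),
deterministic under a seed.  Cluster reproducibility across group halves is
scored with the Sørensen–Dice matrix `D(i,j) = 2|X_i∩Y_j|/(|X_i|+|Y_j|)`;
K selection maximises the worst row-max of D (every cluster must reproduce),
ties to the smaller K.  The declustering algorithm greedily merges the most
similar (Pearson) pair of adjacent clusters, replaces the pair by the
average of the two cluster series, recomputes similarities with the merged
neighbours, and repeats while a merge can stay within the required
`target_size`; ties break to the lowest-index pair, elements without
neighbours stay singletons with a warning.

## The generative model

The simulator draws each group as `X_i = √s·S + √(1−s−η)·I_i + √η·N_i` per
region: one stimulus component S shared by all subjects (multivariate
normal with correlation `C_S`, optionally piecewise over interval states
with instantaneous transitions — windows spanning a boundary mix states, as
real sliding windows do), per-subject intrinsic components `I_i` with
correlation `C_I`, and white noise.  Shares `s` (stimulus) and `η` (noise)
are per-region with `s + η ≤ 1`; the mixture identity is exact and each
component's empirical variance share matches its budget within sampling
error.  An optional per-subject global confound adds one scalar series to
all regions with region-specific gain — the minimal model of
respiration/motion-like within-subject shared noise, which inflates FC but
not ISFC (being additive it also dilutes the stimulus share slightly, so
the noise-immunity demonstration uses a weak-stimulus regime).  Memory
(history dependence) is realised as a per-region leaky integrator on S,
`y_t = λ·y_{t−1} + (1−λ)·x_t` with `λ = e^{−1/τ}` and re-standardisation;
the generative form is this package's choice for producing
context-dependent responses, with τ in TRs and τ = 0 the instantaneous
limit.  Segment scrambling permutes a tiling of the timeline uniformly and
returns the permutation, so analyses can reorder measured data back to
presentation order.  Everything is bit-reproducible under the config seed.

Defaults describe a typical narrative-listening acquisition: 18 subjects,
10 network regions, 280 timepoints at TR 1.5 s (≈ 7 min), stimulus share
0.5, stimulus correlation 0.6, intrinsic correlation 0.3, 10% noise.

**What the simulator does not emulate:** hemodynamic convolution (analyses
operate on measured-signal statistics, and all estimators are
convolution-agnostic zero-lag correlations), spatially structured noise
fields, subject-specific functional topographies, and voxel-level volumes
(regions only).  Passing tests therefore demonstrate the estimators'
statistical behaviour under the three-component model, not performance on
any particular scanner's artefact structure.

## Validation experiments and problem sizes

`isfc.calibration` packages the end-to-end studies asserted by the test
suite and reported by `scripts/acceptance.py`, at these sizes (chosen to
give stable Monte-Carlo estimates on a single CPU):

- family-wise calibration: 200 white-noise datasets (k=6, p=10, n=300),
  1000 surrogate iterations each, q=0.05;
- rest dissociation: k=10, p=6, n=2000, intrinsic correlation 0.6;
- coherence gradient: shares {0, .25, .5, .75, 1}, k=10, p=6, n=1000,
  20 replicates per share;
- history dependence: 8 regions (half instantaneous, half τ=40 TR), twelve
  30-TR segments alternating weak/strong stimulus coupling, k=12, sliding
  windows of 20 TRs, 5 replicates;
- condition decoding: shares {1.0, 0.6, 0.2, 0.0} over a common random
  stimulus pattern and uniform intrinsic network, k=18, p=10, n=300,
  20 replicates;
- reliability scaling: per-group sizes {2, 4, 9, 18}, 20 replicates,
  5 random splits each;
- permutation calibration: 200 independent AR(1) pairs (φ=0.6, n=200),
  500 permutations each.

All randomness derives from one integer seed via `SeedSequence` spawning.

## Known limitations

- ISFC magnitudes are attenuated by the leave-one-out average:
  the expected edge is `s·ρ_S/√(s + (1−s)/(k−1))`, not `s·ρ_S`; the
  attenuation vanishes as k grows.
- The matched-template decoder's small null optimism (above).
- The confound model is a single global series per subject; spatially
  structured artefacts are out of scope.
- Loess smoothing needs at least four points in the local window; very
  sparse behavioural samplings are refused rather than extrapolated.
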