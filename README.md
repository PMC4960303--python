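# isfc — inter-subject functional correlation analysis

`isfc` isolates **stimulus-locked inter-regional correlation** from
multi-subject time-series recordings (typically BOLD fMRI of groups
experiencing the same naturalistic stimulus).  Within-subject functional
connectivity (FC) mixes three signal sources — stimulus-induced responses
(S), intrinsic neural fluctuations (I), and non-neuronal noise (N) — and
cannot tell them apart.  **Inter-subject functional correlation (ISFC)**
correlates region *a* in one subject with region *b* in the *average of all
other subjects*; because I and N are uncorrelated across subjects, only the
shared stimulus-locked component survives.

For subjects `i = 1..k` with z-scored region-by-time matrices `X_i`
(p regions × n timepoints), the subject-level matrix is

    C_i(a, b) = corr( X_i[a, :],  mean_{j≠i} X_j[b, :] )

and the group matrix applies Fisher's r-to-z transform entrywise, averages
the k subject matrices, inverse-transforms, and symmetrises:

    ISFC = ( C + Cᵀ ) / 2,   C = tanh( (1/k) Σ_i atanh(C_i) )

The diagonal of the ISFC matrix is the **inter-subject correlation (ISC)**
of each region; for FC the diagonal is identically 1.  Significance is
assessed nonparametrically with **phase-randomised surrogates** (same
amplitude spectrum, hence same autocorrelation, random phases), and
family-wise error over a whole map is controlled by thresholding at the
upper (1−q) quantile **R\*** of the surrogate distribution of map-wise
maxima.

The package is aimed at researchers analysing naturalistic-stimulus
neuroimaging (or any multi-subject shared-stimulus time series) and
provides:

- `datasets` — containers, TSV/NIfTI readers, DCT high-pass filtering,
  nuisance regression, within-subject z-scoring;
- `correlate` — subject/group ISFC, ISC, seed maps, FC, Fisher averaging
  (with a block-wise path for voxel-scale matrices);
- `surrogates` — phase randomisation, max-statistic null distributions,
  FWER thresholds, permutation correlation p-values;
- `dynamics` — sliding-window ISFC/FC, network fingerprints, split-half
  reliability, segment reordering, behaviour coupling (loess + permutation
  test), cross-network summaries, graph export;
- `decode` — leave-one-subject-out nearest-template decoding of conditions
  and story intervals, k-means network discovery with Sørensen–Dice
  reproducibility and K selection, neighbourhood-correlation declustering;
- `simulate` — a generative three-component model (`X_i = √s·S +
  √(1−s−η)·I_i + √η·N_i`, with optional per-subject global confounds,
  piecewise interval states, segment scrambling, and leaky-integrator
  "memory" regions) used throughout the test suite;
- `ISFCModel` / `FCModel` — a model/results front end with `fit()`,
  `fit_windows()`, and a `summary()` table, plus an `isfc` command-line
  interface (`isfc simulate|estimate|nullthresh|dynamics|graph`).

## Worked example

Simulate 18 subjects listening to a shared stimulus that carries half of
the signal variance (inter-regional stimulus correlation 0.6, intrinsic
correlation 0.3, 10% white noise), then estimate ISFC with surrogate
inference:

```python
from isfc import ISFCModel, SimConfig, simulate_group
from isfc.simulate import uniform_correlation

cfg = SimConfig(k=18, p=5, n=280, stimulus_share=0.5,
                stimulus_corr=uniform_correlation(5, 0.6),
                intrinsic_corr=uniform_correlation(5, 0.3),
                noise_share=0.1, seed=0)
dataset, truth = simulate_group(cfg)
result = ISFCModel(dataset).fit(q=0.01, n_surrogates=1000, seed=1)
print(result.summary())
```

```
=================================================================
ISFC results                            subjects: 18
regions: 5                              condition: sim
mean edge r: +0.4391                    mean ISC: 0.6941
R* (q=0.01, 1000 surrogates): 0.0720; suprathreshold elements: 25
=================================================================
 edge        r  significant
r1-r0 0.463150         True
r2-r0 0.457475         True
...
```

The mean edge (0.44) sits at the analytic expectation for this design,
`s·ρ_S / √(s + (1−s)/(k−1))` ≈ 0.41 (within the sampling error of a single
280-timepoint run): the stimulus-locked correlation `s·ρ_S = 0.30`, divided
by the attenuation of the leave-one-out average; likewise the mean ISC
(0.69) matches `s / √(s + (1−s)/(k−1))` ≈ 0.69.
Every edge clears the surrogate threshold R\* = 0.072.  Repeating the fit
with `stimulus_share=0` leaves FC at the intrinsic level (≈ 0.3 here)
while the ISFC map is empty — the rest-condition dissociation that
motivates the method.

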