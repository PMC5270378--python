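# Methods

## Signal model and analysis window

A pupillogram is a 30 Hz diameter time series of one eye under one of four
chromatic conditions (`r10, r100, b10, b100`): a 10-s light pulse followed
by 10 s of recovery. Feature extraction uses only the stimulus window —
the first `stimulus_duration × sampling_rate` samples after onset (300 at
defaults) — because the constriction and the colour-dependent
sustain/escape dynamics during the pulse carry the melanopsin-weighted
information of interest. Recordings are assumed to start at light onset
(`stimulus_onset_index = 0`); an explicit onset index covers recordings
with a pre-stimulus baseline segment.

Dropouts (blinks, tracking loss — samples that are missing or
non-positive) may be repaired by linear interpolation when a run is at
most `max_gap` samples (default 5, i.e. ~170 ms) and has valid flanking
samples; anything longer, or a run touching the record boundary, marks the
record invalid rather than guessing. Diameters outside (0, 12) mm after
repair are hard errors: they almost always indicate unit mistakes.

## Fourier descriptors

`compute_fd` returns `FD_k = |X[k]|` for `k = 0 … N/2 − 1`, where `X =
numpy.fft.rfft(window)` — raw transform magnitudes with no `1/N` or `2/N`
normalization. The convention is fixed, documented and tested against a
direct `O(N²)` DFT-sum oracle; Parseval's relation under it is

```
sum_n x(n)^2 = (FD_0^2 + |X_{N/2}|^2 [N even] + 2 * sum_{0<k<N/2} FD_k^2) / N
```

and is asserted in the test suite. No windowing/tapering or detrending is
applied before the transform. The choice of scaling is immaterial
downstream: every feature built from the descriptors is a ratio.

Three features derive from the descriptors:

* **Shape vector** `[FD_2/FD_1, FD_3/FD_1, FD_4/FD_1, FD_5/FD_1]`.
  Dividing by `FD_1` removes amplitude scale; excluding `FD_0` removes
  offset; together the vector is invariant to any affine map `a·x + b`
  (a > 0) of the window — a property the suite checks with
  hypothesis-generated transforms. Four components are the default
  (low-order harmonics carry the bulk of waveform shape); the
  dimensionality is a parameter of `shape_vector`.
* **Standardized amplitude** `FD_0′`: each condition's `FD_0` divided by
  the arithmetic mean of the eye's four values, so the four standardized
  values of one eye average exactly 1. A peak-referenced variant
  (division by the eye's maximum-response condition, typically b100) is
  also provided for amplitude comparisons.
* **Combined feature** `f′ = [shape, w·FD_0′]` with fusion weight
  `w ≥ 0`; `w = ∞` (`AMPLITUDE_ONLY`) selects the 1-component
  amplitude-only vector.

Internal computation is at full precision; two-decimal rounding is applied
only when rendering results, which is how the published worked-example
vectors are printed.

## Condition distances and the FE vector

Per eye, Euclidean distances between the four conditions' combined
features give a symmetric 4×4 matrix (fixed order r10, r100, b10, b100);
its strict upper triangle read row-major is the FE vector
`[r10−r100, r10−b10, r10−b100, r100−b10, r100−b100, b10−b100]`. An 8×8
cross-eye variant stacks both eyes' condition sets; its diagonal blocks
reproduce the per-eye matrices, and the diagonal of its off-diagonal block
(same-condition inter-eye distances) quantifies inter-eye asymmetry — the
signature of unilateral disease.

A reproduction note: the published worked-example FE vector is only
recovered when the distance is computed over the *combined* feature
including `FD_0′` at unit weight, not over the shape vector alone. The
implementation therefore always computes FE distances over combined
features at the active `w`; the `w = 1` case reproduces the printed vector
within the tolerance implied by its 2-dp-rounded inputs (±0.015 per
component). Only the Euclidean metric (Minkowski p = 2) is tested against
the worked example; other exponents are not exposed.

## MDS and hierarchical clustering

* **classical** — Torgerson scaling (eigendecomposition of the
  double-centered squared distances). Deterministic; recovers a planted
  Euclidean configuration exactly (Procrustes RMSE < 1e-6 in the suite).
* **stress_majorization** — metric SMACOF minimizing raw stress
  `σ(X) = Σ_{i<j} (δ_ij − d_ij(X))²` via the Guttman transform. The
  majorization guarantees a non-increasing stress sequence, which the
  result exposes (`stress_history`) and tests assert per-iteration. The
  monotone transform of the dissimilarities is the identity (metric MDS);
  isotonic (non-metric) fitting is out of scope.
* **individual_difference** — an INDSCAL-style weighted-Euclidean model
  for multiple matrices: common configuration `X`, nonnegative per-matrix
  dimension weights `w_m`, so matrix m is approximated by distances in
  `X·diag(√w_m)`. Fitting alternates (1) `X` from classical scaling of
  the averaged double-centered matrices followed by guarded Guttman
  refinement and (2) `w_m` by nonnegative least squares on the
  scalar-product matrices. Updates that would increase total stress are
  rejected, so the recorded trace is non-increasing by construction. The
  exact published algorithm is unspecified; this variant honours the same
  objective and is compared qualitatively only. Identical input matrices
  provably receive identical weights (tested), and doubling a matrix's
  distances quadruples its weights.

Embedding coordinates are defined only up to
rotation/reflection/translation; axis signs are canonicalized (the
largest-magnitude coordinate of each axis is made positive) so rendered
configurations are reproducible, and all configuration tests align by
orthogonal Procrustes before comparing. No semantic meaning is assigned to
individual MDS axes.

Hierarchical clustering delegates to scipy's `linkage` with Ward (default)
or average linkage on the observed distances; dendrograms export to Newick
with branch lengths equal to parent–child height differences (labels with
spaces are quoted), and round-trip through a standard Newick parser.

## Random-Forest protocol

Eyes are independent samples (24 rows for a 6 + 6 cohort). Schemes:
two-class (HN = H ∪ N vs D) and three-class (H, N, D). Per repeat a
*stratified* random third is held out, a `RandomForestClassifier` with 500
trees and per-tree bootstrap draws of 6 samples (`tree_sample_size`,
exposed) is fitted on the rest, and the held-out third is scored; 10
repeats by default, pooled contingency counts, per-class error mean ± SD.
Stratification is a deliberate choice: with two dozen samples an
unstratified third can empty a class from the training portion. A split
that nonetheless lacks a class is discarded with a warning and replaced.

The fusion weight is optimized by sweeping the grid
`0, 0.3, 0.5, 1.0, 1.5, 2.0, 3.0, ∞` with the same split seed at every
grid point, so error differences across `w` are paired comparisons.

Feature importances are *held-out* permutation importances: per stratified
split, each FE component is permuted on the held-out third and the
accuracy drop averaged over splits. Evaluating on held-out eyes rather
than the training set keeps the importances unbiased — a forest that
merely memorizes noise scores zero, a property the null-cohort test
asserts.

Proximity clustering fits one forest on all rows, defines proximity of two
eyes as the fraction of trees in which they share a leaf, and clusters the
distances `1 − proximity` with Ward linkage.

All stochastic results are bit-reproducible from the seed; derived
per-repeat seeds stay below 2³¹.

## Synthetic cohort generator

The waveform model is a continuous piecewise-exponential envelope — the
simplest form reproducing the observed morphology (the analysis uses shape
only, so no physiological ODE is warranted): baseline until `latency`
(0.25 s); exponential constriction (`constriction_tau` = 0.4 s) toward
`baseline − amplitude`, treated as complete after 5 time constants;
exponential escape (`recovery_tau` = 2 s) toward
`baseline − sustain_fraction·amplitude` until light offset; then recovery
toward `baseline − pipr_fraction·amplitude`. Defaults:
`sustain_fraction` = 0.35/0.45/0.85/0.95 and `pipr_fraction` = 0/0/0/0.4
for r10/r100/b10/b100 — sustained blue plateaus, red redilation, and a
bright-blue PIPR. Additive Gaussian noise (0.05 mm) and optional dropouts
complete a record. With noise off the output matches the closed form to
1e-9, asserted against an independently coded scalar oracle.

Amplitudes are *fractions of baseline*, calibrated in closed form so that
at the healthy reference baseline (6.46 mm) the mean diameter over the
stimulus window equals the reference values 4.82/4.30/3.74/3.16 mm for
r10/r100/b10/b100 — the envelope is linear in (baseline, amplitude), so
the fraction solves `baseline·(1 − frac·M_c) = target_c` with `M_c` the
unit-profile window mean. Two consequences are intentional:

* the expected stimulated diameters are ordered r10 > r100 > b10 > b100
  in every class (verified empirically at 500 subjects per class), and
* the age effect — patients' smaller elderly baseline (mean 4.87 mm vs
  6.46 mm, SD 0.45) — rescales the waveform affinely, so shape and
  standardized-amplitude features are age-invariant by construction.

Healthy subjects get two similar eyes (inter-eye CV 2% on amplitude
fractions; between-subject CV 8%). Patients get one age-affected normal
eye (healthy-shaped at the smaller baseline) and one diseased eye with
30% amplitude reduction, 20% blue-sustain reduction and an extra 10%
per-condition asymmetry CV. The published record gives no quantitative
deformation for diseased waveforms, so these effect sizes are free
parameters of the generator, chosen once so that the class-mean diameter
ordering above survives in the diseased class (the clinically observed
structure) while leaving a clear disease signature; they are documented
here and not adjusted per analysis. One trial per condition is generated
(single-trial protocol, no repeats). A single global seed expands into
per-(subject, eye, condition) substreams by CRC-32 keying, so any record
is reproducible independently of generation order.

What the generator does **not** emulate: hippus and accommodation
oscillations, circadian or drug modulation, latency/velocity changes with
disease, non-stationary noise, or realistic blink statistics. Passing
tests on synthetic cohorts therefore demonstrate that the pipeline's
machinery is correct and sensitive to the planted effect structure — not
that the published real-cohort error rates transfer. In particular,
because the synthetic age effect is purely affine, age-affected N eyes are
*indistinguishable* from healthy eyes by design (three-class N error near
1), a sharper version of the published observation that the N class is the
hard one.

## Problem sizes and numerical choices

Test and demonstration cohorts use the study-scale 6 + 6 subjects (24
eyes); Monte-Carlo order checks use 500 subjects per class; replicate
counts for stochastic property tests are 20 (10 for the importance null),
with forests of 100–200 trees where a full 500-tree forest adds nothing to
the property under test. Distances and features are computed in float64
at full precision; two-decimal rounding is a rendering convention only.
Tie-breaking in clustering follows scipy's deterministic ordering; sweep
ties resolve to the first grid value. Degenerate inputs fail loudly:
constant windows (FD₁ = 0) raise rather than emitting NaN shape ratios,
as do non-positive FD₀ values and incomplete subjects.
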