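# plrwave

Waveform-shape analysis of chromatic pupillary light reflexes (PLR) for
screening retinal disease.

## The problem

Chromatic pupillometry records the pupil diameter of each eye while a red
(635 nm) or blue (470 nm) light pulse is presented at low or high luminance
(10 or 100 cd/m²) — four conditions coded `r10, r100, b10, b100`, each a
20-s pupillogram at 30 Hz (10-s pulse + 10-s recovery). Blue light drives
the melanopsin (ipRGC) system, which sustains constriction through the
pulse and after its offset; red light drives the transient rod–cone
pathway, so the pupil partially redilates during the pulse. Retinal disease
such as age-related macular degeneration (AMD) distorts these waveforms
asymmetrically between the eyes, while normal ageing mostly shrinks the
baseline pupil. `plrwave` turns these waveforms into compact shape
features and classifies eyes as healthy (H), age-affected normal (N) or
diseased (D).

## The method

For the 10-s stimulus window *x(n)* of one eye × condition, the Fourier
descriptors are the DFT coefficient magnitudes FD₀, FD₁, …. Three feature
constructions follow:

- **shape vector** *f* = [FD₂/FD₁, FD₃/FD₁, FD₄/FD₁, FD₅/FD₁] —
  low-order harmonic ratios, invariant to amplitude scale and offset;
- **standardized amplitude** FD₀′ = FD₀ / mean(FD₀ over the eye's four
  conditions), so the four values of one eye average exactly 1;
- **combined feature** *f*′ = [*f*, *w*·FD₀′] with fusion weight *w*
  (grid 0, 0.3, 0.5, 1.0, 1.5, 2.0, 3.0, and an amplitude-only mode).

Per eye, the Euclidean distances between the four conditions' combined
features form a 4×4 matrix whose strict upper triangle is the 6-component
**FE vector** [r10−r100, r10−b10, r10−b100, r100−b10, r100−b100,
b10−b100]. FE vectors feed multidimensional scaling (classical, SMACOF
stress majorization, or an individual-difference/INDSCAL variant), Ward
hierarchical clustering, and a repeated-split Random-Forest classifier
(500 trees, stratified ⅓ test split, 10 repeats) with held-out permutation
feature importances and proximity-based clustering.

Because no public pupillogram cohort exists for this protocol, the package
includes a synthetic generator (`plrwave.simulate`) producing binocular
four-condition cohorts with the expected morphology: piecewise-exponential
constriction, sustained blue plateaus, red redilation, bright-blue PIPR,
an age effect (smaller elderly baselines) and disease effects (reduced
amplitude, reduced blue sustain, inter-eye asymmetry).

## Worked example

The published worked example for one healthy left eye starts from the r10
FD magnitudes `[501.0, 83.6, 50.6, 28.2, 23.3, 30.0]`:

```python
>>> import numpy as np
>>> from plrwave import FDVector, shape_vector
>>> np.round(shape_vector(FDVector(np.array([501.0, 83.6, 50.6, 28.2, 23.3, 30.0]), n=600)), 2)
array([0.61, 0.34, 0.28, 0.36])
```

FD₂…FD₅ divided by FD₁ = 83.6 give the four shape ratios. A full synthetic
run:

```python
>>> from plrwave import CohortSpec, simulate_cohort, build_feature_rows, rf_classify
>>> rs = simulate_cohort(CohortSpec(seed=1))          # 6 healthy + 6 patients
>>> rows = build_feature_rows(rs, w=1.5)              # 24 eyes x 6 FE features
>>> rows.head(3).round(3)
  subject    eye label    w  r10-r100  r10-b10  r10-b100  r100-b10  r100-b100  b10-b100
0     H01   left     H  1.5     0.223    1.162     1.148     0.989      0.949     0.258
1     H01  right     H  1.5     0.224    1.181     1.202     1.009      1.004     0.230
2     H02   left     H  1.5     0.167    1.136     1.172     0.977      1.009     0.131
>>> rep = rf_classify(rows, scheme="two_class", seed=1)
>>> rep.class_error_mean.round(3).to_dict()
{'D': 0.0, 'HN': 0.0}
```

Healthy eyes show large red-vs-blue distances (`r10-b10` ≈ 1.2: sustained
blue vs transient red) and small same-colour distances; diseased eyes
compress the colour contrast, which the forest exploits — on this strongly
affected synthetic cohort both pooled classes are classified without
error. Under the three-class scheme the age-affected N eyes remain hard to
separate (error 0.9 here): the generator's age effect only rescales the
waveform, which the shape features deliberately ignore.

The same pipeline is available from the shell:

```
plrwave simulate --n-healthy 6 --n-patients 6 --seed 1 --out cohort.csv
plrwave distances --in cohort.csv --w 1.5 --out fe.csv
plrwave sweep --in cohort.csv --classes 2 --seed 1 --out sweep.json
plrwave run --config pipeline.yaml --out-dir runs/demo
```

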