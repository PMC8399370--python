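# Methods

## Signal model and pipeline

`afdet` treats an ECG segment as a uniformly sampled millivolt trace
`EcgSignal(samples, fs)`. The detection pipeline is strictly
feed-forward: denoise → (R-peak QC) → FSWT → quantize/pool/flatten →
classify. R-peak detection is a standalone quality-control stage; the
featurization operates on fixed-length segments and does not depend on
beat locations, so a missed beat cannot corrupt a feature vector.

## Denoising

Baseline wander is modelled as a slowly varying polynomial trend. The
degree-13 least-squares fit is computed against a time axis rescaled
to [−1, 1]; at degree 13 a Vandermonde system on raw sample indices is
numerically useless, while on [−1, 1] the fit is stable and the
residual is orthogonal to the full polynomial span to machine
precision. Detrending is applied per continuous record before
segmentation when records are available, and per segment otherwise —
the two agree for any trend the polynomial can follow.

Savitzky–Golay smoothing (window 9, order 3 at 250 Hz, i.e. a 36 ms
window) replaces each sample with the centre of a local cubic fit. It
reproduces polynomials up to cubic exactly, so P-QRS-T morphology is
preserved while broadband noise variance is reduced by the sum of the
squared convolution coefficients (≈ 0.33 for 9/3). Edges use
polynomial extension (`mode="interp"`), keeping segment length fixed.

## Pan-Tompkins detection

The canonical stages are implemented at the native sampling rate
rather than resampling to the 200 Hz of the original difference
equations: a 2nd-order Butterworth 5–15 Hz bandpass (zero-phase),
five-point derivative, squaring, 150 ms moving-window integration,
then adaptive dual-threshold selection with a 200 ms refractory
period, an 8-beat running RR average, and a search-back pass at half
threshold when a gap exceeds 1.66× the running average. Detections are
refined to the local maximum of the bandpassed signal within ±50 ms.
All thresholds are relative to running peak estimates, which makes the
detected indices exactly invariant to positive amplitude rescaling —
a property the tests exercise directly.

## FSWT discretization

The forward transform is evaluated on the segment's own DFT grid: for
each observation frequency ω the time row is the inverse FFT of
f̂(u) · p̂\*(k(u−ω)/ω) over the signed bin frequencies u. This makes
the frequency grid spacing 1/duration, reproducing the 400-column
matrix for a 5 s / 0–80 Hz analysis, and costs O(N_ω · N log N).
Numerical choices:

- **DC column.** σ = ω/k collapses to zero width at ω = 0, so the grid
  starts at the first positive bin. Baseline content is removed by the
  detrend stage anyway.
- **Real-signal convention.** Only non-negative observation
  frequencies are stored; the inverse doubles the real part of the
  positive-frequency integral. Round-trip reconstruction of content
  inside the analysed band is then exact up to floating-point error
  (measured ~1e−14), because the stored columns coincide with DFT bins
  and p̂(0) = 1 collapses the inner τ-integral onto the spectrum.
- **Conjugation.** The slice function enters conjugated. The three
  named slices are real, but user-supplied complex slices follow the
  same code path (property-tested against the brute-force oracle).
- **k = 3 default.** The resolution factor is exposed as a parameter;
  a constant is the reproducible choice. k = 3 puts the half-power
  width of a pure-tone response at roughly a third of the observation
  frequency — sharp enough to separate the 4–9 Hz fibrillatory band
  from QRS energy, wide enough that a 5 s segment's 0.2 Hz bins are
  not undersmoothed. Resolution sharpens monotonically with k
  (property-tested over k ∈ {1, 3, 10}).
- **Gaussian slice default**: smooth, strictly positive, rapidly
  decaying; the alternatives e^{−|ω|} and 1/(1+ω²) are provided.

## Featurization

Quantization is per segment: |W| is min-max scaled to 0–255 and
rounded, which makes features invariant to overall gain and electrode
contact differences; a constant matrix maps to zero. Pooling is
non-overlapping M×N block averaging applied *after* quantization
(10 time rows × 5 frequency columns by default → 40 ms × 1 Hz pooled
resolution), and the pooled matrix is flattened row-major
(time-major). When the window divides the matrix exactly, pooling
conserves the mean; trailing partial blocks are dropped.

## Classifiers

The Gaussian-kernel SVM uses K(x,y) = exp(−‖x−y‖²/scale²) with the
tuned defaults scale = 979.08, box constraint C = 248.68. Both the
kernel formula *and* an internal z-scoring of features are part of the
model: the tuned values were obtained in an environment whose kernel
scale applies to standardized predictors, and under any other
convention they are meaningless — on raw 10,000-dimensional 0–255
features the pairwise distances (~4·10³) dwarf the scale, the Gram
matrix degenerates to near-identity, and the classifier memorizes
rather than generalizes (we measured ~0.93 vs ~0.975 held-out accuracy
with standardization). In scikit-learn terms the model is
`StandardScaler` + `SVC(C=248.68, gamma=1/979.08²)`.

KNN uses k = 1 with correlation distance and inverse-distance weights;
correlation distance compares the *shape* of the pooled time-frequency
pattern rather than its magnitude. The bagged ensemble aggregates 100
bootstrap Gini trees by majority vote; the single decision tree and
Gaussian naive Bayes serve as contrast models. Hyperparameter tuning
is a seeded random search (30 iterations default) minimizing 10-fold
stratified CV error over kernel scale ∈ [10⁻³, 10³]·√d and
C ∈ [10⁻³, 10³] (log-uniform); the shipped defaults make tuning
optional.

Metrics use AF as the positive class. Accuracy, sensitivity and
specificity follow the standard confusion-count definitions; a zero
denominator yields NaN with a warning, never a silent 0 or 1, and the
identity acc = (se·P + sp·N)/(P+N) holds exactly whenever defined.

## Synthetic data: what it emulates and what it does not

Each beat is a sum of five Gaussians (P, Q, R, S, T) with default
amplitudes 0.15/−0.1/1.0/−0.2/0.3 mV; the P centre sits 170 ms before
the R peak, inside the 250–120 ms pre-R window where P-wave energy is
physiologically expected. RR intervals are log-normal (strictly
positive, parameterized by mean heart rate and coefficient of
variation): NSR defaults to 75 bpm with CV 0.03, AF to 95 bpm with CV
0.25 — AF is typically conducted faster and is defined by its
irregularity. The AF template has its P amplitude forced to exactly
zero, and a fibrillatory component — three random-phase sinusoids
drawn uniformly from 4–9 Hz, scaled so the sum carries the power of a
single sinusoid at the stated `fwave_amp` (default 0.08 mV, a fine-to-
moderate f wave) — is added. Ground-truth beat times are returned with
every segment, so detector tests need no manual annotation.

Study segments are contaminated with 0.2 mV drift at 0.3 Hz, 0.05 mV
mains interference at 50 Hz, and 0.05 mV white noise before denoising.

The generator is a morphological emulator, not a physiological model:
no respiratory modulation, no heart-rate drift, no ectopy, no
electrode-motion artefacts, no inter-subject morphology variation, and
its f wave is a 3-line spectrum rather than a broadband process.
Passing tests therefore demonstrate that the pipeline separates the
defining AF signatures (absent P, f-wave band energy, RR irregularity)
under realistic stationary noise — not that it matches any particular
clinical performance level on real recordings, which additionally
contend with all the effects listed above.

## Problem sizes

The test suite and the acceptance script run the classification study
at 300 balanced 5 s segments per seed over 5 seeds with a 9:1 split —
large enough that the default models sit on the flat part of their
learning curves (held-out accuracy changes by <2 % when doubling the
training set) while the full suite completes in a few minutes. R-peak
sensitivity is measured over 20 independent 10 s recordings; FSWT
oracle equivalence is checked at n = 64 where the O(N²·N_ω) direct
summation is affordable.

## Known limitations

- The WFDB layer reads/writes only format-16 signals and MIT rhythm
  annotations — enough for AF-database replication round trips, not a
  general WFDB implementation.
- The resolution factor k is a constant, not a function of observation
  time and frequency; it is exposed as a parameter.
- `run_experiment` drives the synthetic source only; real-record
  studies compose `load_wfdb_record` → `segment_by_rhythm` →
  `balance_classes` directly.
- Binary rhythm classification only (AF vs non-AF); atrial flutter and
  junctional rhythm intervals are excluded from dataset assembly, not
  classified.
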