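# Methods

This note records the models, estimator conventions, numerical choices and
known limitations of `eegfc`, in the order the pipeline runs.

## Signal model of the synthetic generator

Each channel is a band-centred stochastic oscillator: Gaussian white noise
whose spectrum is masked to the band of interest, kept as an analytic
(positive-frequency) signal and normalized to unit RMS. Stochastic
carriers rather than pure sinusoids are used deliberately: with pure tones
every connectivity metric saturates at 1, whereas narrowband noise makes
coherence and PLV take intermediate values that respond smoothly to the
coupling strength.

Coupling between channels *i* and *j* with strength `c ∈ [0, 1]` and lag
`ψ` mixes a shared carrier `s(t)` into both channels:

    x_i = c·Re(s) + (1 − c)·u_i
    x_j = c·Re(s e^{−iψ}) + (1 − c)·u_j

where `u_i, u_j` are independent carriers in the same band. The lag is
applied by rotating the analytic carrier, so the downstream phase
difference is controlled exactly: `c = 1, ψ = 0` gives PLV 1 and PLI 0;
`c = 1, ψ = π/2` gives PLI 1; `c = 0` leaves the channels independent.
Optional shared amplitude envelopes (a slow 0.1–1 Hz Rayleigh-like
envelope multiplying both channels) produce amplitude correlation without
phase locking. Independent broadband noise of standard deviation
`noise_sd` (default 0.2 against unit-RMS carriers, i.e. ≈ −14 dB) is added
per channel.

Cohorts assign per-subject seeds via `SeedSequence([master, index])`, so
subjects are independent but the whole cohort is reproducible bit-for-bit.
The default cohort shape is 24+24 subjects × 30 epochs × 6 s × 250 Hz ×
128 channels; per-trial block labels ("Neu"/"Emo") split the epochs in
half. The group effect is a per-group coupling override applied only to
the designated group.

What the generator does **not** emulate: volume conduction / field spread
(each channel is a separate source; zero-lag mixing across many channels
is absent), 1/f background spectra, artifacts (blinks, EMG, line noise),
electrode geometry, and non-stationarity across trials. Passing tests
therefore demonstrate that the estimators, graph metrics, image encoding
and classifier behave correctly on signals with known coupling — not that
the pipeline is robust to the confounds of real recordings (in particular,
real zero-lag volume conduction is exactly what PLI is designed to
discount, and that discount is only exercised synthetically here).

## Preprocessing

Filtering uses 4th-order Butterworth sections applied forward–backward
(`sosfiltfilt`), i.e. zero phase — required because instantaneous phase is
extracted downstream. Broadband defaults are 0.5–70 Hz; band filters use
the canonical δ/θ/α/β/γ intervals, half-open `[f_lo, f_hi)`. Cutoffs at
or above Nyquist are rejected. Segmentation cuts continuous signals into
fixed-length epochs (default 6 s) either at supplied marks or by uniform
tiling, discarding partial tails; marks too close to the end drop that
epoch with a warning. Artifact removal is a pluggable `clean(rec,
cleaner)` hook (identity by default) since synthetic data are clean and
real pipelines delegate to dedicated tools.

## Connectivity estimators

All four metrics produce one symmetric matrix per trial, per band.

- **Coherence**: Hann-tapered windows within the trial (default 1 s, 50 %
  overlap, so a 6 s trial has 11 windows), cross- and auto-spectra averaged
  over windows, coherence formed per FFT bin, then averaged (unweighted)
  over the bins whose centres fall in the band. Averaging must be internal
  to the trial because one matrix per trial is required; a single-window
  coherence is identically 1 and is rejected.
- **Correlation**: Pearson correlation of the band-filtered series within
  the trial. Absolute values are passed downstream (thresholds live on
  (0, 1); image pixels are nonnegative); the signed matrix is retained in
  `signed_values`. Zero-variance channels are a hard error.
- **PLV / PLI**: phases from the analytic signal of the band-filtered
  series; the first and last 0.5 s of each epoch are trimmed (configurable)
  because Hilbert-transform phase is unreliable at the edges. PLI wraps
  phase differences to (−π, π] with `sign(0) = 0`.

Time-domain band filtering (rather than spectral masking) was chosen for
correlation/PLV/PLI; it is the standard EEG practice and keeps one
filtered representation shared by all three metrics. The exact spectral
estimator settings (window length, taper, overlap) are exposed as
arguments and recorded here as defaults rather than hidden constants.

Null levels: between independent channels PLV/PLI do not approach the
i.i.d. `≈ √π/2·n^{−1/2}` rate, because narrowband phases are autocorrelated
(a 5 Hz-wide band at 250 Hz yields roughly 25× fewer effective samples).
Tests compare the estimator mathematics against i.i.d. resampling oracles
at the phase level and treat pipeline nulls as contrasts (coupled ≫ null).

## Graph analysis

Binarization uses a strict rule (edge iff value > T). The sweep covers
interior thresholds at step 0.025 (coherence/correlation/PLV: 39 points)
or 0.005 (PLI: 199 points). Metrics:

- clustering `C_i = 2t_i / (k_i(k_i−1))`, 0 for degree < 2; network C is
  the node mean;
- path length L = mean shortest-path length over **connected ordered
  pairs**; infinite distances in disconnected graphs are excluded (this
  keeps the sweep defined at high thresholds, where the graph fragments);
  an edgeless graph has no L and that threshold is recorded as missing;
- random references: 20 graphs drawn uniformly among graphs with the same
  node and edge count (not degree-preserving rewiring — the null model is
  "the same amount of connectivity, placed completely at random");
  `γ = C/Cr`, `λ = L/Lr`, `S = γ/λ`.

Graph analysis operates on the subject's trial-averaged matrix (one
network per subject per band/block), matching the subject-level group
statistics. Per-electrode group comparisons are independent two-sample
t-tests on node clustering at a fixed threshold (conventionally T = 0.15),
flagged at p < 0.05 ("sig") and 0.05 ≤ p < 0.1 ("trend"), uncorrected by
default with an optional Benjamini–Hochberg switch — electrode-wise EEG
tables are conventionally reported uncorrected, and the switch makes the
stricter choice available.

## Image encoding

Row-major enumeration of the strictly-upper triangle, refilled row by row
into a `⌊√(n(n−1)/2)⌋`-sided square; the tail is discarded. Row-major
order is essential: it is the only enumeration for which the discarded
tail of a 128-channel matrix consists exactly of the 28 pairs among the
last eight electrodes (the face electrodes most affected by myogenic and
ocular activity). Pixel values are the raw metric values (already bounded
per metric); no per-image normalization is applied by default. Three-band
stacks order channels by descending single-band CV accuracy (red = best).
Electrode location information is deliberately not represented.

## CNN and training

Architecture: conv 32@3×3 (stride 1, pad 1) → ReLU → conv 32@3×3 → ReLU →
maxpool 2×2 stride 2 → flatten → FC 512 → ReLU → dropout 0.5 → FC 2 →
softmax. For 90×90 inputs the pooled map is 45×45×32 (flattened 64,800).
The conv–conv–pool ordering (a single pooling stage) follows the stacked
two-convolution design; dropout is applied only after the hidden fully
connected layer. Loss is cross-entropy on softmax outputs (log-sum-exp
stabilized). Training: Adam (lr 10⁻³, β₁ = 0.9, β₂ = 0.999), Xavier
(Glorot-uniform) initialization, 15 epochs, batch 30. Early stopping is
"keep best": the full epoch budget runs and the weights from the epoch
with the highest validation accuracy are restored (no patience abort);
with no validation set it is disabled with a warning. All randomness
(init, shuffling, dropout) flows from one seed, so runs are reproducible.

The network is implemented in numpy: convolutions as im2col patch-matrix
products in NHWC layout (forward, weight gradient and input gradient are
all BLAS sgemm calls in float32), max-pool subgradients split evenly among
tied maxima, and a fused single-pass Adam update (numba when available,
vectorized numpy otherwise). Gradients are verified against central
finite differences in float64.

## Cross-validation and baselines

Folds are subject-wise: with two balanced groups of k subjects, fold i
tests one subject per group (pairing by sorted ID — the pairing rule is a
convention chosen for determinism), validates on the cyclically next pair
and trains on the rest; with 24+24 subjects each fold trains on 44. No
subject's trials ever appear in more than one set (enforced structurally
and rechecked at run time). Accuracy is scored per trial, pooled over the
folds of a repeat; repeats (default 9) re-initialize weights with derived
seeds and are summarized as mean ± sd with per-repeat ROC curves and the
vertically averaged mean curve.

Baselines use scikit-learn defaults on the same folds: Gaussian naive
Bayes (standing in for the BayesNet family), logistic regression, kNN at
k ∈ {1, 5, 10} and random forest, fed per-trial mean-connectivity features
(mean of the off-diagonal upper triangle, one column per band); the
maximum accuracy across classifiers is reported alongside the per-family
values. Validation subjects join the baseline training split since these
classifiers do no early stopping.

## Scaled end-to-end experiment

The acceptance experiment runs the full pipeline at a desk scale chosen to
finish in minutes: 12+12 subjects, 30 epochs, 32 channels (→ 22×22
images), alpha-band coupling on 8 fixed channel pairs with mixing weight
0.8 in the "depressed" group vs 0.3 in controls (a deliberately strong,
clearly detectable effect — no quantitative real-world effect size is
available to calibrate against), coherence images, 12-fold subject-wise
CV, 3 repeats; plus a zero-effect arm (both groups at 0.3) that must
classify within chance bounds. Chance bounds are computed at subject
resolution (24 test subjects), since trials within a subject are
correlated and trial-level binomial bounds would be anti-conservative.

## Configuration file for `eegfc simulate`

```yaml
n_per_group: 24        # subjects per group
n_epochs: 30           # epochs per subject
epoch_len_s: 6.0       # seconds per epoch
fs: 250.0              # Hz
n_channels: 128
seed: 0
base:                  # coupling applied to every subject
  band: alpha
  noise_sd: 0.2
  pairs: []            # [channel_i, channel_j, strength, phase_lag]
group_effect:          # per-group overrides (same pair -> replaced)
  depressed:
    band: alpha
    noise_sd: 0.2
    pairs:
      - [0, 1, 0.8, 0.0]
```

## Known limitations

- The generator's realism gaps listed above; in particular no
  volume-conduction confound, so coherence/correlation/PLV are not
  penalized relative to PLI the way they would be on scalp EEG.
- Coherence windows within a 6 s trial are few (11 at 50 % overlap), so
  per-trial coherence is noisy at the single-pair level; per-trial PLI on
  6 s of narrowband signal is likewise a high-variance estimate.
- The uniform random-graph null keeps edge count but not the degree
  sequence; γ and λ therefore differ from degree-preserving nulls on
  graphs with skewed degrees.
- `L` on disconnected graphs ignores unreachable pairs, which flatters
  fragmented networks at high thresholds; the number of excluded pairs is
  logged at debug level.
- The CNN is CPU-oriented; wall time scales linearly with images ×
  epochs × folds × repeats (the default acceptance experiment performs
  72 fold-trainings).
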