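# Methods

## Model

Let X be one trial of C-channel EEG with T samples, and let two conditions
be labelled 1 and 2 (when labels are arbitrary integers, the smaller value
is condition 1).  For an FIR half-order k ≥ 0, the delay embedding stacks
the 2k+1 shifted copies of every channel:

    X̃[(i+k)·C + c, t] = X[c, t + k + i],   i = −k … +k,  t = 0 … T−2k−1.

Only the valid region is kept — the k samples at each end, where some shift
would run off the trial, are dropped, and nothing is zero-padded.  Padding
would inject edge transients into every covariance estimate, while 2k ≪ T
in all intended uses, so the loss of 2k samples is immaterial.  The block
order is delay-major (all channels of delay −k first), which makes the
per-delay spatial filters of a fitted column contiguous slices.

A weight vector w̃ ∈ R^D (D = C·(2k+1)) applied to X̃ is algebraically
identical to filtering each channel c with its own 2k+1-tap FIR filter
b_c[i] = w̃[(i+k)C + c] and summing the filtered channels.  This identity is
asserted to 1e-10 in the test suite and is the basis of all filter
interpretation: slicing by delay yields 2k+1 spatial filters, slicing by
channel yields C channel-specific FIR filters whose frequency response is
H_c(f) = Σ_i b_c[i]·exp(−j2πfi/fs).  The symmetric, non-causal support
(i from −k to +k) means H is complex in general; magnitude is what the
analysis tables report.  The induced group delay is zero at the centre of
the symmetric support; we adopt the symmetric convention throughout and
offer no causal (0…k) variant.

## Covariances and the regularised eigenproblem

Each trial contributes X̃X̃ᵀ normalised to unit trace; per-condition
covariances Σ̃₁, Σ̃₂ are arithmetic means of these, renormalised to trace 1.
Per-trial trace normalisation is standard CSP practice: it removes
trial-to-trial global amplitude fluctuations and, more importantly here,
makes the ridge strength ε comparable across datasets, so a single grid
{10⁻⁴, 10⁻⁵, 10⁻⁶} is meaningful everywhere.  (Pooling samples across
trials instead of averaging normalised per-trial covariances would agree up
to normalisation for equal-length trials; we implement and document the
per-trial choice.)

Filters solve

    (Σ̃₁ + εI) w̃ = λ (Σ̃₁ + Σ̃₂ + 2εI) w̃ .

Regularising *both* sides with the identity keeps the classic CSP semantics:
every λ lies strictly in (0, 1) when ε > 0, and swapping the class roles
maps the spectrum to 1 − λ (asserted as a property test).  In the
ε-dominated limit both sides approach multiples of the identity and all
eigenvalues collapse to 1/2; monotone shrinkage of |λ − 1/2| with growing ε
is also property-tested.  With ε = 0 a singular composite matrix raises an
explicit error advising regularisation — exactly the failure mode that
motivates the ridge: the augmented "channel" count D can overwhelm the
number of samples.

The solve itself is `scipy.linalg.eigh(A, B)` (generalised
symmetric-definite); the package's contribution is the construction around
it, not the LAPACK call.  Two independent oracles check it: a closed-form
diagonal 2×2 problem, and an adaptive random search of the generalised
Rayleigh quotient over a budget of 1e5 random unit directions (uniform
first round, then Gaussian perturbations of the incumbent with
geometrically shrinking scale; plain uniform sampling cannot localise an
extremal direction in 5–6 dimensions to the tolerances we use, so the
search narrows — but never consults an eigensolver).

Eigenvectors are returned with unit Euclidean norm and the sign fixed so
each column's largest-magnitude entry is positive; both are free in the
mathematics, fixing them makes fits bit-reproducible.  A model keeps the m
columns of largest eigenvalue (descending) followed by the m of smallest
(ascending).  At k = 0 the whole construction reduces to regularised CSP;
the suite verifies filters and features against an independent
whitening-route implementation to 1e-10.

## Features, classifier, metric

Features are ln(var) of each trial projected on each retained column
(variance with ddof = 1).  Log-variances are *not* normalised across the
selected filters; a Ramoser-style normalised variant can be obtained by
post-processing but is not the default.  A projected series with exactly
zero variance raises an error naming the trial and filter rather than
silently producing −∞.

The read-out is a soft-margin linear SVM (libsvm via scikit-learn) with
unit base cost and per-class penalties n/(2·n_c) — inversely proportional
to class frequency, so 41 targets against 4000 distractors weight the
minority ≈ 98× heavier.  Linear kernel and unit cost are deliberate: 4–6
dimensional log-variance features are near-linearly separable in this
literature, and fewer knobs means less to tune.  Balanced accuracy (mean of
per-class recalls) is the imbalance-robust metric; with equal class sizes
it coincides exactly with plain accuracy.  Defaults: accuracy for balanced
designs, balanced accuracy for imbalanced ones, both selectable.

Hyperparameters (k, ε) are chosen by stratified 5-fold cross-validation
over k ∈ {0, 1, 3, 5} × ε ∈ {10⁻⁴, 10⁻⁵, 10⁻⁶} with a fixed fold seed (0);
ties prefer smaller k, then larger ε — the simpler, more regularised model.
Fixed-parameter mode uses k = 5, ε = 10⁻⁵.

## Preprocessing recipes

* **mi**: epochs band-pass filtered 8–30 Hz with a 5th-order Butterworth
  filter, applied causally by default (a zero-phase flag exists; which was
  used originally for this recipe is not knowable, so the causal reading is
  the default).
* **rsvp**: the continuous recording is high-pass filtered at 1 Hz twice,
  then low-pass filtered at 25 Hz, with linear-phase windowed-sinc FIR
  filters (Hamming window, order ⌈3·fs/cutoff⌉ rounded up to even) applied
  zero-phase — the event-locked 0–500 ms window is latency-sensitive, so
  the FIR stage must not shift peaks.  This emulates the common
  EEGLAB-style FIR routine and is documented as an approximation, not a
  bit-level reproduction of any particular toolbox.

Epoch windows are half-open [t0, t1) with 0-based indexing: round((t1−t0)·fs)
samples per trial, the sample at exactly t1 excluded.  0.5 s at 250 Hz is
always 125 samples; [0.5 s, 2.5 s) at 100 Hz is always 200.

## Synthetic data

The generator emulates the two protocol families without any recorded data.

*mi-like*: latent band-limited Gaussian sources (white noise passed twice
through a 4th-order Butterworth band-pass — the repeated pass sharpens the
skirts so > 80 % of source power sits inside the nominal band), normalised
to unit standard deviation per trial, scaled by a class-dependent amplitude
ratio r (so the planted band-power ratio is r²), projected onto channels by
a mixing row, plus white sensor noise.  *rsvp-like*: identical background
plus a half-sine transient of given latency (peak time), width and
amplitude added to target trials on a loaded channel subset.

Three canned scenarios (8 channels) drive tests and the acceptance script:

* **(a)** one broadband source (8–30 Hz, class ratio 2) on channels 0–2,
  60 trials/class at 100 Hz, 2 s — purely spatial structure; CSP suffices
  and cross-validation picks k = 0 in most runs.
* **(b)** two sources on the *same* channels: 10 Hz ± 2 with class ratio 2,
  and 22 Hz ± 4 with ratio 0.5 at twice the loadings, so the class-1 power
  excess at 10 Hz is exactly offset by a class-2 excess at 22 Hz and total
  channel variance carries no label information.  Only the spectral split
  is discriminative: CSP decodes at chance, the k = 5 model separates the
  classes and its leading filter's FIR response on the discriminative
  channel concentrates in 8–12 Hz.
* **(c)** 24 targets vs 1200 distractors (1:50) at 250 Hz, 0.5 s epochs,
  with a 300 ms-latency, 200 ms-wide, amplitude-1.5 transient on channels
  3–5 over a shared 10 Hz background and unit noise — mirrors the
  event-detection regime (realistic P300 latency and imbalance) at a size
  that keeps repeated fits cheap.

One seeded `numpy` Generator drives each `generate` call, so datasets are
bit-reproducible; stochastic checks fix seeds and use ≥ 10 replicates.

What the generator does **not** model: 1/f background spectra, artifacts
(blinks, EMG), non-stationarity across a session, and volume-conduction
forward physics.  Passing tests therefore demonstrate correctness of the
algorithm and the claimed qualitative behaviours under controlled
conditions; they are not evidence about decoding accuracy on real scalp
recordings.

## Numerical choices and degenerate inputs

* Covariances are symmetrised ((S+Sᵀ)/2) after accumulation; symmetry is
  validated to 1e-12 and positive semidefiniteness to −1e-10·trace.
* ε = 0 is allowed only for well-conditioned composites; singularity is
  detected via the smallest eigenvalue against 1e-12·trace.
* Zero-power trials (trace 0), zero-variance projections, single-class
  label vectors, epochs shorter than 2k+1 samples, cutoffs at or above
  Nyquist and out-of-range windows are all rejected with errors naming the
  offending field; nothing is silently floored.
* Causal FIR application compensates the linear-phase group delay
  (numtaps//2) so filtered signals stay time-aligned; zero-phase
  application uses forward–backward filtering with a pad clamped to the
  signal length.
* Model files are canonical JSON (sorted keys, fixed separators,
  base64-embedded float64 payload), so identical fits yield byte-identical
  files; the optional linear read-out (coefficients, intercept, classes) is
  stored alongside the filter bank.

## Problem sizes

Tests and the acceptance script run entirely on the scenario sizes above:
D = 88 augmented dimensions at k = 5 for 8 channels, 120–1224 trials,
20 replicate seeds for the planted-band study and 10 for the imbalance
study.  These sizes give stable success rates (the replicate criteria pass
with wide margins) while a full run of the acceptance script takes a few
seconds on one CPU.

## Known limitations

* Two conditions only; no multiclass extension, no online updating, and no
  shrinkage estimators beyond the εI ridge.
* The EDF/GDF import path is a thin adapter contract (`from_mne_raw`,
  duck-typed) and is not exercised against real recorder files in the
  suite.
* Amplitude units are treated as opaque; no montage, re-referencing or
  artifact handling.
* At high channel counts with few trials, cross-validated selection is
  noisy (and slow, since D grows with k); the fixed-parameter mode is the
  safer default there — consistent with the known sample-hunger of the
  augmented covariance estimate.
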