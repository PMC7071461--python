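# Methods

`pnespipe` implements a complete resting-EEG epoch-classification pipeline —
synthetic cohort generation, preprocessing, Welch band-moment feature
extraction, and classifier evaluation under subject-level validation — for
a two-class problem (healthy controls, CNT, versus a patient class labelled
PNES). This note documents the models, the defaults and why they were
chosen, and what the synthetic experiments do and do not demonstrate.

## Signal model of the synthetic cohorts

Each channel of a simulated subject is a sum of independent zero-mean
Gaussian components:

- four band-limited noises, one per conventional rhythm — delta (1–4 Hz),
  theta (4–8 Hz), alpha (8–13 Hz), beta (13–32 Hz) — produced by 4th-order
  Butterworth band-pass filtering of white noise (applied
  forward–backward), renormalised to unit variance and scaled by the square
  root of the profile's relative band power. At 256 Hz all four bands keep
  ≥ 80 % of their Welch-estimated power inside their nominal range;
- a 1/f^α broadband background (α = 1 by default, relative power 0.5),
  shaped in the frequency domain with the envelope held flat below 1 Hz to
  avoid the DC singularity;
- optionally a 50 Hz line-noise sinusoid with a random phase per channel
  (amplitude 0 by default, since the analysis notch removes it anyway).

Class structure enters only through the per-band relative powers of the
two `ClassSpectralProfile`s. Subject heterogeneity is one lognormal
multiplicative power factor per band per subject (σ = `subject_sd`,
default 0.1), shared by all channels: this produces the subject-coherent
spectral fingerprint that makes subject-level and epoch-level train/test
splitting genuinely different. Channels are otherwise independent — the
downstream features are strictly per-channel, so spatial covariance would
add realism but no coverage.

Default cohort layout: 10 subjects per class, 19 channels named by the
10/20 system, 256 Hz, 120 non-overlapping 5-s epochs per subject
(153,600 samples per channel). Per-subject random streams are spawned from
`numpy.random.SeedSequence(seed)` in subject order, so the whole cohort is
a pure function of (profiles, spec, seed) and any single subject can be
regenerated independently.

The default demonstration contrast doubles the PNES class's alpha power.
This is a free simulation parameter chosen to be detectable and
physiologically plausible for eyes-closed resting EEG; it is **not** a
claim about PNES electrophysiology, for which no spectral biomarker is
established.

What the generator does *not* emulate: event-related transients,
eye-blink/EMG/ECG artifacts, volume conduction and channel covariance,
non-stationarity within a recording, or reference-electrode effects.
Passing results on these cohorts therefore validate the pipeline's
mechanics (spectral estimation, feature layout, split hygiene, classifier
wiring), not clinical performance.

## Preprocessing

The canonical order for raw input is: downsample (512 → 256 Hz,
anti-aliased decimation) → 3rd-order Butterworth band-pass 1–70 Hz plus
50 Hz IIR notch (Q = 30) → artifact masking → epoching. Filters are
applied zero-phase (forward–backward, doubling the effective order); this
is the standard offline-EEG choice and keeps epochs aligned with the raw
time base. The notch Q trades line suppression against erosion of the
45–55 Hz region; Q = 30 gives > 20× RMS attenuation of a 50 Hz tone while
leaving the beta band untouched. The analysis high-pass is 1 Hz; hardware
acquisition filters (0.5 Hz high-pass) are treated as provenance only.

Artifact annotations are an input (lists of (start_s, end_s) spans from
manual review), never computed. Masking removes the spans, concatenates
the clean remainder, and records segment boundaries; epoching cuts
half-open windows `[iL, (i+1)L)` within segments only, so no epoch ever
straddles a cut. A trailing partial window is discarded and at most
`max_epochs` (default 120) epochs are kept — when a recording holds more
clean signal than 120 × 5 s, the excess is simply ignored.

## Spectral features

Per channel of each 1280-sample epoch, the PSD is the average of L = 9
modified periodograms: 256-sample Hamming-tapered segments with 50 %
overlap (hop 128), one-sided density scaling
`Pxx(f) = |DFT(x_i·w)|² / (fs · Σw²)`, averaged arithmetically. The
estimator is implemented in-package (it is the analytical core of the
pipeline and its segment geometry `L = floor((N−M)/h)+1` is contractual);
unit tests verify bit-level agreement (1e-10 relative) both with an
explicit segment-loop direct-DFT oracle and with `scipy.signal.welch`
(detrending disabled). On the default grid the bin spacing is 1 Hz, and
for white noise the density integrates to the signal variance within 5 %.

Each channel's PSD is sliced into delta/theta/alpha/beta and the whole
band (1–32 Hz), half-open `[low, high)` so shared edges (4, 8, 13 Hz)
count exactly once; the four sub-bands partition the whole band's bins.
Each slice is summarised by four moments of its bin values: mean m,
population (1/N) standard deviation d, Fisher–Pearson skewness v and
Pearson non-excess kurtosis k; a degenerate slice (d = 0) sets v = k = 0
so no NaN reaches the classifiers. Because the PSD is quadratic in signal
amplitude, m and d scale exactly with amplitude², while v and k are
scale-invariant.

Feature order is channel-major, then band (delta, theta, alpha, beta,
whole), then moment (m, d, v, k): 20 values per channel, 380 per
19-channel epoch, 45,600 per 120-epoch subject. Column names encode the
triple (`Fp1_alpha_m`, …) and round-trip through `parse_feature_name`.

## Classifier evaluation

`EpochClassificationExperiment(table).fit()` evaluates an RBF-kernel SVM
(γ = 0.01, C = 1; degree and coef0 are inert for this kernel and retained
for provenance), LDA, and Gaussian naive Bayes (the "NB" model) over two
schemes, always splitting whole subjects:

- **random split**: 7 training subjects per class drawn uniformly
  (with 10+10 subjects × 120 epochs this is 1,680 training and 720 test
  epochs, a 70/30 subject split);
- **leave-one-subject-out (LOO)**: one fold per subject.

Features are z-scored per column with statistics fitted on the training
partition only (zero-SD columns map to 0); this is on by default because
the RBF kernel at γ = 0.01 on raw PSD moments is uncontrolled, and can be
disabled (`--no-scaling`). An epoch-level random split exists behind an
explicit flag purely to quantify the optimism of leaking subjects across
partitions; it is off by default. Every subject-level split is checked at
run time for train/test subject disjointness.

Per split, the results carry confusion counts (PNES positive), accuracy,
per-class and macro precision/recall/F1 (the usual count identities,
verified property-style against direct formula evaluation), and ROC/AUC by
threshold sweep with tie grouping and trapezoidal integration (verified
against the Mann–Whitney rank statistic, ties included). Summaries are
mean ± SD across splits; per-scheme ROC is the vertical average of
per-split curves on a common FPR grid. Because each LOO test set contains
a single subject — hence a single class — per-split precision and AUC are
degenerate there, and the results object additionally reports **pooled**
metrics computed from all held-out predictions of a scheme.

## Known failure mode: leave-one-subject-out on null data

With equal class sizes, every LOO fold trains on 9 subjects of the
held-out subject's class versus 10 of the other: the held-out class is
always the training minority. On a null cohort (identical class profiles)
this has a drastic consequence for the configured SVM: at γ = 0.01 the
380-dimensional z-scored feature space puts typical squared distances near
700, so the kernel matrix is nearly orthogonal, the decision function
collapses to its intercept, and the SVM predicts the training-majority
class for every epoch — which is always the *wrong* class for the held-out
subject. Measured LOO accuracy on null cohorts is therefore ≈ 0 for the
SVM (not 0.5), while LDA and naive Bayes, whose predictions on null data
are dominated by sampling noise rather than the class prior, stay at
chance (0.43–0.50 across seeds). Class-balanced SVM weights and raw
(unscaled) features were measured and do not repair this. Separately,
with *nonzero* subject jitter all three classifiers can dip below chance
under LOO (anti-learning): they overfit subject fingerprints, and the
held-out subject's fingerprint resembles no training subject of its own
class. For these reasons the package's chance-level calibration condition
is the *exchangeable null* — both classes drawn from one profile with
`subject_sd = 0` — and the SVM's collapse there is asserted in the test
suite as a documented failure mode rather than hidden. Users comparing
classifiers under LOO on weak-signal data should treat below-chance SVM
accuracy as this artifact, not as information.

## Numerical and design choices

- Welch taper is the periodic Hamming window (`scipy.signal.get_window`);
  window length = nfft = 256 by default, all configurable.
- Decimation uses `scipy.signal.decimate` (zero-phase, order-8 Chebyshev
  anti-alias) and requires an integer rate ratio.
- EDF files are written with 1-s records, int16 samples, symmetric
  physical scaling; round-trip error is bounded by half a digital step,
  `(phys_max − phys_min)/65535/2`. Reading goes through MNE. The ASCII
  writer uses 17 significant digits, so its round-trip is bit-exact.
- Moment estimators are biased (1/N) on purpose: they are bounded
  summaries used as features, not inferential statistics.
- Degenerate rules: zero-SD feature columns standardise to 0; zero-variance
  PSD slices give v = k = 0; ROC on one-class test sets raises.
- Problem sizes in the test suite: unit tests run on reduced cohorts
  (3+3 subjects, 2–19 channels, 6–10 epochs); the acceptance suite and
  `scripts/acceptance.py` run the full 10+10 × 120-epoch layout, which
  completes in about two minutes on one CPU.

## Limitations

- Synthetic validation only: no claim transfers to clinical EEG.
- The per-fold class imbalance of LOO is inherent to the scheme as
  specified (train on all remaining subjects); the pipeline reports it
  rather than rebalancing folds.
- No hyperparameter search, probability calibration, or statistical tests
  between classifiers; the evaluation grid reports means ± SD and pooled
  metrics only.
- Automated artifact detection is out of scope; annotations are trusted
  input.
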