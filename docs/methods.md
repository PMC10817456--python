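# Methods

## Problem and pipeline

The package asks whether resting-state EEG and single-pulse TMS-evoked EEG
carry enough signal over frontal cortex to separate patients with major
depressive disorder (MDD) from healthy controls (HC). The pipeline is:

1. **Recordings** — per subject, a 5-minute eyes-closed resting recording
   and an 80-pulse single-pulse TMS-EEG recording over 17 frontal 10-10
   electrodes (Fp1, Fpz, Fp2, AF7, AF3, AFz, AF4, AF8, F7, F5, F3, F1, Fz,
   F2, F4, F6, F8), nominally sampled at 3 kHz.
2. **Preprocessing** — resting data are cut into non-overlapping 6 s
   epochs; TMS data into 4 s epochs (−2 to +2 s around each pulse) with
   per-channel mean-baseline correction over −1550…−50 ms. Amplitude-based
   channel/epoch rejection is followed by a first ICA (TMS only, decay
   templates), zero-phase Butterworth band-pass 0.5–100 Hz (order 4) plus
   48–52 Hz notch (order 2), polyphase downsampling to 1 kHz, and a second
   ICA (blink topography, line-noise peaks). IC removals are capped at
   ⌊0.20·n⌋ combined across the two TMS stages and ⌊0.08·n⌋ for resting
   data. Analysis windows: pre-stimulus [−1550, −50) ms and post-stimulus
   [50, 550) ms; the ±50 ms around the pulse is never used. Intervals are
   half-open and converted to samples by rounding.
3. **Features** — per modality: Welch band power (500 ms Hann segments,
   50 % overlap; a segment is two cycles of the 4 Hz theta edge) integrated
   over θ (4–7), α (8–13), β (14–30), γ (30–45 Hz); the weighted phase lag
   index (wPLI) for all 136 channel pairs per band; and the Tort modulation
   index (MI) for θ–γ and α–γ coupling averaged over the left-DLPFC
   electrodes (F3, F5, AF3). That is 68 + 544 + 2 = 614 features per
   modality: RST (per-epoch features averaged over resting epochs), PRE and
   PST (features of the epoch-averaged evoked trace in each window), and
   DIF = PST − PRE; 2456 features in all.
4. **Screening** — two-sided Mann–Whitney U at p < 0.01, without
   multiple-testing correction (dimensionality reduction, not inference).
5. **Modeling** — nested double cross-validation: stratified 5-fold outer
   loop; inside each outer training split, screening, z-scoring, and a
   random grid search tuned by inner 10-fold mean AUC; nine classifiers
   (LR, LDA, SVM, KNN, NB, DT, RF, ET, lightGBM) over all 15 non-empty
   combinations of {RST, PRE, PST, DIF}. Fold ROC curves are averaged
   vertically on a 101-point FPR grid; the reported AUC is the mean of the
   fold AUCs ± their sample SD.
6. **Attribution and statistics** — permutation importance (held-out AUC
   drop, 10 repeats, averaged over outer folds), top-20 intersection across
   the best linear models; post hoc one-way ANCOVA of a feature on group
   with age as covariate (df = (1, n−3)); Spearman correlations against
   MADRS/STAI/MMSE within each group.

## Estimators

* **wPLI** over the time-sample distribution of the analytic cross-term
  `X_t = x̃_t · conj(ỹ_t)`: `|Σ_t Im X_t| / Σ_t |Im X_t|`, with the
  convention 0 when the denominator vanishes (implemented with a
  scale-relative tolerance, since zero-lag coupling leaves only float noise
  in the imaginary part). Band filtering for the Hilbert transform uses
  250 ms reflection padding that is discarded after the transform. The
  estimator is applied to single epochs (RST) and to the single
  epoch-averaged trace (PRE/PST): averaging across trials leaves a single
  trace, so the sample distribution is over time points within the window.
* **MI**: mean Hilbert amplitude of the fast band per phase bin of the slow
  band (18 bins), normalized to a distribution p, and
  `MI = (log N + Σ p_j log p_j)/log N`. Empty bins are merged into their
  neighbours (reducing the effective bin count) with a warning.
* **Band power**: mean Welch PSD over the bins inside [lo, hi] times the
  bandwidth, so that flat spectra give power proportional to bandwidth
  irrespective of the frequency-bin grid.
* **Mann–Whitney U**: exact enumeration when the pooled sample is ≤ 16 and
  tie-free, otherwise the normal approximation with tie and continuity
  corrections (vectorized across feature columns).
* **ANCOVA**: F test of the group term from nested OLS fits
  (`value ~ group + age` vs `value ~ age`).

## Synthetic cohorts and planted effects

No public recordings exist for this protocol, so the generator produces
two-group cohorts with known ground truth. Background is 1/f (power
spectral density ∝ 1/f, configurable exponent) at 10 µV rms plus 1 µV white
sensor noise, independent across channels, with an independent per-channel
alpha rhythm (3 µV) for realism. Oscillatory sources planted in resting
data are band-filtered Gaussian noise, not pure tones, so phase estimates
carry realistic variance. Clinical covariates are drawn from per-group
Gaussians clipped to instrument ranges (age 45.8±12.2 vs 40.5±12.2; MADRS
31.8±7.8 vs 1.1±2.0; STAI-trait 54.2±20.1 vs 32.1±9.2; STAI-state
55.4±20.1 vs 34.2±8.9; MMSE 29.1±1.4 vs 28.5±3.3).

Each planted effect specifies a feature name, a direction, a standardized
latent effect size d (default 1.2), and a mechanism. Every subject draws a
standard-normal latent per effect, shifted by ±d in the MDD group:

* **power_scale** (e.g. resting AFz β power, MDD higher): a band-limited
  oscillation at the electrode with log-normal amplitude
  `12 µV · exp(0.30 · latent)`, capped at 30 µV rms so extreme draws stay
  below the amplitude-rejection threshold. The oscillation is planted in a
  slightly narrowed core of the band so its filter skirts leak no
  measurable power into neighbouring bands. It dominates the background in
  its band, so the log-power separation approximately preserves d (the
  rank-based screen is invariant to the monotone power scale).
* **shared_source_lag**, resting (F6–F4 γ wPLI, MDD higher): a
  constant-power pair source (5 µV rms per electrode) whose *coherent
  fraction* — the share that is a common band-noise source with a 90° lag
  versus independent band noise — follows a logistic map of the latent
  (`logit = 0.5 + 0.6 · latent`). Grading the fraction rather than the
  amplitude keeps band power at the two electrodes uninformative about the
  group.
* **shared_source_lag**, DIF (three pre-to-post connectivity changes, MDD
  lower): pulse-locked tone bursts that survive additive averaging. One
  channel of the pair carries a tapered source tone; the other a mix of
  the 90°-lagged copy (weight = coherent fraction) with an in-band tone
  offset by a whole number of cycles per window and phased so its
  imaginary cross-term integrates to zero under the Tukey taper; the
  mixture is renormalized to unit rms so band power carries no trace of
  the fraction. Over the resulting transfer the window wPLI is close to
  linear in the fraction, so the effect is planted in fraction space: each
  subject draws a baseline fraction `0.25 ± 0.16` that drives the
  pre-window, and the post-window adds a change `0.12 + 0.13 · latent`
  (doubled for the θ band, whose 500 ms window supports fewer effective
  phase samples), clipped to [0.05, 0.95]. The baseline cancels in
  DIF = PST − PRE, so the group signal lives in the change while PRE and
  PST vary across subjects — without this, DIF and PST would be collinear
  and split the classifiers' permutation importance between them. A
  channel shared by several same-band effects carries one common source
  tone so the planted pairs do not contaminate each other.
* **pac_depth**: a high-band carrier with unit envelope is amplitude-
  modulated as `1 + depth · cos(phase)` of the low-band component.

Within the MDD group the β-power latent shares a severity variable with
the MADRS/STAI noise, with weights solved from the target rank correlations
(0.28 for MADRS, 0.36 for STAI) assuming ~15 % latent-to-feature
attenuation, so the planted clinical coupling is recoverable at roughly the
configured size.

Optional artifacts: blink-like 300 ms transients (~80 µV, frontal-polar
weighted) in resting data, and exponential TMS decay artifacts (120 µV,
τ = 100 ms, frontal-weighted) after each pulse. The decay amplitude sits
below the ±150 µV rejection threshold by design, so cleanup is the ICA
stage's job, as in real TMS-EEG practice.

What the generator does **not** emulate: volume conduction and realistic
mixing topographies, head geometry, eye/muscle artifact taxonomies beyond
the two above, non-stationarities such as drowsiness, or any biophysical
(neural-mass) dynamics. Passing tests therefore show that the pipeline
recovers effects of the stated kind and size under controlled conditions —
not that it would perform equally on clinical recordings.

## Numerical and design choices

* Filters are zero-phase (forward–backward) Butterworth; the band-pass
  upper edge is clipped to 0.45·fs with a warning when the sampling rate is
  too low to honour 100 Hz.
* Downsampling is polyphase with anti-alias filtering; recordings at or
  below the target rate pass through unchanged (no upsampling).
* ICA is FastICA with a fixed seed. Stage heuristics: first TMS stage —
  |correlation| of the epoch-averaged component with an exponential decay
  template (τ = 100 ms, 10–500 ms window) weighted by amplitude-weighted
  sign consistency (decay artifacts are one-signed; evoked oscillations
  cross zero), threshold 0.6; second/resting stage — frontal-polar
  topography dominance ≥ 2 combined with < 4 Hz power fraction ≥ 0.65
  (blinks), or a 48–52 Hz spectral peak ≥ 10× its neighbourhood (line
  noise). Flagged components above the remaining cap are truncated to the
  highest scoring. A decomposition is skipped with a warning when fewer
  than 20·n_channels² samples are available.
* Screening placement defaults to per-fold (leakage-safe); `global`
  placement reproduces whole-sample screening and is reported side by side.
  When fewer than two features pass in a fold, the two smallest-p features
  are used, logged.
* Hyperparameter grids are log-spaced (regularization, kernel widths,
  smoothing) or small-integer (tree depths, neighbours, leaves); a random
  draw that cannot be fit on a small inner split is discarded and redrawn
  from the sampled budget. Stochastic estimators receive seeds derived from
  the cross-validation seed; fixing the seed reproduces fold AUCs exactly.
* Vertical ROC averaging interpolates each fold's TPR onto a common
  101-point FPR grid with a (0, 0) anchor; the mean AUC is the arithmetic
  mean of fold AUCs (not the area under the averaged curve), and the SD is
  the sample SD across folds.
* Permutation importance is computed on outer test folds (generalizable
  reliance), 10 repeats; a feature not selected in a fold contributes 0 for
  that fold. The cross-model intersection uses top-20 lists.

## Problem sizes used in the test suite and acceptance script

Full-scale defaults (n = 60/60, 3 kHz, 300 s rest, 80 pulses, budget 25,
inner 10-fold) describe the experiment the package reproduces; simulation
studies that need many cohorts run at a reduced profile the package also
exposes: 500 Hz, 18 s rest (3 epochs), 10 pulses, with tuning budget 6 and
inner 3-fold where cross-validation is repeated many times. The planted
effects remain recoverable at this scale (that is what the recovery tests
check); the reduced sizes only enlarge estimator variance. ICA is skipped
in those simulation studies because the cohorts are generated without
artifacts; the ICA stages are exercised separately on recordings with
injected decay artifacts.

## Known limitations

* The wPLI of an epoch-averaged trace over a 500 ms window rests on few
  effective phase samples; mid-range values are intrinsically noisy. The
  generator works around this (see above), but on real data PRE/PST wPLI
  features should be treated as coarse.
* Whole-sample (`global`) screening leaks test-fold information into the
  candidate set; the leakage-canary test demonstrates the effect. Reported
  AUCs under global placement are optimistic and should be compared with
  per-fold placement.
* The blink/line-noise ICA heuristics are deliberately conservative; they
  are tuned to produce no false removals on clean synthetic data rather
  than to maximize sensitivity on real recordings.
* ANCOVA assumes a common age slope in both groups; no interaction term is
  fitted.
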