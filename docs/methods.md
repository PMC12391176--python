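# Methods

This note documents the models, parameter choices, and known limitations of
the pipeline, in the order data flows through it.

## Synthetic cohort

The generator emulates a pinprick-SEP study in acute/subacute stroke at the
level of the measured signals, not the biophysics: there is no head model,
and no ocular or muscle artifact model.

**Protocol.** Ten sets of 8 stimuli (one per skin compartment of the hand
dorsum, random order within a set) per hand, hands alternating set by set,
the whole block run twice: 160 stimuli per hand. Stimulus onsets are snapped
to the 256 Hz sample grid. The inter-stimulus interval is not part of the
study record; we use 3.0 ± 0.5 s (uniform jitter), long enough that the
−1.5…2.2 s analysis epochs of adjacent stimuli do not overlap in time
(though wavelet smearing still couples them at the lowest frequencies — see
*Limitations*).

**Background EEG.** Per participant, channels are Gaussian noise with a
1/f^α power spectrum (α = 1 by default), scaled to 10 µV RMS, with a shared
1/f source giving inter-channel correlation ≈ 0.5 (volume conduction;
the bad-channel screen's neighbor-correlation criterion relies on it).
Participants are statistically independent; all randomness derives from the
cohort seed through named per-participant substreams, so any single
participant can be regenerated in isolation.

**Evoked response.** A biphasic template (negative Gaussian lobe peaking at
60% of the positive latency, then a positive lobe) is numerically rescaled
and shifted so that its noise-free negative-to-positive excursion and
positive-peak time match the subject's parameters exactly on a 32×
oversampled grid, then added at the contralateral central electrode for
every stimulus. Group distributions of amplitude and latency are the
canonical healthy / motor / sensorimotor values (2.81 ± 1.30 µV @
202.69 ± 70.62 ms; 3.22 ± 2.68 @ 169.09 ± 76.05; 1.36 ± 0.54 @
161.46 ± 66.63), with amplitude floored at 0.3 µV and latency clipped to
120–400 ms so every injected SEP stays measurable inside the peak-search
windows.

**Event-related (de)synchronizations.** Five phenomena are injected as
multiplicative gains on band-limited components of the background:
the channel receives (g − 1)·envelope(t)·bandpass(x), so that at the
envelope peak the band amplitude is scaled by g (20·log10 g in dB power).
Two distinctions matter:

- *Modulated band vs measured window.* The gain acts on the physiological
  rhythm band (delta 1–3.5 Hz, theta 4.2–6, mu/alpha 7–12.5, high-beta
  16–26, low-beta rebound 12.5–16.5); the canonical ROI windows
  (delta 1–4 Hz 0–543 ms, theta 4–6 Hz 0–262 ms, alpha 5–13 Hz 47–785 ms,
  beta1 13–27 Hz 70–566 ms, beta2 11–17 Hz 820–1601 ms) are what the
  10-cycle wavelet decomposition *measures* after spectral/temporal
  smearing, and are the recovery targets. Driving the literal window bands
  instead makes alpha and beta1 — which share the 13 Hz edge and overlap in
  time — a single desynchronization whose spectral profile peaks exactly at
  the boundary, which no labeling rule can honestly split.
- *Envelope.* A Tukey (α = 0.5) time course over the window: full depth over
  the central half, raised-cosine waxing/waning over the outer quarters.
  Modulations that switch on and off as rectangles are neither
  physiological nor recoverable with bounded extents.

Group mean modulation depths are 0.4–1.8 dB in magnitude (healthy alpha
−1.8 dB, sensorimotor alpha −0.9 dB, etc.), with 0.75 dB between-subject SD —
the scale of the per-feature power distributions such studies report
(individual values spanning roughly −2…+2 dB). Much larger depths make the
spectral-leakage halos around each effect statistically significant
everywhere and are not representative.

**Clinical scores.** Linear in the injected per-subject magnitudes
(amplitude in µV, the five modulation depths in dB) plus Gaussian noise,
clipped to instrument ranges (FMA 0–66, EmNSA exteroception 0–32, PTT in
mA): FMA depends on beta1 (coefficient −19, noise SD 15), EmNSA on beta2 and
a delta × stroke-type interaction, PTT on an amplitude × stroke-type
interaction; T2 = T1 + a generated change (FMA change on beta2, EmNSA change
on amplitude × type, PTT change on type only). Healthy participants have no
clinical scores. These defaults give the statistical stage recoverable
targets with the directions the pipeline is designed to detect.

## Preprocessing

Zero-phase band-pass: an 845-tap Hamming windowed-sinc FIR (1 Hz transition
at the low edge), applied forward–backward — implemented as a single
convolution with the filter's autocorrelation, which is mathematically
identical for a linear-phase FIR and halves the cost. Stop-band attenuation
after the double pass exceeds 40 dB at DC and at 64 Hz.

Channel screening replaces proprietary cleaning tools with two documented
criteria: robust log-variance z-score (median/MAD, MAD floored at 0.1
log-units, threshold 3.5) and best-neighbor correlation (minimum 0.4). Bad
channels are dropped, not interpolated; the common average is computed over
retained channels only. Segment rejection marks 1 s sliding windows
(0.25 s step) whose peak-to-peak exceeds 200 µV on any channel, excises the
merged spans, drops events whose full −1.5…2.2 s epoch touches a span, and
re-indexes the rest; retained samples are bit-identical. An explicit no-op
hook marks where an ICA stage could be inserted; the synthetic data contain
no artifact components, so its absence changes nothing testable here.

## Time–frequency decomposition

Morlet family: 30 log-spaced frequencies f_k = 35^(k/29), k = 0…29, fixed
width σ_t(f) = 10/(2πf) s (10 cycles), kernels truncated at ±5σ_t and scaled
to unit energy. The amplitude normalization is irrelevant downstream — the
dB baseline ratio cancels any per-frequency factor — and is fixed only for
bit-reproducibility. The implementation cross-checks against an independent
Morlet TFR implementation (same 10-cycle width) to 0.02 dB.

Power is computed by convolving the *continuous* cleaned channel once per
frequency and epoching |·|² afterwards. This equals epoch-wise convolution
with the epoch padded by the true neighboring signal, and therefore has no
artificial within-epoch edge effects; the epoch-wise operation (with
per-frequency edge-contamination counts in its metadata) is retained for
epoch-only inputs. Normalization is trial-average-then-dB; per-trial
normalization is available but off by default.

Condition assignment: stroke participants contribute the ipsilesional
central channel during impaired-hand stimulation; healthy participants the
channel contralateral to each stimulated hand, with the two hand conditions
averaged per participant before cohort-level masking.

## Bootstrap mask and ROIs

The mask tests each analysis-window bin (0–1.6 s) against the pre-stimulus
baseline across participants (one-sample t of dB minus the participant's
per-frequency baseline mean, df = n−1), with a per-bin null from 2000
circular shifts of the maps over time and frequency, and includes bins whose
|t| reaches the 95th percentile of their own null (a switch restores the
literal one-sided rule on signed t).

**Why shifts are drawn per participant.** If one common (Δf, Δt) is applied
to every participant, the t-map commutes with the relabeling: the "null"
t-map is exactly the observed t-map rotated, each bin's null distribution is
the map's own t-values, and the procedure reduces to selecting the top 5% of
|t| bins — it can never include an extended effect in full, no matter how
strong. Drawing an independent shift per participant per iteration destroys
the event alignment across participants while preserving each map's marginal
structure, giving a genuine null. The shared-shift variant is kept as a
config option because it admits exhaustive enumeration of all F × T shifts,
against which the engine is verified bin-for-bin on toy grids.

**ROI labeling.** Mask bins are stratified by t sign (a synchronization and
a desynchronization are different phenomena even when their bins touch),
restricted to bins whose grand-average |dB| ≥ 0.25 (with ~160 trials the
t-test resolves offsets of ~0.2 dB, so a bare mask also captures
physiologically meaningless leakage halos), and grouped by 4-neighbor
connectivity. A component whose row-marginal mean |t| profile dips below 0.7
of the smaller flanking peak is cut at the trough (recursively): adjacent
band-limited phenomena otherwise fuse through spectral smearing. Components
smaller than 10 bins are dropped. Each ROI reports its frequency/time
bounds, sign, and a band label from its |t|-weighted centroid frequency.
ROI power is the plain mean of the participant's dB map over the ROI's
member bins.

## Statistics

- One-way ANOVA of SEP amplitude on group; Tukey-corrected pairwise
  contrasts are computed on request regardless of the omnibus p (the
  analysis is exploratory); Cohen's d uses the (n−1)-weighted pooled SD of
  the two contrasted cells.
- Mixed model POWER ~ GROUP × FEATURE with a participant random intercept
  (REML); a singular random-intercept fit falls back to ordinary regression
  with a prominent warning. Term tests are Wald F with residual denominator
  df (n_obs − number of fixed-effect columns) — a simple approximation,
  named in every output.
- Clinical models: ordinary regression of the T1 score or T2−T1 change on
  amplitude, the five ROI powers, stroke type, and each feature × type
  interaction, in the stroke subset.
- Backward-stepwise reduction: drop the highest-p eliminable term with
  p ≥ 0.05, where a term is eliminable only while no retained interaction
  contains it; ties break by dropping the later term in the fixed ordering,
  so selection is deterministic given a table. Note the structural
  consequence: with k inactive candidate terms the final model is free of
  false inclusions only with probability ≈ 0.95^k (≈ 0.54 at k = 12), so
  "exact" model recovery cannot exceed that, while retention of true terms
  reaches 100% at moderate effect sizes. Outlier handling, where requested,
  is a documented residual rule (drop |z| > 3 on model residuals).

## Numerical conventions

0-based sample indexing; half-open sample windows [start, end); times in
seconds internally, milliseconds in reports; signals in µV. Epoch windows:
time-domain −0.5…1.5 s (baseline −0.5…0), time–frequency −1.5…2.2 s
(dB baseline −0.4…−0.1 s, analysis 0–1.6 s). Peak search: negative peak in
50–250 ms, positive peak in (t_neg, 500 ms] — config-exposed, bracketing the
canonical latencies. EDF files are written by a minimal 16-bit writer (one
1 s record per second, final record zero-padded, per-channel symmetric
physical range) and read back through a standard EDF reader, which doubles
as a round-trip check.

## What passing tests do and do not show

The synthetic cohort has Gaussian, stationary backgrounds, identical
spectral shape across participants, no artifacts, and exactly linear
clinical links. Passing tests therefore demonstrate the *pipeline's*
correctness and statistical calibration, not robustness to real-world EEG
nonstationarity, artifacts, or nonlinear clinical relationships.

Known structural limitations, measured and deliberate:

- At 1–2 Hz the 10-cycle wavelet integrates ~3 s of signal, so a 543 ms
  delta modulation is diluted below detectability there, and the delta ROI
  can never span the full 1–4 Hz window with bounded time extent.
- The dB baseline (−0.4…−0.1 s) lies inside the backward temporal smear of
  the delta response; the inflated baseline produces a genuine negative
  late-epoch mirror region at 2–3 Hz of magnitude comparable to the
  synchronization itself, which the mask correctly reports as an extra ROI.
- The printed theta window is frequency-adjacent to delta and overlapped by
  the printed alpha window; theta frequently merges with delta into one
  low-frequency synchronization.

Consequently a typical default cohort yields 5–6 ROIs covering all five
phenomena with correct signs, with window-overlap Jaccard ≈ 0.5–0.8 for
alpha/beta1/beta2 but ≈ 0.2–0.4 for delta/theta. The problem sizes used in
the test suite and acceptance script (26-participant cohorts, 500-iteration
nulls for Monte-Carlo calibration runs, n = 50 regression cohorts) were
chosen to keep full runs to a few minutes while leaving Monte-Carlo error
well below the tolerances tested.
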