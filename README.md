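# pinprick-tfr

EEG analysis of pinprick somatosensory evoked potentials (SEPs) for stroke
research: time-domain peak measurement, Morlet time–frequency decomposition,
a circular-shift bootstrap mask that discovers event-related
(de)synchronization regions of interest, and the group-level and clinical
association models built on the extracted features. Because clinical
recordings of this kind are rarely shareable, the package ships a synthetic
cohort generator that emulates the full study — 26 participants
(10 healthy, 6 motor stroke, 10 sensorimotor stroke), 160 pinprick stimuli
per hand at 256 Hz, biphasic evoked responses, five band-power modulations,
and clinical scores driven by the injected EEG effects — so every stage is
testable against known ground truth.

It is aimed at clinical neurophysiologists and methods developers who want a
tested, reproducible implementation of this analysis chain, either to run on
their own EDF recordings (stage by stage via the CLI) or to study the
behavior of the masking procedure itself.

## The analysis

1. **Preprocessing** — 1–35 Hz zero-phase (forward–backward) FIR band-pass;
   removal of channels with outlying robust log-variance or no correlated
   neighbor; common-average reference over retained channels; excision of
   data spans exceeding 200 µV peak-to-peak with event re-indexing.
2. **Time domain** — epochs −0.5…1.5 s around each pinprick, baseline
   −0.5…0 s, averaged per hand; the SEP is summarized by its
   negative–positive peak-to-peak amplitude and positive-peak latency at C3
   or C4 (ipsilesional for stroke, contralateral to the stimulated dominant
   hand for controls).
3. **Time–frequency** — convolution with complex Morlet wavelets
   w(t) = exp(i2πft)·exp(−t²/(2σ_t²)), σ_t = 10/(2πf), at 30 log-spaced
   frequencies f_k = 35^(k/29) from 1 to 35 Hz; power = |convolution|²,
   trial-averaged, then dB-normalized against the frequency-specific mean
   power in −0.4…−0.1 s: dB(f,t) = 10·log10(P(f,t)/P̄_baseline(f)).
4. **Bootstrap mask** — per (f,t) bin in 0–1.6 s, a one-sample t across
   participants of dB minus each participant's baseline mean; a null built
   from 2000 circular shifts of the maps over time and frequency; a bin
   enters the mask when |t| reaches the 95th percentile of its own null.
   Connected components become ROIs (with sign stratification, an
   effect-size floor, and a band-trough split rule; see
   [docs/methods.md](docs/methods.md)).
5. **Statistics** — one-way ANOVA of amplitude on group with Tukey
   post-hocs and Cohen's d; a linear mixed model POWER ~ GROUP × FEATURE
   with participant random intercept; and backward-stepwise regressions of
   FMA / EmNSA / PTT (at T1 and as T2−T1 change) on the EEG features,
   stroke type, and their interactions.

## Worked example

The numbered drivers under `analysis/` run the whole study on one synthetic
cohort (seed 1; set `PINPRICK_SEED` to change it) and write their tables
under `results/`:

```sh
cd analysis
python 01_simulate_cohort.py       # ground truth + clinical tables
python 02_preprocess_and_sep.py    # cleaning, SEP peaks, ANOVA (caches TFRs)
python 03_bootstrap_mask_rois.py   # 2000-iteration mask + ROI table + figure
python 04_roi_power_statistics.py  # ROI power, mixed model
python 05_clinical_models.py       # stepwise clinical regressions
```

Step 02 prints the group comparison of measured SEP amplitudes:

```
measured SEP amplitude (uV) by group:
              mean   std
healthy       2.62  1.13
motor         3.58  1.54
sensorimotor  1.53  0.59

[anova] np_amplitude ~ C(group)
  C(group): F = 7.054, p = 0.0041
  post-hoc contrasts:
    healthy vs sensorimotor: diff = -1.086, p_adj = 0.0818, d = -1.206
    motor vs sensorimotor: diff = -2.042, p_adj = 0.0034, d = -1.969
```

— the sensorimotor group's attenuated SEP (injected mean 1.36 µV vs 2.81 µV
in controls) is recovered through the full chain. Step 03 reports each
discovered ROI with its overlap against the canonical injected windows,
e.g. on this cohort the beta-band resynchronization (11.6–16.8 Hz,
863–1570 ms) matches its injected window with Jaccard 0.80 and the alpha
desynchronization with 0.53, while the delta/theta synchronizations merge
into one low-frequency region (Jaccard 0.27) — the methods note discusses
why the lowest bands are structurally hard to bound with 10-cycle wavelets.

To run the same stages on files instead (EDF + events TSV per participant),
use the CLI: `pinprick-tfr simulate|preprocess|erp|tfr|mask|features|stats|run`,
e.g. `pinprick-tfr run --seed 1 --out results/pipeline`.

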