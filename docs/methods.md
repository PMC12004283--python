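# Methods

This note documents the models, conventions and numerical choices behind
`hrvaffect`, and what the synthetic validation does and does not establish
about real recordings.

## The synthetic cohort generator

The generator emulates the block-design affective session: one 60-s
baseline, twelve 55-s videos (six per condition, seeded uniform shuffle),
each followed by a 55-s rest. An optional flag inserts an extra 55-s
rest-labelled gap after each video to mimic a self-report interlude in a
healthy-subject variant of the timeline; its content is out of scope and
the normalization always references the event labelled `rest`.

**Beat model.** Beats arise by integrate-and-fire over the instantaneous
rate `1/m(t)` with heart period (ms)

```
m(t) = m0 + A_LF sin(2π f_LF t) + A_HF sin(2π f_HF t) + δ(condition at t) + ε
```

The deterministic rate is integrated on a 10-ms grid (cumulative
trapezoid); a beat fires at each unit crossing, after which per-beat
Gaussian noise ε (SD `sigma`) is added to the intervals and beat times are
rebuilt cumulatively, with draws truncated so intervals stay positive. The
condition shift δ applies only inside stimulus windows (no carry-over),
matching the rest-referenced normalization downstream. This is *not* a
physiological simulator (no IPFM spectral calibration, no respiratory
coupling, no morphology pathology); it exists to embed band-limited
variability and known mean-RR shifts that the pipeline must recover.

**Defaults.** `m0 = 850 ms`, `A_LF = 20 ms` at `f_LF = 0.1 Hz`,
`A_HF = 25 ms` at `f_HF = 0.25 Hz`, `sigma = 10 ms`,
`δ(acquaintance) = +25 ms`, `δ(stranger) = 0`. These are fixture
conventions chosen to be physiologically plausible for an adult at rest
(~70 bpm, modest autonomic modulation, a small bradycardic orienting-type
response); no quantitative group-level physiology was available to
calibrate them, so the patient groups are modelled simply by scaling δ
(default 0 — "no response"). The default cohort is 17 HC, 5 MCS, 6 UWS.

**ECG synthesis.** A P-QRS-T template (sum of five Gaussians, R amplitude
1 mV) is placed at each beat time; contamination is additive sinusoidal
baseline wander (default 0.1 mV at 0.25 Hz), 50 Hz mains (0.05 mV) and
white noise (SD 0.05 mV — 5% of R amplitude, the "moderate noise" level of
the validation experiments).

**Ectopic injection** displaces selected non-adjacent interior beats to
0.6× the preceding interval, leaving the next beat untouched (compensatory
pause). Beat count is preserved, which keeps the <20% ectopic fraction
well-defined, and displaced beats carry a ground-truth annotation.

## Preprocessing

Resampling (polyphase, rational approximation of the rate ratio) to
256 Hz; 5th-order Butterworth high-pass at 0.5 Hz; IIR notch at 50 Hz with
Q = 30 (narrow enough to spare QRS energy). Filters run forward-backward
by default: zero phase preserves R-peak timing, the quantity of interest
(single-pass available via `zero_phase=False`).

**Pan–Tompkins detection**: 5–15 Hz band-pass, five-point derivative
(group delay compensated), squaring, 150-ms centered moving-window
integration; candidate peaks at ≥200 ms spacing are classified against
adaptive dual thresholds (signal/noise running estimates, 1/8 update
gain), with search-back at 1.66× the running R-R estimate; accepted
fiducials are refined to the local maximum of the band-passed ECG within
±50 ms. The refinement is a deterministic stand-in for visual inspection.
Records shorter than 5 s, or yielding fewer than 3 beats, are rejected.

**Ectopic correction**: interval *i* is flagged when it deviates from the
median of its `k = 5` preceding (unflagged) and following neighbours by
more than `tol = 0.2` of that median, or falls outside a 200–3000 ms
plausibility gate. A run of flagged intervals implicates the beats strictly
between its anchor (unflagged) beats; if the flagged-beat fraction reaches
`max_fraction = 0.20` the series raises an uncorrectable-series error —
the rule under which excessively noisy subjects are excluded. Otherwise
flagged intervals are replaced by a cubic spline over beat index fitted to
unflagged intervals, rescaled within each run so anchor beat times are
preserved exactly: only flagged beats move, unflagged times are
bit-identical, and beat count never changes. A single isolated aberrant
interval between two anchors cannot be corrected without inserting a beat;
it is annotated but left in place. The local-median rule is an automated,
reproducible surrogate for the manual editing common in practice; both
`tol` and `k` are configurable.

## Features

Ten time-domain measures on each window's R-R series (ms): mean, median,
MAD (×1.4826 normal-consistency by convention of common HRV tooling; raw
MAD via flag), sample SD (n−1), RMSSD, SDSD (n−1), 80th/20th percentiles
(linear interpolation), pNN20/pNN50 as the percentage of |successive
differences| strictly greater than 20/50 ms. pNN50 is sometimes printed
with a "<" in feature tables; the universal ">" definition is used.

Frequency domain: the tachogram (interval vs terminating-beat time) is
cubic-interpolated to a uniform 4 Hz grid, mean-removed, and a Welch PSD
with a single full-window Hann segment (no averaging is possible at 55 s;
segmenting is configurable for longer windows) is integrated over
0.15–0.4 Hz to give HF; HFn = HF / power(0.04–0.4 Hz), the dominant
normalization convention. Because 55 s is about half the duration
recommended for resolving the low-frequency band, every sub-120-s window
carries a low-reliability flag on the spectral features rather than a
changed formula; zero-variance windows return HF = HFn = 0 with a
degenerate flag.

Intervals are assigned to the window containing their terminating beat,
half-open `[start, end)`, so each interval belongs to exactly one
contiguous window. Windows with fewer than 4 intervals are explicit
invalid markers, never silent zeros.

## Normalization

Per stimulation window and feature: `(stimulus − preceding rest) / MAD`,
the preceding rest being the rest (or the baseline, for the first video)
immediately before the stimulus in protocol order. The subject MAD is the
raw MAD over the feature's values in *all* of the subject's windows —
per-condition MADs would leak condition information into the scale, and a
normalization denominator does not need the 1.4826 consistency constant
(both choices configurable; whether real analyses scale by the MAD of raw
window values or of stim−rest differences is ambiguous, so the choice is
explicit and switchable). A zero MAD is floored at 1e-9 with a degenerate
flag; subjects with fewer than 3 valid windows are excluded per feature.
Missing windows propagate as exclusions with reason codes, never as
imputations.

## Statistics

The sampling unit defaults to normalized window-level values pooled across
a group's subjects (17 HC × 6 videos = 102 values per condition), which is
the unit consistent with effect sizes reported as `r = |Z|/√N` at
window-level N in comparable analyses; per-subject condition means are
available via `unit="subject"`. Within-group condition contrasts use the
Wilcoxon signed-rank test with windows paired by protocol position within
subject; between-group contrasts use the rank-sum test on independent
pooled samples.

Both tests report a Z from the tie-corrected normal approximation (zeros
dropped, mid-ranks, no continuity correction), signed by the direction of
the median difference. Exact p-values replace the approximation in small
samples: the signed-rank null is enumerated by convolution over doubled
mid-ranks for up to 25 informative pairs (exact even with ties), and the
rank-sum exact distribution is used for tie-free samples of combined size
≤ 30. Bonferroni correction multiplies each raw p by the family size —
the 12 features within one contrast (configurable) — and significance is
declared at corrected p < 0.05. The Shapiro–Wilk screen is advisory: the
pipeline always proceeds nonparametrically. The demographics comparison is
a pooled-variance independent t-test with descriptives under both SD
conventions.

## Validation experiments and their limits

`hrvaffect.experiments` (reused by `scripts/acceptance.py`) measures, on
synthetic ground truth: detector sensitivity/PPV at 50–120 bpm under
moderate noise (±10 ms matching); ectopic flag recall and post-correction
interval error at correctable fractions, plus rejection at 25%; empirical
type-I error of both Wilcoxon variants and the Bonferroni family-wise
error over 1000 null replicates (n = 30); and end-to-end recovery of the
embedded +25 ms HC-only effect over 100 seeded cohort replicates (success
= significant HC MeanNN and MedianNN contrasts and no significant
patient-group condition contrast). Replicates run at beat level rather
than waveform level to keep the experiment a few minutes long; waveform
→ detection fidelity is established separately by the detector and
end-to-end window-mean tests.

Passing these experiments shows the chain is internally correct and
well-calibrated under the generator's assumptions. It does **not** show
that real ECG from wheelchair-bound, frequently moving patients behaves
this way: real recordings have nonstationary noise, respiration-coupled
variability, medication effects and morphology changes that the generator
deliberately omits. Printed group medians and Z values from any particular
study depend on its recordings and are not reproducible from synthetic
data; only the qualitative pattern (HC condition effect present, patient
effect absent, group differences detectable) is.

## Known limitations

* Single-lead analysis only; no arrhythmia classification or P/T-wave
  delineation.
* The ectopic corrector cannot fix isolated missed beats (single long
  intervals between valid anchors) without beat insertion.
* LF-band and derived measures (nuLF, LF/HF) are intentionally absent:
  55-s windows cannot estimate them reliably.
* The exact rank-sum path requires tie-free samples; heavily tied small
  samples fall back to the tie-corrected normal approximation.
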