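# Methods

This note documents the models, numerical conventions and design choices
behind `therasig`, in the spirit of a package reference manual: what each
stage assumes, which constants matter, and what the synthetic validation
does and does not demonstrate.

## Session model

A session is three ordered, non-overlapping, half-open time intervals
[start, end) labelled PRE, MTI, POST, read from explicit annotations
(case-insensitive, remappable via a label map; missing labels are an
error, never inferred). Time is in seconds; sample indices are 0-based
with both interval edges floored (`[floor(start·fs), floor(end·fs))`), so
epoch counts are unambiguous. Analysis uses a *central window* per period
— 5, 15 and 5 minutes for PRE, MTI, POST — trimmed symmetrically with any
sub-sample remainder assigned to the right edge; periods shorter than
their target are used in their entirety. The same use-entire-period rule
applies to all three periods, including MTI (session schedules in an ICU
are dynamic and all periods can run short).

## Filtering and artifact handling

All analysis filters are 4th-order Butterworth applied forward–backward
(zero phase, effective 8th order): 1–30 Hz for EEG, 1–40 Hz for ECG,
20–200 Hz for EMG (content below 20 Hz is motion/blink artifact on facial
leads). Reflect padding of about three time constants of the low cutoff
precedes the forward–backward pass so filter transients never reach the
analysed windows. The EMG path adds zero-phase notches at 60 Hz and its
harmonics up to the band edge (Q chosen for a ≈1 Hz single-pass −3 dB
width; >30 dB rejection at the line frequency).

Artifact handling replaces interactive visual inspection with a
deterministic robust-amplitude screen: 1-s windows whose peak absolute
amplitude exceeds median + 5·1.4826·MAD of the channel's per-window peaks
are marked bad; epochs overlapping a bad span are dropped, sample values
are never altered. A user-supplied annotations table can override the
automatic mask.

Ocular activity is removed by linear ICA: the EEG is decomposed into as
many components as its effective rank (FastICA, fixed seed; the unmixing
matrix is estimated on a ~20 000-sample decimated copy and applied to the
full recording — it is a property of the mixing, not of every sample).
Each component is scored by the *minimum* of its absolute correlations
with the two frontal blink proxies (Fp1 and Fp2, low-passed at 4 Hz). A
genuine blink loads on both frontal channels; a component carrying a
single channel's background delta correlates with only one, which is why
the two-proxy minimum separates the blink-free null far more cleanly than
a single mean-frontal proxy (whose null correlation sits near 0.46, on
top of the 0.5 decision threshold). At most one component — the top
scorer, if it reaches 0.5 — is zeroed; otherwise nothing is removed and
the decision is logged. Data that already had a component projected out
is decomposed at its reduced rank rather than refused, so a second pass
is a no-op.

## EEG band power

Per 3-s epoch (1.5-s overlap) and channel, Welch PSD with Hann-windowed
1.5-s segments, 50 % overlap, mean averaging, density scaling — ≥2
averages per epoch at ~0.67 Hz resolution. Band power integrates the
density over Delta 1–4, Theta 4–8, Alpha 8–12, SlowBeta 12–18, FastBeta
18–30 Hz using Simpson's rule implemented as differences of the
*cumulative* Simpson integral. This makes band powers exactly additive
over the partition (summing naive per-band composite Simpson values is
not additive when a band spans an odd number of grid intervals) while
retaining Simpson's polynomial exactness; a flat density over a 4-Hz band
integrates to exactly 4× its level. One known property of Simpson on
peaked spectra: a pure sinusoid's 3-grid-point Hann peak is overestimated
by up to 1/9 by the quadratic interpolation through the flanking pairs;
the trapezoidal integral of the same density satisfies Parseval exactly,
and for broadband signals the two agree.

z-scoring uses the PRE epochs' sample mean and sample SD (n−1 denominator)
per channel × band; PRE z-scores therefore have mean 0, SD 1 by
construction, and z is invariant to per-channel gain. The per-recording
value entering group statistics is the period mean z (one number per
recording per cell); both recordings of a patient are treated as
independent units, with per-patient averaging available as an option.
Epochs are formed inside period windows, so no epoch straddles a period
boundary. Group contrasts (MTI−PRE, POST−PRE) report the mean and
population SD of per-recording differences, the unpaired permutation p,
and BH-adjusted p across the 8 electrodes within each band.

Spectral leakage caveat: Hann main-lobe smear (~±1.3 Hz at 1.5-s
segments) moves a small, *systematic* fraction of a strong band-limited
effect across the shared band edge. A doubled alpha power at one channel
is therefore accompanied by a small (z ≈ 0.3) but consistent apparent
increase in the adjacent 12–18 Hz band at that channel, which a
consistent-effect test will flag at any cohort size. Effect uniqueness is
accordingly a within-band (FDR-family) statement, not a dataset-wide one.

## Heart-rate variability

R peaks: squared-derivative energy smoothed over 80 ms; an initial
percentile threshold is refined from the detected peak population
(0.25 × median peak energy); 250-ms refractory period; the R time is the
absolute-amplitude maximum within ±60 ms of the energy peak. Flat
(disconnected-lead) stretches carry no derivative energy and yield no
detections. The detector assumes its input is the 1–40 Hz filtered ECG.

R-R cleaning: intervals outside 300–1500 ms are invalid; each invalid run
is replaced by linear interpolation between flanking valid values
(nearest-valid at the edges), preserving the interval count; >20 %
invalid (configurable) raises a quality error. The operation is
idempotent. Cubic splines are reserved for the 4-Hz resampling, where
they are part of the spectral method.

Time domain: meanRR, STDRR (sample SD, n−1), and pRR50 — the percentage
of *successive* R-R differences strictly exceeding 50 ms (the standard
pNN50-style reading).

Poincaré: R-R values are z-scored against the same session's PRE window
mean/SD (per-patient pooling is a config option); (zₙ, zₙ₊₁) pairs form
the cloud. SD1 is the RMS perpendicular distance to the identity line,
|zₙ−zₙ₊₁|/√2 — algebraically identical to RMSSD/√2 of the z-series, which
the tests verify to 1e-9 — and SD2 the population SD of the projection
(zₙ+zₙ₊₁)/√2 along the line.

Frequency domain: each R-R value is anchored at its terminating peak;
cubic-spline resampling to 4 Hz over the period window; mean removal;
Welch with Hann window, segment length min(T, 256 s), 50 % overlap
(resolves 0.04 Hz whenever T ≥ 5 min). The density is normalized by total
0–2 Hz power; LF integrates [f_low, 0.15] Hz and HF [0.15, 0.4] Hz
(cumulative-Simpson differences), reported as percentages of total power;
LF/HF is the ratio of the unscaled integrals. The adaptive cutoff
f_low = max(0.04, 12/T) uses the *requested* window length, so a nominal
240-s window gives exactly 0.05 Hz; windows under 60 s are refused, and
f_low ≥ 0.15 Hz makes LF undefined (error).

## Facial EMG

Per 2-s epoch (1-s overlap): RMS amplitude, z-scored to PRE with the same
convention as EEG. Spectral analysis requires fs ≥ 512 Hz (Nyquist for
the 200 Hz band edge); per-epoch Welch uses Hann 1-s segments with 50 %
overlap (1 Hz resolution, ≥3 averages). The period MNF is computed from
the *mean-then-normalized* PSD (epoch PSDs averaged, divided by total
20–200 Hz power) as the discrete spectral centroid Σf·P/ΣP over the
20–200 Hz grid; the equivalent ratio of Simpson integrals of f·P and P is
computed as an internal cross-check and must agree within 0.1 Hz. The
per-epoch-MNF-then-average alternative agrees for stationary signals and
is not separately exposed.

## Permutation inference

The two-sample statistic is the difference of means. When the number of
distinct label splits C(n+m, n) is at most the permutation budget
(default 1600), the test enumerates all splits and returns the exact
proportion with |T*| ≥ |T_obs| (ties compared with a 1e-12 slack so
float round-off cannot break exact ties). Otherwise it samples
permutations and returns the +1-corrected estimate
(1 + #extreme)/(1 + n_perm), which is never 0 and keeps the test valid.
Per-comparison seeds derive from a hash of (global seed, feature, pair),
so p-values are independent of execution order. The unpaired test is the
default even though periods are within-subject (matching the design of
comparing period means across all patients and recordings); a paired
sign-flip variant is a natural extension but is not the default. BH-FDR
is the standard step-up (sort, qᵢ = pᵢ·m/i, running minimum from the top,
cap at 1, original order restored); note the step-up map is *not*
idempotent — re-adjusting adjusted values inflates them again — so
adjusted p-values are terminal outputs, never re-fed.

Per-recording period means are the exchangeable units entering every
group test; pooling epochs across recordings would fabricate sample size
and is deliberately not the default.

## Clinical scores

One row per patient-session: VAS pre/post per session, HADS
anxiety/depression at first/last timepoint per patient (duplicated across
a patient's session rows; the last timepoint may be missing and such
patients are excluded from HADS change summaries, with the count
reported). VAS summaries treat each recorded session as one unit; a
per-patient-mean variant is a one-liner on the same table and both views
are legitimate for this design. Summary SDs use the population (N)
denominator, which is the convention the bundled cohort table's printed
SDs follow; displayed rounding is 1–3 decimals, stored values full
precision. MCID thresholds (1.4 VAS points, 1.7 HADS points per scale)
live in a config mapping, not in logic.

## Synthetic sessions

The generator produces, per period, signals whose analysis-level
parameters are known exactly:

- **EEG** — per channel, a sum over the five bands of band-limited
  Gaussian noise built by frequency-domain shaping (white noise, rFFT,
  zero outside the band, rescale, inverse), so the within-band variance
  equals multiplier(period) × the PRE base power *exactly* per
  realization. Default base powers follow a rough resting 1/f profile
  (Delta 30, Theta 15, Alpha 15, SlowBeta 8, FastBeta 5 µV²). Optional
  blink transients are biphasic ~2.5 Hz pulses, full-size frontally with
  a posterior falloff.
- **ECG** — RRₙ = meanRR + a_LF·sin(2πf_LF tₙ) + a_HF·sin(2πf_HF tₙ) + εₙ
  with ε truncated Gaussian (±3 SD) and a profile-level guard keeping RR
  inside 300–1500 ms; a Mexican-hat QRS template (80 ms, 1 mV) is placed
  at each cumulative peak time over additive white noise. Ground-truth
  peak times are returned and written as sidecar JSON for detector
  validation.
- **EMG** — Gaussian noise shaped so its PSD follows a Gaussian envelope
  (SD 30 Hz, truncated to 20–200 Hz) centred on the period's target
  centroid (truncation shifts the true centroid by ≤0.3 Hz for central
  targets), rescaled to the period's exact RMS.
- **Clinical table** — integer VAS/HADS draws with configurable mean
  shifts, clipped to range with a warning, a configurable
  missing-last-HADS fraction and single-session patients.

The default *study-shaped* dataset has 9 patients, one with a single
session (17 sessions), one session without ECG, two without an EMG
channel, and one sampled at 256 Hz (EMG-ineligible) — 17/16/14 analysable
sessions per modality. Default effect profiles encode the qualitative
intervention pattern (MTI-only occipital alpha increase and frontal
delta/theta plus frontotemporal fast-beta decrease; HF-dominant
autonomic balance during MTI with larger overall variability in POST;
EMG centroid lowered 6.5 Hz during MTI at unchanged amplitude).

What the synthetic data does **not** emulate: 1/f-continuous spectra
(bands are independent), non-stationarity within periods, respiratory
coupling of R-R beyond fixed-frequency sinusoids, realistic QRS
morphology or ectopy, volume-conducted cross-channel correlation, or
burn-specific pathophysiology. Passing parameter-recovery tests therefore
demonstrates the *pipeline's* correctness and calibration, not clinical
validity on real recordings.

## I/O

Datasets are discovered as `sub-*/ses-*/eeg/*_eeg.vhdr|.edf` with BIDS
`*_events.tsv` (onset/duration/trial_type) and `*_channels.tsv`
(name/type). Only EDF(+) and BrainVision are accepted; anything else is a
clear unsupported-format error. Modality resolution prefers the
channels.tsv `type` column, then a label prefix heuristic (ECG*/EKG*,
EMG*), then errors. All modalities of a session share one raw file and
sampling rate (as multiplexed acquisition hardware produces); units are
normalized to µV (EEG/EMG) and mV (ECG) on load. The synthetic writer
emits BrainVision (text header + IEEE-float data) in the same layout.
Result tables are TSV with '.' decimals, UTF-8, Unix newlines and
shortest-round-trip float rendering — reruns are byte-identical, and
reading with a round-trip float parser reproduces every value exactly.

## Problem sizes and determinism

Everything is a pure function of (input, seed): generators take explicit
seeds, ICA and permutation seeds come from the run config, per-comparison
seeds are hash-derived. The test-suite and acceptance runs use desk-scale
problem sizes chosen to keep statistical tolerances meaningful: 45–120-s
periods for EEG/EMG recovery and null simulations, 240–300-s windows for
tachogram spectra (the LF resolution floor), 17 synthetic recordings per
cohort (matching the session count of the emulated design), 20 seeds for
power estimates, and 1000 replicates for the type-I error check.

## Known limitations

- The permutation test treats the two recordings of a patient as
  independent; a hierarchical (mixed-effects) treatment is out of scope.
- The ocular stage removes at most one component by design; sessions with
  multiple strong non-blink artifact components rely on the amplitude
  mask instead.
- The R-peak detector is built for template-like synthetic ECG and clean
  clinical leads; pathological morphologies (bundle-branch block, pacing
  artifacts) are untested.
- EDF reading is exercised through the same mne code path as BrainVision
  but the bundled writer emits BrainVision only, so EDF round-trips are
  not covered by the test suite.
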