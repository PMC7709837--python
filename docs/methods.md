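# Methods

## The measure

Respiratory sinus arrhythmia (RSA) — heart rate rising with inspiration and
falling with expiration — is read out synchronously with a paced-breathing
protocol rather than spectrally. The protocol is 3 s inhale, 3 s hold, 3 s
exhale, 1 s pause (10-s cycle, 6 breaths/min). Beat-to-beat heart rate is
averaged in two 1-s windows per cycle, 2.5–3.5 s (the expected heart-rate
peak, end of inspiration) and 7.5–8.5 s (the expected trough, mid
expiration), both half-open `[start, end)` in recording time with the cycle
origin at the start of the first inhale. Per cycle, `RSA_sync = HR_insp −
HR_exp` and `HR-I:E_sync = HR_insp / HR_exp`; per participant, the mean over
valid cycles (mean of per-cycle ratios by default; a ratio-of-session-means
variant is available since published group tables may reflect session-level
averages). Spontaneous, unsynchronized breathing samples random breath
phases, so its expected ratio is 1; synchronized deep breathing concentrates
the peak and trough inside the windows.

Window heart rate is the time-weighted mean of the instantaneous-HR step
function (`ihr_k = 60/ibi_k` on `[beat_k, beat_{k+1})`) restricted to
physiologically in-range intervals (0.25 s ≤ IBI ≤ 2 s, i.e. 30–240 bpm);
a window is invalid below 50% in-range coverage, and a participant summary
requires at least 4 valid cycles. The time-weighted mean was chosen over
"beats in window" counting because child heart rates put only 1–2 beats in a
1-s window, making counts parity-sensitive.

Because the step function averages the rate over whole inter-beat intervals,
the windowed measure systematically underestimates the continuous modulation
(the window mean of a ~0.7-s-resolution step function cannot reach the
instantaneous extremes). This is a property of the measure, not an
implementation artifact, and it is why the synthetic ground truth (below) is
defined at the beat level.

## Synthetic cohort generator

The generator emulates the study conditions: 80 children allocated
18/20/21/21 across age groups 5–7, 8–10, 11–13 and 14–17 years, each
recorded 60 s breathing spontaneously and 120 s paced.

Per participant:

* **Baseline heart rate** — normal, truncated to [55, 130] bpm, sd 9 bpm,
  group means 81.6 / 79.75 / 89.55 / 85.35 bpm (the midpoints of the
  observed spontaneous inspiration- and expiration-window medians per age
  group).
* **Target ratio r** — Beta(2, 2.6) scaled onto [1.01, 1.60]; this puts the
  median at 1.26 with quartiles ≈ 1.17/1.36, matching the reported
  deep-breathing population summary. The RSA amplitude follows as
  `rsa_amp = baseline · (r−1)/(r+1)` (half peak-to-trough modulation), so the
  ratio of the modulation extremes equals r.
* **Modulation waveform g** — piecewise raised-cosine over the 10-s cycle:
  rise from a start level s0 to +1 at the end of the inhale, decay to a
  plateau level p = 0.5 over the hold, descent to −1 at the
  expiration-window centre (8.0 s), recovery to s0 over the rest. Each
  raised-cosine segment has mean (a+b)/2, so s0 is solved analytically from
  the zero-mean condition (s0 = −0.9 at the defaults). g is therefore
  exactly zero-mean with exact ±1 peaks at the window centres; the cycle
  mean of the instantaneous rate equals the baseline.
* **Instantaneous HR** — `baseline + rsa_amp · g(phase)`. Paced mode locks
  the phase to the protocol grid (perfect compliance). Spontaneous mode
  advances the phase through the participant's own breath cycle — period
  uniform in [2.5, 5.0] s, random initial phase, ±10% multiplicative
  per-breath jitter (preventing accidental phase-locking to the 10-s grid) —
  with the RSA amplitude attenuated ×0.5, since RSA shrinks at faster
  breathing rates.
* **Beats** — integrate-and-fire: a beat whenever ∫IHR/60 dt crosses an
  integer, inverted from the cumulative trapezoid on a 1-ms grid.
* **PPG rendering** — each beat adds a fixed pulse (unit Gaussian systolic
  lobe, σ = 60 ms, peak exactly at the beat time, plus a 0.3-amplitude
  dicrotic lobe 250 ms later), sampled at 100 Hz by default (the pulse
  oximeter's rate is not published; 100 Hz is typical of such hardware and
  configurable). Disturbances: sinusoidal baseline wander (0.3 a.u. at
  0.2 Hz — below the filter passband), white noise (σ = 0.05 a.u. against
  unit pulses), and transient Gaussian spikes (2/min, amplitude 2–4) as a
  crude stand-in for motion artifacts.

**Ground truth.** The oracle per-cycle window heart rates are computed from
the *exact* beat times through the same time-weighted step-function window
estimator, and the true participant ratio is the mean of those per-cycle
ratios. Recovery error against this truth therefore isolates what the
pipeline can get wrong — rendering, filtering, detection, interpolation —
rather than re-measuring the measure's own beat-level discretization (which
would add an amplitude-dependent pseudo-error up to ~0.02 on the ratio).
With zero modulation the truth ratio is exactly 1.

**Determinism.** A cohort seed spawns one `SeedSequence` child per
participant; profile draws and noise draws use separate streams, and the
draw order is fixed (age, baseline, ratio, then mode-specific parameters) so
the same seed yields the same latent participant in both modes — the paired
design the study uses.

**What the generator does not emulate.** Real finger-oximetry artifact
spectra, pulse-shape variability between children, SpO2, sensor dropout,
imperfect compliance with the pacing animation (paced mode is phase-locked),
and the slight sub-unity bias of observed spontaneous ratios (simulated
spontaneous medians sit at ≈ 1.00 rather than 0.98). Passing tests therefore
demonstrate pipeline correctness under idealized physiology, not clinical
performance.

## Beat detection

The waveform is band-limited to 0.5–4 Hz with a Butterworth band-pass of
total order 4 (two poles per edge; the filter family is a conventional
choice — maximally flat passband). Offline the filter runs forward-backward
(zero phase, which doubles the effective attenuation order and keeps the 1-s
windows aligned); a causal single-pass mode exists for streaming, with a
group-delay estimate at the band centre available to subtract before window
lookup. Beats are negative-going zero crossings of the first-difference
signal (local maxima), refined by linear interpolation across the crossing;
flat tops resolve to their earliest sample. Candidates within a 0.25-s
refractory period keep the larger peak, and maxima below 0.3× the 75th
percentile of positive-peak amplitudes are rejected — a robust gate against
noise ripple between pulses that plain zero-crossing detection would admit.
Inter-beat gaps above 2 s are flagged and excluded from windowed estimates
downstream. At 20 dB SNR the detector recovers ≥ 99% of true beats within
±30 ms with ≤ 1% spurious detections; at zero noise the median timing error
is ~2 ms.

## Feedback engine

Each time a sampling window closes (every 5 s), the rolling ratio pairs the
most recent valid inspiration-window HR with the most recent valid
expiration-window HR. An update is compliant iff ratio ≥ 1.1 (boundary
inclusive — the published level states no comparison direction). Compliance
multiplies the balloon altitude by `G = (10^6 / 1)^(5/120) = 10^{1/4} ≈
1.778`, calibrated so 24 consecutive compliant updates — 120 s of continuous
compliance — climb from 1 m to exactly 1,000,000 m. The altitude is stored
as a step count and exponentiated on demand, so the endpoint is exact with
no multiplicative drift. Non-compliance holds the altitude by default
(keeping the balloon up); an optional decay policy divides by G, floored at
the start altitude. The first update of a session (only one window closed)
emits no decision. The in-app altitude mapping is not published beyond its
endpoint; the exponential schedule here is calibrated to that endpoint only.

## Cohort statistics

Quantiles use linear interpolation (inclusive, "type 7" — the convention of
numpy and R's default), fixed because the source tables state none; with
{1,2,3,4} this gives quartiles 1.75/3.25. The paced-vs-spontaneous
comparison is a paired Wilcoxon signed-rank test: zero differences dropped
before ranking (classical practice), midranks for ties, exact null
distribution by dynamic programming over doubled midranks for n ≤ 25, and a
normal approximation with tie and continuity corrections otherwise. The
location estimate is the Hodges–Lehmann pseudo-median (median of the
n(n+1)/2 Walsh averages of the differences), with the distribution-free
signed-rank confidence interval (order statistics of the sorted Walsh
averages at the exact critical count, the construction R's `wilcox.test`
uses), guaranteeing ≥ 95% coverage. The compliance threshold is derived as
the midpoint of the non-overlapping inter-quartile ranges — (spontaneous Q3
+ deep Q1)/2 rounded to one decimal — which maps the published quartiles
(1.02, 1.16) to the published 1.1; overlapping IQRs return a flagged
midpoint instead of failing.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study size (n = 80,
both modes, 100 Hz) in a few seconds, so no scaling-down is needed.
Integrate-and-fire uses a 1-ms grid (beat-time error ≪ 1 ms at child heart
rates). Windows and cycles are half-open to make adjacent windows disjoint;
cycle slots per recording are `floor(duration/10)` (6 spontaneous, 12
paced). Filter design rejects bands reaching the Nyquist frequency and
signals shorter than ~3 settling spans of the low edge. All randomness flows
from explicit integer seeds; identical (seed, config) reproduce recordings
byte-for-byte after serialization (fixed 6-decimal formatting, sorted JSON
keys).

## Known limitations

* The windowed measure underestimates continuous RSA by construction; no
  spectral (HF-power) cross-estimate is provided, as frequency-domain RSA
  does not serve real-time feedback.
* Spontaneous-mode simulation yields ratio medians at ≈ 1.00; the small
  sub-unity bias in observed children is not modeled.
* The causal/streaming detection path estimates latency at a single
  frequency; precise per-beat latency varies with heart rate.
* Artifact modeling is limited to transient spikes; sustained motion or
  perfusion changes are out of scope.
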