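# Methods

## Signal model and assumptions

The chest impedance pneumograph (IP) is treated as an uncalibrated,
uniformly sampled waveform in which inspiration produces an upward
excursion.  The pipeline assumes (i) breathing occupies frequencies well
below the cardiac band (breathing < 1.2 Hz for the rates of interest,
cardiac 1.5–4.5 Hz, i.e. 90–270 bpm), (ii) movement artefacts are
large-amplitude excursions relative to the recording-wide signal scale,
and (iii) a central apnoea is a cessation of respiratory effort — the IP
goes quiet.  Obstructive apnoea, where effort continues against a closed
airway, is invisible to this signal by construction and out of scope.

## Preprocessing

**Artefact masking.**  A sample is masked when its residual from a
rolling median exceeds `k_mad x 1.4826 x rolling MAD`.  The rolling
statistics use a 30 s window evaluated on a 0.5 s hop grid and
interpolated; the mask is dilated by `mask_pad_s` on each side.  Two
numerical choices matter.  First, the window must be long relative to
plausible artefact durations — with a short window an artefact dominates
its own scale estimate and escapes masking; 30 s keeps a 5–10 s artefact
a minority of the window.  Second, the rolling scale is floored at half
the recording-wide robust scale (the median of the rolling MADs):
without the floor, the local MAD collapses during genuine apnoeas and
the masker flags quiet spans and pause edges — exactly the intervals the
pipeline exists to measure.  With the floor, only excursions large on
the scale of the whole recording are masked.  Defaults: `k_mad = 6`,
`mask_pad_s = 0.5 s`.  Masked samples are bridged by linear
interpolation before filtering (so artefact energy cannot ring through
the filters), set to zero in the output, and excluded from every
downstream SD/RMS computation.

**Zeroing.**  The baseline is removed by a zero-phase spectral
projection: rfft bins below `baseline_cutoff_hz` (default 0.1 Hz,
comfortably below the slowest breathing of interest at ~0.17 Hz) are
zeroed.  A projection was chosen over an IIR high-pass because it is
exactly idempotent and maps constants exactly to zero; the cost is
potential ringing at sharp edges, which is acceptable because masked
spans are interpolated first.  After filtering, the mean over non-masked
samples is subtracted so the usable signal is zero-centred.

**Cardiac-frequency removal.**  The per-sample cardiac frequency is the
numeric HR channel divided by 60 and interpolated to the IP timebase,
clipped to 1.5–4.5 Hz; where HR is missing for more than 5 s the
frequency falls back to the argmax of the IP spectrogram (8 s windows)
restricted to the same band.  No ECG channel is used or required.  The
notch is a zero-phase elliptic band-stop with stopband `f0 ±
notch_halfwidth_hz` (default ±0.3 Hz), passband edges at ±1.5x the
half-width, 0.1 dB passband ripple and 25 dB stopband attenuation —
after forward-backward application, <= 0.2 dB (~2 %) ripple and >= 50 dB
suppression.  When the frequency trace varies, the signal is processed
in 30 s blocks (8 s context, 1 s crossfade), each re-designed around the
block-median frequency.  The tightest configuration is a 100 bpm heart
rate (1.67 Hz): the lower passband edge sits at 1.22 Hz, just above the
1.2 Hz breathing-band protection point.

## Breath detection

A breath onset is an upward crossing of an adaptive amplitude threshold:
`alpha` x the population SD of the non-masked filtered signal spanning
the most recent `n_breaths` detected breaths (defaults `alpha = 0.4`,
`n_breaths = 15`, the validated optimum).  The exact update contract is
documented in `ibikit.breaths` and mirrored by a brute-force per-sample
reference in the test suite; the two must agree bit for bit.  Design
points where the definition was genuinely open:

- **Bootstrap**: until `n_breaths` breaths exist, the SD is computed
  over the trailing `init_window_s` (15 s) of signal, starting from the
  first 15 s at initialisation.
- **Hysteresis**: after each accepted breath the signal must fall below
  `rearm_fraction` (0.5) of the threshold before the next crossing
  counts.  A plain below-threshold reset double-counts ~8 % of breaths
  under moderate noise, because noise riding the falling limb of a
  breath re-crosses the threshold; the Schmitt-trigger re-arm removes
  the doubles without affecting sensitivity.
- **Refractory**: 0.3 s (a 200 breaths/min ceiling) guards against
  residual fast transients.
- **Masked spans** suspend detection and freeze the SD buffer, so
  artefacts neither trigger breaths nor corrupt the threshold.
- **IBIs** are onset-to-onset.  An interval is invalid when masked
  samples cover more than `max_artefact_overlap` (0.1) of it; invalid
  intervals are excluded from all statistics, separating loss of signal
  from true pauses.

Because the threshold updates only at accepted breaths, it freezes at
the pre-pause level during apnoeas; noise and the attenuated cardiac
residue remain sub-threshold, which is what makes long IBIs detectable
at all.

The respiratory-rate trace counts breaths in a trailing window (default
30 s); during the warm-up the count is normalised by the covered span
rather than the full window, which removes the start-of-trace bias from
the time-averaged rate.

## Apnoea classification

Candidates are valid IBIs >= 20 s.  Five features per candidate: RMS of
the filtered IP during the episode, in the 10 s before onset and the
10 s after the end (masked samples excluded), and the change in HR and
SpO2 over the 60 s from onset.  "Change" is operationalised as window
minimum minus the median of the 10 s pre-onset baseline (negative =
drop): the minimum-versus-baseline form captures the depth of
bradycardia/desaturation, which is the physiologically meaningful
quantity, in preference to a mean change.  Windows with < 50 % usable
coverage yield missing features; such candidates are excluded from
training and reported as indeterminate rather than forced into a class.

The classifier is a linear soft-margin SVM (`C = 1`, standardisation
always on) fitted deterministically; the persisted model is plain JSON
(weights, bias, feature means/scales) and predictions use only those
linear parameters, so a round-tripped model predicts identically.
Evaluation uses leave-one-subject-out cross-validation pooled over
held-out subjects, with accuracy, FPR, FNR and MCC (MCC reported as 0
when a confusion-matrix marginal is zero).  Co-occurrence utilities flag
bradycardia (HR < 100 bpm at any point during the pause plus 60 s) and
desaturation (SpO2 < 80 %), and bradycardia episodes are maximal runs of
HR < 100 bpm lasting >= 15 s.

## Epoch statistics

Six metrics per subject-epoch: time-averaged RR; mean, median and sample
SD (ddof = 1) of valid IBIs; proportions of IBIs strictly longer than
5 s and 10 s.  Before/after comparison uses the paired t statistic on
per-subject differences with a sign-flip permutation null: when
`2^n <= n_perm` the full enumeration is used and the test is exact
(p = count/2^n, identity included); otherwise `n_perm` random sign
vectors with the `(1 + count)/(1 + n_perm)` convention, which guarantees
p > 0 and validity at finite n.  Degenerate difference vectors are
handled explicitly (all-zero -> t = 0, p = 1; zero-variance nonzero ->
signed infinity, consistently compared).  Tests are two-sided by
default with one-sided alternatives available.  The six p-values are
adjusted with Hochberg's step-up method (ascending p, adj_m = p_m,
adj_i = min(adj_{i+1}, (m-i+1) p_i), capped at 1), cross-checked in the
tests against statsmodels and a brute-force recursion.

## The simulator

`simulate_recording` builds the IP as breathing + cardiac + noise:

- **Breathing**: a phase-accumulator sinusoid.  The instantaneous rate
  is the configured mean modulated by a unit-variance AR(1) process
  (8 s time constant) scaled by `breath_rate_jitter`; the amplitude
  envelope is a smoothed random walk whose per-minute RMS increment is
  `amplitude_drift`, clipped to [0.2, 2] x the nominal amplitude.  A
  ground-truth breath is the upward zero-crossing of the phase, which
  matches onset detection by threshold crossing and is exact by
  construction.
- **Cardiac**: a pure tone at `cardiac_rate` with amplitude
  `cardiac_amplitude_ratio` x the breath amplitude.
- **Noise**: white Gaussian, SD `noise_sd`.

Defaults (62.5 Hz IP, 1 Hz numerics, 50 breaths/min, jitter 0.05, drift
0.05/min, 150 bpm cardiac at ratio 0.2, noise SD 0.05 on unit breath
amplitude) are plausible for monitor exports of this type but
uncalibrated against any real cohort.

Injections: cessation pauses (kinds `pause` for any duration and
`apnoea-*` for >= 20 s) remove the breathing component with 0.2 s
raised-cosine edge ramps, retain cardiac at half amplitude, and snap
their boundaries to the ground-truth breath grid — the effective start
leaves the last pre-pause breath 0.5 s to complete its onset, and the
end moves forward to the next breath onset so breathing resumes with an
inspiration.  Without snapping, the detector fires on the mid-cycle
resumption up to one period before the next nominal breath, which is a
convention mismatch, not a detection error.  `low-amplitude-false-alarm`
segments scale breathing to 10 % (shallow breathing / poor electrode
contact): the truth keeps its breaths, but they are undetectable, which
is precisely the false-alarm class the classifier must reject.  HR/SpO2
responses are raised-cosine dips reaching the nadir 30 s after onset and
recovering by 90 s, matching the 60 s feature window.  Movement
artefacts are ramped plateaus of >= 3x the breath amplitude with a slow
wobble (an electrode-shift signature).

`simulate_feature_set` draws the two candidate classes as unit-variance
Gaussians in the standardised 5-feature space, their means `separation`
SD apart along a fixed direction (true apnoeas: quiet during, active
before/after, deep HR/SpO2 drops; false alarms: uniformly quiet,
near-zero deltas); RMS columns are clipped at zero.  `separation = 0`
makes the classes exchangeable, giving the chance-level control.

**What the simulator does not emulate** — and therefore what passing
tests cannot show about real data: cardiorespiratory coupling and
amplitude modulation of the IP by the heartbeat (only an additive tone),
periodic breathing, obstructive apnoea, non-Gaussian electrode noise,
real artefact morphology, and drifting heart rates within an epoch.
Performance numbers from the synthetic cohorts characterise the
algorithmic contracts, not expected clinical accuracy.

## Study conditions for the cohort-level checks

Chosen once, as the package's standard synthetic conditions: breath
recovery uses 20 five-minute recordings spanning 30–80 breaths/min with
noise SD 0.08 and cardiac ratio 0.25; pause recovery uses 10 recordings
at high SNR (noise 0.02, cardiac 0.1) with pauses of 5–30 s; the
respiratory-depression analogue uses 15 subjects with two 10-minute
epochs each (base rate U(42, 48) breaths/min), the after epoch at 0.85x
the rate with injected pause counts tripled (2 -> 6 per epoch, durations
U(6, 14) s); the null-calibration check uses 1000 replicates of 15
paired differences with 2000 permutations each.

## Known limitations

- The IP is uncalibrated; no tidal-volume or amplitude interpretation is
  attempted, and inspiration/expiration are not segmented.
- Candidate onset is the last detected breath before the gap, so a
  missed final breath lengthens the candidate by one period.
- The notch protects the breathing band only up to 1.2 Hz; breathing
  above ~72 breaths/min with a heart rate at the 100 bpm clip would be
  attenuated.
- Hochberg's method assumes non-negative dependence among the six
  metric p-values; the metrics are strongly correlated, which is the
  standard setting for it, but no stronger guarantee is claimed.
- Apnoeas interrupted by clinical intervention produce artefact-masked
  (invalid) intervals rather than measured pauses — deliberate, but it
  means such events are undercounted.
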