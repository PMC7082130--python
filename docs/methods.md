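# Methods

This note records the modeling choices behind `ovispindle`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic-data generator does and does not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions

Time is in seconds, sample indices are 0-based, and all event and epoch
intervals are half-open `[start, end)`.  Signal values are held in millivolts
internally; EDF files are written in microvolts (16-bit) and converted on
read.  Hypnograms use 10 s epochs with stages W, WU (wake ± rumination),
S1/S2 and U1/U2 (light/deep NREM ± rumination), R (REM); `N`/`U` are accepted
as unresolved NREM placeholders ahead of delta-power substaging.

## Detection model

The detector assumes spindles are transient narrowband bursts that raise the
5–16 Hz wavelet power envelope well above its long-run mean, on one channel
at a time, against a background whose band power is stationary enough for a
single per-channel baseline mean to be meaningful.

Envelope: complex Morlet (`cmor1.5-1.0`), center frequencies 5–16 Hz in
0.5 Hz steps.  Coefficients are L1-normalized — the library's L2-normalized
output is divided by sqrt(scale) — so that a sinusoid of fixed amplitude
produces the same envelope power at every center frequency.  Without this,
power at 15 Hz is ~3× weaker than at 5 Hz for equal amplitudes and
upper-band spindles are systematically penalized.  Power is averaged across
scales and smoothed with a moving average.

Parameters (all in `DetectionConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| `detect_band` | 5–16 | Hz | detection band; wider than the classical band to catch slow variants |
| `classical_band` | 10–16 | Hz | classical spindle view and the positive-peak filter band |
| `threshold_factor` | 1.8 | – | candidate threshold: 180% of baseline mean band power |
| `boundary_prominence_frac` | 0.8 | – | boundary cutoff from the peak prominence |
| `boundary_mean_frac` | 1.2 | – | boundary floor: 120% of baseline channel mean |
| `min_dur`, `max_dur` | 0.3, 3.0 | s | accepted duration window |
| `fft_bins` | 1024 | – | zero-padded event FFT; resolution rate/1024 ≈ 0.244 Hz at 250 Hz |
| `spike_factor` | 10 | – | noise-spike rule on the max/mean absolute first difference |
| `min_pos_peaks` | 3 | – | positive peaks required in the 10–16 Hz filtered segment |
| `smooth_s` | 0.2 | s | envelope smoothing (~2–3 spindle cycles), see below |
| `freq_step` | 0.5 | Hz | wavelet center-frequency spacing |
| `boundary_rule` | `drop_by` | – | see below |

**Boundary rule.**  Two readings of "power dropped to <80% of the prominence
of its peak, or <120% of the channel mean power" are implemented.  The
default, `drop_by`, places the cutoff at `peak − 0.8·prominence` (the
envelope has lost 80% of the peak's prominence), floored at `1.2 × channel
mean`.  The alternative `drop_to` uses `0.8 × prominence` directly as the
cutoff.  `drop_to` retains only the top fifth of a waxing–waning burst's
power profile — about 21% of a Hann-envelope event's support — after which
almost any true spindle shorter than ~1.5 s fails the 0.3 s minimum, so
`drop_by` is the default.  Boundaries never extend across a neighboring
candidate's envelope peak, so adjacent spindles split rather than merge.

**Envelope smoothing.**  The 200 ms moving average is the one free numerical
parameter with real leverage.  A narrowband envelope in noise shows deep
multipath-style fades on a ~0.2 s timescale; with smoothing much below 200 ms
these fades split single bursts into sub-threshold fragments, and with much
more smoothing sub-0.3 s transients are smeared past the duration floor.
200 ms recovers ≥0.9 of injected events at envelope SNR 5 while keeping
boundary errors near 0.2 s (measured by the acceptance tests).  Consequence:
the effective floor on measurable event duration is set by the smoothing, so
a 0.2 s burst may present as a ≥0.3 s envelope event at the default; the
duration-rejection pathway is therefore exercised at `smooth_s=0.1` in tests.

**Numerical details.**  Ties in the event FFT's peak bin resolve to the
lowest frequency (first argmax).  Flat candidates (zero prominence) are
returned unchanged with a warning flag.  A constant segment is not a noise
spike (0 > 0 is false).  Events whose refined interval has fewer than two
samples are dropped.  Overlapping refined intervals on one channel (possible
when two candidates refine into the same region) are merged with a warning.

**The false-alarm floor.**  At 180% of the mean, any background whose band
power fluctuates accepts some rate of weak events; on the synthetic
background this floor is of the same order as the injected spindle rate
(reported as `detection_precision` by the acceptance script).  The floor is a
property of the thresholds, not a bug: recall, boundary and frequency
recovery are measured against ground truth by matching, and the comparative
statistics (NREM vs wake densities, local vs simultaneous slow-wave
amplitudes, state-space separation) are carried by the true events on top of
the floor.

## Characterization

Simultaneity is pairwise temporal overlap between accepted events on
different channels, with no transitive closure.  Pair connectivity counts
events of multiplicity exactly 2; widespread ("global") connectivity counts
events of multiplicity ≥ 4.  Both matrices are symmetric; `global`
normalization divides by the number of unordered co-occurring pairs (sums to
1), `per_channel_row` divides each row by its sum.  Event-to-epoch assignment
uses the event midpoint, which is unambiguous for events straddling epoch
boundaries.  Artifact-flagged epochs are excluded from both the numerator and
denominator of every density.

## Slow-wave coupling

The slow-wave trace is a zero-phase 4th-order Butterworth band-pass at
0.5–2 Hz.  Peak-to-peak amplitude takes, among local maxima and minima within
±3 s of the spindle center, the maximum and minimum *nearest in time* to the
center (they are not required to flank it).  The phase at the spindle center
is the angle of the analytic (Hilbert) representation, 0 at the SW positive
peak, −π/2 at the ascending zero crossing, ±π at the trough.  The analytic
phase is one convention among several for a "spindle–SW phase angle"; results
depending on absolute phase values should be interpreted with that in mind.
Windows clipped by a recording edge are flagged; events with under 1 s of
usable window on either side are excluded from coupling statistics.

## Macrostructure

Substaging computes per-epoch delta power (0.5–4 Hz, Hann-windowed full-epoch
FFT, mean over channels) and labels an NREM epoch deep when its delta power
is ≥50% of the maximum over the non-artifact NREM epochs being substaged
(using the recording-wide maximum would let a wake artifact set the ceiling).
Epochs exactly at threshold are deep.  The S vs U (rumination) family of each
epoch is preserved.

Sleep cycles require ≥30 s of wake, then ≥2 min of strictly contiguous NREM
(any interior non-NREM epoch ends the run), terminated by wake or by a REM
run of ≥1 min; a shorter REM run invalidates the candidate cycle.  The cycle
spans NREM onset to terminator onset.  Within-cycle profiles use the first
three cycles of ≥18 min, counting accepted spindles in consecutive 3 min
windows and normalizing all included windows to sum to 1; fewer qualifying
cycles are used as available and reported.

## State space

Band powers sum FFT bins whose centers fall in the half-open band
`[low, high)`; since each numerator band nests in its denominator, both
ratios are bounded by [0, 1].  The full-epoch transform (2500 samples at
250 Hz) is used rather than a 1024-bin transform: 10 s epochs need the
0.1 Hz resolution to resolve the 0.5 Hz band edges, and the ratio of summed
powers is insensitive to the FFT length beyond that.  The grid spans
[0, 1.025) in 41 cells of 0.025 so a ratio of exactly 1.0 lands in the last
cell; 41 × 41 = 1681 cells.  Per-subject maps are normalized by their epoch
count; combined maps are plain sums, so the combined total equals the subject
count, and contour levels are 2.5× and 5× the uniform density
n_subjects/1681.  Epochs with zero denominator power are excluded;
spindle-centered epochs are restricted to local spindles whose midpoint lies
in a non-artifact wake or NREM epoch, and epochs extending past a recording
edge are skipped.

## The synthetic-data generator

The generator emulates the *statistical context* the pipeline must operate
in, not thalamocortical biophysics:

- 1/f background (α=1, RMS 0.02 mV in NREM) per channel, independent across
  channels, with lognormal amplitude modulation (σ=0.6 of log amplitude,
  correlation time 4 s).  The modulation reproduces the right-skewed,
  burst-like band-power distribution of real EEG; a strictly Gaussian
  background spends roughly 5–10% of its time above 180% of its own mean band
  power, which would make a mean-referenced threshold uninformative.
- Stage structure: deep/light NREM add 0.5–2 Hz slow-wave activity at RMS
  0.03/0.012 mV (putting nearest-extrema SW peak-to-peak values near the
  0.06–0.10 mV range); wake and REM attenuate the 1/f background to 0.5/0.6
  of its NREM scale (low-voltage desynchronized EEG) and add low-amplitude
  white broadband noise.
- Spindles: sinusoids under a Hann amplitude envelope.  Frequencies are
  uniform on 10–16 Hz; durations are lognormal (median 0.9 s, log-sd 0.35)
  clipped to 0.5–2 s, the right-skewed, ~1 s-typical distribution reported
  for real spindles.  Amplitude is `amplitude_snr` (default 5) × the
  channel's 10–16 Hz background RMS.  A `global_fraction` (default 0.4) of
  events is co-timed on ≥4 random channels and coupled to an injected slow
  wave (1 Hz cosine under a 2.5 s Hann window, amplitude 0.03–0.05 mV) whose
  positive peak coincides with the spindle center; the rest are single-
  channel and uncoupled.  Same-channel events keep ≥1 s clearance.
- Rates per stage (events/min): 4.5 deep NREM, 2.5 light NREM, 0.3 wake,
  0 REM — NREM-dominant with sparse wake events.
- Artifacts: single-sample voltage spikes of 20× the local (1 s) standard
  deviation at 0.2/min, exercising the 10× noise-spike rule with margin.

Everything is drawn from one seed (background and event placement use
independent child generators), the injected event table is exact, and
`recording − background` equals the summed event waveforms to the last bit.

What it does **not** emulate — and hence what passing tests do not show
about real data: volume conduction and inter-channel correlation (real
simultaneous spindles share filtered background, synthetic ones only share
injected waveforms); EMG/movement contamination and electrode artifacts
beyond single-sample spikes; spindle frequency drift within an event and
refractoriness; realistic wake alpha rhythms (so "wake spindle" phenomenology
cannot be studied on synthetic data); and any between-subject variability
structure (acceptance "subjects" are independent seeds of the same
configuration).

## Known limitations

- The detector's weak-event floor at the default thresholds means absolute
  densities track the threshold as much as the physiology; comparative and
  ground-truth-matched quantities are the meaningful outputs.
- Peak frequency comes from the maximum FFT bin of a short Hann-windowed
  segment; at envelope SNR 5 the per-event jitter is a few tenths of a Hz
  even with exact boundaries, so frequency recovery is assessed by the
  median error.
- Boundary estimates cover the high-power core of a waxing–waning event, not
  its full support; onset/offset errors scale with event duration.
- EDF output pads the final second with zeros (whole 1 s records, integer
  sampling rates only) and stores 16-bit quantized values scaled per channel.
- `downsample` uses polyphase FIR anti-aliasing with a rational rate factor
  (denominator up to 10⁴); exotic rate pairs beyond that are not supported.
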