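# ovispindle

Sleep-spindle detection and characterization for multichannel cortical EEG,
built around the kind of long wireless recordings made from large animals
(the default channel montage is the eight-site bilateral ovine layout
A1/A2/C/P, left and right).  It is aimed at sleep neurophysiologists who need
an automated, reproducible pipeline from raw EEG + hypnogram to spindle
catalogs, topography, slow-wave coupling, sleep-cycle density profiles and
spectral state-space maps — plus a synthetic polysomnography generator so the
whole pipeline can be validated against known ground truth.

## The method

**Detection.**  For each channel a complex Morlet wavelet transform (center
frequencies 5–16 Hz in 0.5 Hz steps, L1-normalized) yields the mean band
power envelope P(t), smoothed with a 200 ms moving average.  Candidate
spindles are maximal runs where

    P(t) > 1.8 · mean(P_baseline)

with the mean taken per channel over a designated baseline recording (a
"night 2" role; the recording itself is used, with a warning, when no
baseline is given).  Event boundaries are refined around the envelope peak:
with peak prominence *p* (height above the higher flanking minimum), the
boundary cutoff is

    max( P_peak − 0.8·p ,  1.2 · mean(P_baseline) )

and the event extends outward from the peak to the first samples below the
cutoff, never crossing a neighboring candidate's peak.  Each event's raw
segment then gets a Hann-windowed, 1024-bin FFT (resolution ≈ 0.244 Hz at
250 Hz); the peak-power bin inside 5–16 Hz gives peak frequency and power.
Events are discarded when the duration is outside 0.3–3 s, the peak frequency
leaves the detection band, the segment contains a voltage step more than 10×
its mean absolute first difference (noise spike), or the 10–16 Hz zero-phase
filtered trace contains fewer than three positive peaks.  Rejected events are
retained with their rejection reason; a "classical" view restricts accepted
events to 10–16 Hz peak frequencies.

**Characterization.**  Spindles overlapping in time on different channels are
*simultaneous* (pairwise, half-open intervals, no transitive closure); an
event's multiplicity is 1 + its distinct partner channels.  Connectivity
matrices tally co-occurring channel pairs for two-channel events and for
widespread (≥4 channel) events, normalized either over all unordered pairs
(sums to 1) or per channel row.  Densities are accepted spindles per minute
of (non-artifact) stage time.

**Slow-wave coupling.**  The channel's EEG is band-passed to 0.5–2 Hz
(zero-phase); within ±3 s of each spindle center the positive and negative
peaks nearest the center give the SW peak-to-peak amplitude, and the phase of
the analytic signal at the center gives the coupling phase (0 = SW positive
peak, ±π = trough).

**Macrostructure.**  Light vs deep NREM is split at 50% of the maximum
per-epoch delta (0.5–4 Hz) power.  A sleep cycle starts after ≥30 s of wake,
needs ≥2 min of contiguous NREM, and terminates at wake or at a REM run of
≥1 min; within-cycle spindle density is profiled over 3 min windows of the
first three cycles lasting ≥18 min, normalized to proportions.

**State space.**  Every 10 s epoch is summarized by two spectral ratios,
SSR1 = power(6.5–9 Hz)/power(0.5–9 Hz) and
SSR2 = power(0.5–20 Hz)/power(0.5–100 Hz), from Hann-windowed full-epoch
FFTs averaged over channels (or taken from the spindle's own channel).
Ratios are binned on a 41 × 41 grid of 0.025-wide cells (1681 cells),
normalized per subject to total 1 and summed across subjects; contour levels
at 2.5× and 5× the uniform density (n_subjects/1681) outline the dominant
wake and NREM regions.

## Worked example

```python
from ovispindle import (SimConfig, generate_study, detect_spindles,
                        accepted_events, annotate_simultaneity, stage_density,
                        couple_events, compare_local_vs_simultaneous,
                        find_sleep_cycles, match_events)

cfg = SimConfig(seed=42, stage_sequence=(
    ("W", 60.0), ("S1", 180.0), ("S2", 600.0), ("R", 90.0)))
rec, hyp, truth = generate_study(cfg)            # 15.5 min, 8 channels
events = detect_spindles(rec, baseline=rec)
acc = accepted_events(events)
matches, misses = match_events(truth, acc)
print(f"injected {len(truth)} spindles, accepted {len(acc)} events, "
      f"recall {len(matches) / (len(matches) + len(misses)):.2f}")
print(f"NREM density {stage_density(acc, hyp, {'S1','S2'}) / 8:.1f} /min/channel, "
      f"wake density {stage_density(acc, hyp, {'W'}) / 8:.1f} /min/channel")
catalog = annotate_simultaneity(acc)
sw = compare_local_vs_simultaneous(catalog, couple_events(rec, catalog.events))
print(f"{catalog.n_local} local vs {catalog.n_simultaneous} simultaneous; "
      f"SW p2p {sw['mean_p2p_local']:.3f} vs {sw['mean_p2p_simultaneous']:.3f} mV")
print(f"sleep cycles: {find_sleep_cycles(hyp)}")
```

prints

```
injected 56 spindles, accepted 1317 events, recall 0.96
NREM density 12.2 /min/channel, wake density 0.6 /min/channel
272 local vs 1045 simultaneous; SW p2p 0.054 vs 0.062 mV
sleep cycles: [SleepCycle(start=60.0, end=840.0, terminator='rem')]
```

Reading the numbers: all 56 injected ground-truth bursts occur in NREM, and
96% of their per-channel instances are recovered.  The accepted count is much
larger than the injected count because, at a threshold of 180% of the mean
band power, the detector also accepts weak background fluctuations — the
NREM-to-wake density contrast (12.2 vs 0.6 per minute per channel) and the
higher slow-wave peak-to-peak amplitude around simultaneous spindles
(0.062 vs 0.054 mV) are carried by the injected events on top of that floor.
The one wake→NREM→REM passage satisfies the 30 s/2 min/1 min cycle rule.

The same pipeline is available from the shell:

```bash
ovispindle simulate --config sim.yaml --out rec.edf --truth truth.csv --hypnogram hyp.csv
ovispindle detect --rec rec.edf --out events.csv
ovispindle characterize --events events.csv --hypnogram hyp.csv \
    --out summary.csv --connectivity conn.csv
ovispindle swcouple --rec rec.edf --events events.csv --out coupling.csv
ovispindle cycles --hypnogram hyp.csv --events events.csv \
    --out-cycles cycles.csv --out-profile profile.csv
ovispindle statespace --rec rec.edf --hypnogram hyp.csv --out map.csv --contours
ovispindle report --dir . --out report.txt
```

Every command writes a JSON manifest (config snapshot, input hashes, seed,
version) and each CSV output references it in a leading comment line.

## Layout

- `ovispindle.eeg_io` — Recording/Hypnogram containers, EDF + delimited-text
  I/O, polyphase downsampling, common average reference
- `ovispindle.synthetic_data` — ground-truth study generator
- `ovispindle.spindle_detection` — envelope, thresholds, boundary
  refinement, spectral features, acceptance filters
- `ovispindle.characterization` — simultaneity, connectivity, densities
- `ovispindle.sw_coupling` — slow-wave peak-to-peak and phase
- `ovispindle.macrostructure` — substaging, sleep cycles, density profiles
- `ovispindle.state_space` — SSR ratios, density maps, contours
- `ovispindle.cli` — the `ovispindle` command

See `docs/methods.md` for modeling assumptions, parameter defaults and known
limitations.
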