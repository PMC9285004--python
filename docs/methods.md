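# Methods

This note documents the algorithms, parameter conventions, and design
choices behind `mealfp`, and what the synthetic-data tests do and do not
establish about real recordings.

## Data model and conventions

Channels are addressed on a fixed 64×64 electrode grid with 1-based rows
and columns; the linear index is `(row − 1) × 64 + col` ∈ 1..4096.  Grid
coordinates are converted to micrometers by the electrode pitch
(default 60 µm).  Voltages are in mV, time in seconds from recording
start, and every interval is half-open `[start, end)`.  Traces are
stored as 32-bit floats in an open HDF5 layout
(`/recording/{traces, sample_rate_hz, pitch_um, start_time_s, channels}`);
vendor acquisition formats are proprietary, so adapters are expected to
convert into this layout.  Selective reads index the HDF5 dataset
directly and never load unrequested channels.

## Downsampling

The decimation factor is `q = floor(source_rate / target_rate)`; the
achieved rate `source_rate / q` is reported and may differ from the
request for non-integer ratios; making the scheme explicit keeps
output sample counts exactly predictable.  The anti-alias filter is a symmetric (zero-phase)
Hamming-window FIR low-pass with cutoff 0.4 × target rate and
`60 q + 1` taps, applied over reflection padding; output length is
`floor(N / q)`.  A tone 0.93× the target Nyquist is attenuated by more
than 20 dB, while signals band-limited below 0.4× the target Nyquist
keep their energy to within 1%.

## Filtering, spectra, band powers

Digital filters are 4th-order Butterworth designs applied
forward-backward (`sosfiltfilt`), so event timing is not shifted —
a requirement for the seizure detector downstream.  A band-pass whose
upper edge lands at or above Nyquist (e.g. 40–150 Hz at a 300 Hz
working rate) is clipped to 0.99 × Nyquist with a warning rather than
rejected.

Amplitude spectra are one-sided and normalized so a sine of amplitude
A mV peaks at A mV (interior bins scaled 2/N; DC and Nyquist 1/N).
The STFT uses Hann windows over consecutive segments (default 1 s, no
overlap; a trailing partial segment is discarded, so the bin count is
exactly `floor(duration / segment)`).  The per-bin *summed magnitude* —
the sum of magnitude components at frequencies strictly below half the
sampling rate — is the spectral-activity signal for seizure detection.

Band powers are mean Welch PSD (1 s Hann segments, 50% overlap) over
the conventional EEG bands delta 0.5–4, theta 4–8, alpha 8–13, beta
13–30, gamma 30–100 Hz (clipped to Nyquist; configurable).  Traces are
mV, so the PSD is scaled by 10⁻⁶ and reported in V²/Hz, the unit used
in the exported CSV.

## LFP peak detection

A peak is a strict local extremum whose amplitude relative to the
channel baseline reaches `threshold_mv` (default 0.07 mV) and whose
full width at the baseline level reaches `min_duration_s` (default
0.02 s); no upper limits apply.  Choices the definition leaves open:

* **Baseline** — the median of the analysed trace segment.  It is robust
  to sparse activity and cheap; it is configurable for callers that
  prefer a pre-computed noise floor.
* **Width** — the distance between the baseline crossings on either
  side of the apex (trace edges when the trace never returns to
  baseline).  Width is therefore a function of the waveform only, not
  of the detection threshold; this makes the detected count monotone
  non-increasing in both threshold and minimum duration, a property the
  test suite enforces over parameter grids.  The cost is that two
  apexes riding one suprabaseline excursion share its crossings and are
  reported with the same (wide) width.
* **Polarity** — maxima and minima are detected separately and merged;
  when opposite-polarity apexes fall within `min_duration_s` (the two
  phases of one biphasic event) only the larger is kept.

The detector is vectorized but defined to be *exactly* equivalent to an
exhaustive per-sample scan; the suite checks bit-for-bit agreement with
an independently written brute-force oracle on 1,000 random traces.

## Channel-group summaries

Per channel: peak count, count/s, mean peak amplitude and duration
(undefined — empty CSV fields, never 0 — when no peaks were detected,
to avoid biasing group means), and band powers.  Per group: a channel
is **active** when its count is *strictly greater than* 20 in the
analysed interval; the **top-N** statistics (N = 20 by default) are
computed over the min(N, active) channels with the largest counts, ties
broken toward the lower linear index for determinism.  The group mean
amplitude/duration is the mean of per-channel means over those
channels.  Rasters order channels by linear index and conserve event
counts under binning.

## Seizure-envelope detection

Per channel:

1. **Baseline** (`baseline_len_s` = 60 s, searched within the first
   `baseline_search_s` = 300 s).  Candidate windows start on a 10 s
   grid; each is scored by the number of samples beyond 6 robust
   (MAD-based) standard deviations of the whole trace plus the window
   variance normalized by the median candidate variance; the earliest
   minimum wins.  "Quiet" (free of LFP events, seizure activity, and
   electrical noise spikes) is a criterion rather than an algorithm, so
   this deterministic scoring is a design choice of this package.  Channels with zero baseline
   SD are skipped with a warning rather than failing the group.
2. **Two activity streams.**  Spectral: summed STFT magnitude >
   baseline mean + `spectral_k` (6) SD per 1 s bin.  LFP: peaks with
   amplitude ≥ `voltage_k` (6) × baseline voltage SD sustained
   `lfp_event_duration_s` (0.035 s); samples spanned by each peak are
   marked active.
3. **Continuity.**  Each stream is smoothed by centered moving means
   with a short and a long window; a point is inside a region when the
   short-window density ≥ `density_cutoff_short` (0.1), and adjacent
   regions merge when the long-window density stays ≥
   `density_cutoff_long` (0.05) across the gap.  The window lengths are
   in datapoints of the stream they filter: 30/500 samples for the LFP
   stream (0.1 s / 1.67 s at 300 Hz) and 5/30 bins for the 1 s spectral
   stream — 500 one-second bins would exceed typical inter-seizure
   spacing, so the spectral windows are the same *durations* rescaled
   to bins.
4. **Envelope.**  Intersections of spectral and LFP regions lasting at
   least `min_envelope_s` (10 s) are seizure envelopes.  The end is the
   end of the overlap (only the start has a distinguished definition).  The
   start is the first spectral-threshold crossing within one bin before
   the overlap, then refined to the first suprathreshold voltage sample
   within ±1 bin of it *that begins sustained activity* (at least 5% of
   the following bin suprathreshold).  The refinement gives onsets at
   sample resolution — 1 s spectral bins cannot resolve the ≤ 1 s
   onset lags of fast propagation — while the sustained-activity
   condition prevents an isolated interictal spike in the reach-back
   region from defining the onset.  Note that discharges shortly before
   the oscillatory phase still count toward the onset; the method does
   not separate pre-ictal from ictal activity (doing so reliably
   requires frequency components well above 100 Hz, outside this
   band-limited regime).

## Network metrics

Over a group and analysis window, **participating** channels are those
with an envelope intersecting the window.  **Initiators** are all
channels whose earliest start falls within `initiator_bin_s` (same
quantized bin) of the global earliest start.  The default tolerance is
0.05 s, matched to the sample-resolution refined onsets; a 1 s
(STFT-bin) tolerance is available via `find_initiators(..., bin_s=1.0)`
but makes every channel an initiator when a fast wave crosses the array
in under a second.

* **Max spread distance** — max over (initiator, participant) pairs of
  Euclidean grid distance × pitch (µm).
* **Duration** — per channel `end − start`; mean and max over
  participating channels.
* **Propagation speed** — max spread distance divided by a mean onset
  lag (µm/s), undefined (flagged, never silently NaN) when there are no
  non-initiator participants or the lag is zero.  Which channels the
  mean onset lag averages over is a convention.  Averaging over *all*
  non-initiator participants
  biases the estimate upward by max(d)/mean(d) (≈ 1.8 on a square
  region) for a constant-speed radial wave, so the default
  (`lag_stat="farthest"`) averages the onset lags of the maximally
  distant participating channel(s) — the channels that define the
  numerator — which recovers the wave speed; `lag_stat="mean"` gives
  the all-participants convention.

## Synthetic recordings

The generator emulates a low-Mg²⁺-style brain-slice recording:
per-channel independent Gaussian noise (default SD 0.02 mV at 300 Hz),
optional Poisson interictal spikes (biphasic, default 0.15 mV / 0.05 s),
and a seizure-like event that starts at a focal origin channel and
spreads radially at constant speed (channel onset = origin onset +
distance / speed).  Each channel's burst is a large biphasic onset
discharge at the exact onset, a 2 s linearly ramped 8 Hz oscillation
(default 0.5 mV) sustained for the configured duration, and Poisson
"spike riders" — so both the spectral and the LFP branches of the
detector are exercised, and the onset discharge gives ground-truth lag
recovery a sample-accurate marker.  One master seed drives everything;
per-channel substreams are derived from (seed, linear index), so output
is independent of channel iteration order and bit-stable across runs.

What the generator does **not** emulate: 1/f background spectra,
electrode-correlated noise, anisotropic or non-constant propagation,
waveform diversity across channels, drifting baselines, and artifacts.
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under the stated conditions, not that it is robust to
every recording; on real slices a few envelopes should still be
verified by eye, and thresholds adjusted when the signal-to-noise ratio
is poor.

## Numerical and degenerate-input choices

* Ties in baseline-window scoring and top-N selection break toward the
  earliest window / lowest linear index (determinism).
* Zero-SD (constant) channels: validation error in the stream
  detectors; skipped with a warning at the recording level.
* "No SLE" is a valid empty result (exit 0 on the CLI), not an error.
* Degenerate metric fields are `None`/empty-CSV, never 0 or silent NaN.
* Repeated runs with identical inputs and parameters are byte-identical
  for CSV/JSON outputs; PNG outputs strip variable metadata.

## Problem sizes in the test suite

The suite and the acceptance script regenerate all fixtures: 1,000
random traces (≤ 3,000 samples) for oracle equivalence; 20 × 120 s
noise-only recordings for specificity; 20 seeded 30 s SLEs (and 20 ×
8 s bursts, which must never be reported against the 10 s minimum) for
sensitivity; and 36 radial-wave scenarios (speeds 250–2,000 µm/s ×
durations 15–60 s × 3 seeds) on a 20×20 grid at 300 Hz for network
recovery — sizes chosen so the whole suite runs in minutes on one CPU
while still exercising every detector branch at the defaults.

## Known limitations

* Whole-recording, in-memory processing; no streaming for
  larger-than-RAM files.
* No pre-ictal/ictal discrimination and no seizure-type classification.
* The peak-width rule can report duplicate wide peaks for noise apexes
  riding a single large excursion (see LFP peak detection above).
* Isotropic propagation is assumed by the speed estimate's pairing of
  the farthest channels with the spread distance.
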