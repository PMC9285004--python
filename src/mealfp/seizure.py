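"""Unsupervised seizure-like-event (SLE) detection and network metrics.

Per channel, the detector works on two parallel activity streams:

* **spectral** — summed STFT magnitude (1 s Hann segments, no overlap)
  thresholded at baseline mean + ``spectral_k`` standard deviations;
* **LFP** — discrete peaks with amplitude above ``voltage_k`` baseline
  standard deviations sustained for ``lfp_event_duration_s``.

Each stream is smoothed by two sliding windows (a short one that finds
regions of continuous activity and a long one that bridges brief gaps).
Time intervals where both streams are continuously active for at least
``min_envelope_s`` form the seizure envelope.  The envelope start is
identified by the first spectral-threshold crossing, then refined to the
first suprathreshold voltage sample within one STFT bin of it, giving
sample-resolution onsets for propagation measurements.

Group-level network metrics follow: the initiation channel(s), maximum
spread distance (Euclidean grid distance × electrode pitch), per-channel
durations, and the propagation speed (max spread distance divided by the
mean onset lag of the maximally distant channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dsp import SpectrogramFrame, stft_magnitude
from .lfp import DetectionParams, LFPPeak, detect_lfp_peaks
from .recording import ChannelGroup, ChannelID, Recording, TimeRange, ValidationError


@dataclass(frozen=True)
class SeizureParams:
    """Detection parameters; defaults are the platform's standard values.

    ``window_short``/``window_long`` are in datapoints of the LFP sample
    stream; ``window_short_bins``/``window_long_bins`` are the equivalent
    windows for the 1 s spectral-bin stream.
    """

    baseline_len_s: float = 60.0
    baseline_search_s: float = 300.0
    spectral_k: float = 6.0
    voltage_k: float = 6.0
    lfp_event_duration_s: float = 0.035
    window_short: int = 30
    window_long: int = 500
    window_short_bins: int = 5
    window_long_bins: int = 30
    density_cutoff_short: float = 0.1
    density_cutoff_long: float = 0.05
    min_envelope_s: float = 10.0
    merge_gap_s: float = 0.0
    stft_segment_s: float = 1.0
    initiator_bin_s: float = 0.05
    lag_stat: str = "farthest"  # "farthest" | "mean"

    def __post_init__(self) -> None:
        if self.window_short >= self.window_long:
            raise ValidationError("window_short must be < window_long")
        if self.window_short_bins >= self.window_long_bins:
            raise ValidationError("window_short_bins must be < window_long_bins")
        if self.min_envelope_s <= 0:
            raise ValidationError("min_envelope_s must be positive")
        if self.spectral_k <= 0 or self.voltage_k <= 0:
            raise ValidationError("SD multipliers must be positive")
        for c in (self.density_cutoff_short, self.density_cutoff_long):
            if not (0 < c <= 1):
                raise ValidationError("density cutoffs must be in (0, 1]")
        if self.initiator_bin_s <= 0:
            raise ValidationError("initiator_bin_s must be positive")
        if self.lag_stat not in ("farthest", "mean"):
            raise ValidationError(f"unknown lag_stat {self.lag_stat!r}")


@dataclass
class BaselineStats:
    """Quiet-reference statistics for one channel."""

    window: TimeRange
    voltage_mean_mv: float
    voltage_sd_mv: float
    spectral_mean: float
    spectral_sd: float
    baseline_mv: float  # median of the full analysed trace


@dataclass
class ActivitySeries:
    """Uniformly sampled boolean activity stream."""

    times: np.ndarray  # strictly increasing, uniform spacing
    active: np.ndarray  # bool, same length
    stream: str  # "spectral" | "lfp"

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass(frozen=True)
class SeizureEnvelope:
    """Per-channel seizure interval [start_s, end_s)."""

    channel: Optional[ChannelID]
    start_s: float
    end_s: float
    onset_source: str = "spectral"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SLEGroupMetrics:
    """Network metrics for one group and analysis window."""

    group: ChannelGroup
    window: TimeRange
    initiators: Set[ChannelID]
    participating: Set[ChannelID]
    max_distance_um: Optional[float]
    mean_duration_s: Optional[float]
    max_duration_s: Optional[float]
    propagation_speed_um_s: Optional[float]
    speed_defined: bool = False

    @property
    def has_sle(self) -> bool:
        return bool(self.participating)


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def select_baseline(
    trace, sample_rate_hz: float, params: SeizureParams = SeizureParams()
) -> BaselineStats:
    """Automatically select the quietest 60 s reference window in the
    first 5 min of the trace.

    Candidate windows start on a 10 s grid; each is scored by the number
    of samples beyond 6 robust (MAD-based) standard deviations plus its
    variance normalized by the median candidate variance.  The earliest
    minimum-score window wins, which makes the choice deterministic.
    """
    x = np.asarray(trace, dtype=np.float64)
    if sample_rate_hz <= 0:
        raise ValidationError("sample rate must be positive")
    duration = x.size / sample_rate_hz
    if duration < params.baseline_len_s:
        raise ValidationError(
            f"trace ({duration:.1f} s) shorter than baseline window "
            f"({params.baseline_len_s} s)"
        )
    search_end = min(duration, params.baseline_search_s)
    if duration < params.baseline_search_s:
        warnings.warn(
            "trace shorter than the baseline search span; searching the whole trace"
        )
    wlen = int(round(params.baseline_len_s * sample_rate_hz))
    step = int(round(10.0 * sample_rate_hz))
    last_start = int(round(search_end * sample_rate_hz)) - wlen
    starts = list(range(0, max(last_start, 0) + 1, step))
    med = float(np.median(x))
    rsd = _robust_sd(x)
    if rsd == 0:
        rsd = float(np.std(x)) or 1.0
    variances = np.array([np.var(x[s : s + wlen]) for s in starts])
    norm = float(np.median(variances)) or 1.0
    scores = []
    for s, v in zip(starts, variances):
        w = x[s : s + wlen]
        outliers = int(np.count_nonzero(np.abs(w - med) > 6.0 * rsd))
        scores.append(outliers + v / norm)
    best = int(np.argmin(scores))  # argmin takes the earliest tie
    s0 = starts[best]
    w = x[s0 : s0 + wlen]
    frame = stft_magnitude(w, sample_rate_hz, segment_s=params.stft_segment_s)
    return BaselineStats(
        window=TimeRange(s0 / sample_rate_hz, (s0 + wlen) / sample_rate_hz),
        voltage_mean_mv=float(np.mean(w)),
        voltage_sd_mv=float(np.std(w)),
        spectral_mean=float(np.mean(frame.summed_magnitude)),
        spectral_sd=float(np.std(frame.summed_magnitude)),
        baseline_mv=med,
    )


def detect_spectral_activity(
    frame: SpectrogramFrame, baseline: BaselineStats, params: SeizureParams = SeizureParams()
) -> ActivitySeries:
    """Threshold the summed STFT magnitude at mean + k·SD of baseline."""
    if baseline.spectral_sd == 0:
        raise ValidationError("zero baseline spectral SD (degenerate constant trace)")
    threshold = baseline.spectral_mean + params.spectral_k * baseline.spectral_sd
    return ActivitySeries(
        times=np.asarray(frame.times_s, dtype=float),
        active=np.asarray(frame.summed_magnitude) > threshold,
        stream="spectral",
    )


def detect_lfp_activity(
    trace,
    sample_rate_hz: float,
    baseline: BaselineStats,
    params: SeizureParams = SeizureParams(),
) -> ActivitySeries:
    """Mark samples covered by LFP peaks exceeding k·SD of baseline voltage
    for the fixed event duration."""
    x = np.asarray(trace, dtype=np.float64)
    if baseline.voltage_sd_mv == 0:
        raise ValidationError("zero baseline voltage SD (degenerate constant trace)")
    det = DetectionParams(
        threshold_mv=params.voltage_k * baseline.voltage_sd_mv,
        min_duration_s=params.lfp_event_duration_s,
        polarity="both",
    )
    peaks = detect_lfp_peaks(x, sample_rate_hz, det, baseline=baseline.baseline_mv)
    active = np.zeros(x.size, dtype=bool)
    for p in peaks:
        i0 = max(0, int(round((p.time_s - p.width_s / 2) * sample_rate_hz)))
        i1 = min(x.size, int(round((p.time_s + p.width_s / 2) * sample_rate_hz)) + 1)
        active[i0:i1] = True
    times = np.arange(x.size) / sample_rate_hz
    return ActivitySeries(times=times, active=active, stream="lfp")


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def continuity_filter(
    series: ActivitySeries,
    window_short: int,
    window_long: int,
    params: SeizureParams = SeizureParams(),
) -> List[TimeRange]:
    """Turn a boolean activity stream into maximal continuous intervals.

    A time point belongs to a region when the centered short-window
    activity density reaches ``density_cutoff_short``; adjacent regions
    are merged when the long-window density stays at or above
    ``density_cutoff_long`` throughout the gap.
    """
    active = np.asarray(series.active, dtype=float)
    n = active.size
    if window_long > n or window_short > n:
        raise ValidationError("sliding window longer than the series")
    dens_short = _moving_mean(active, window_short)
    dens_long = _moving_mean(active, window_long)
    in_region = dens_short >= params.density_cutoff_short
    if not in_region.any():
        return []
    # index runs of in_region
    edges = np.diff(in_region.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if in_region[0]:
        starts.insert(0, 0)
    if in_region[-1]:
        ends.append(n)
    merged: List[List[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        gap = dens_long[merged[-1][1] : s]
        if gap.size and np.min(gap) >= params.density_cutoff_long:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    dt = series.dt or 1.0
    t0 = float(series.times[0])
    out = []
    for s, e in merged:
        start = t0 + (s - 0.5) * dt if series.stream == "spectral" else t0 + s * dt
        end = t0 + (e - 0.5) * dt if series.stream == "spectral" else t0 + e * dt
        out.append(TimeRange(max(start, 0.0), end))
    return out


def _intersect(a: List[TimeRange], b: List[TimeRange]) -> List[TimeRange]:
    out = []
    for ra in a:
        for rb in b:
            lo = max(ra.start_s, rb.start_s)
            hi = min(ra.end_s, rb.end_s)
            if hi > lo:
                out.append(TimeRange(lo, hi))
    return out


def detect_seizure_envelopes(
    trace,
    sample_rate_hz: float,
    params: SeizureParams = SeizureParams(),
    channel: Optional[ChannelID] = None,
) -> List[SeizureEnvelope]:
    """Full per-channel pipeline: baseline → spectral & LFP continuity →
    overlap ≥ ``min_envelope_s`` → refined start times."""
    x = np.asarray(trace, dtype=np.float64)
    baseline = select_baseline(x, sample_rate_hz, params)
    if baseline.voltage_sd_mv == 0 or baseline.spectral_sd == 0:
        warnings.warn("degenerate channel (zero baseline SD); skipping detection")
        return []
    frame = stft_magnitude(x, sample_rate_hz, segment_s=params.stft_segment_s)
    spectral = detect_spectral_activity(frame, baseline, params)
    lfp = detect_lfp_activity(x, sample_rate_hz, baseline, params)
    spec_regions = continuity_filter(
        spectral, params.window_short_bins, params.window_long_bins, params
    )
    lfp_regions = continuity_filter(lfp, params.window_short, params.window_long, params)
    overlaps = [
        r for r in _intersect(spec_regions, lfp_regions)
        if r.duration_s >= params.min_envelope_s
    ]
    bin_s = params.stft_segment_s
    v_thresh = params.voltage_k * baseline.voltage_sd_mv
    above = np.abs(x - baseline.baseline_mv) > v_thresh
    spec_bin_starts = spectral.times - bin_s / 2.0  # left edge of each bin
    envelopes: List[SeizureEnvelope] = []
    for r in overlaps:
        # snap: first spectral-threshold crossing within [start - 1 bin, start]
        mask = (
            spectral.active
            & (spec_bin_starts >= r.start_s - bin_s - 1e-9)
            & (spec_bin_starts <= r.start_s + 1e-9)
        )
        idx = np.flatnonzero(mask)
        snapped = float(spec_bin_starts[idx[0]]) if idx.size else r.start_s
        # refine to the first suprathreshold voltage sample within +/- 1 bin
        # that begins *sustained* activity (an isolated interictal spike in
        # the reach-back region must not define the onset)
        i0 = max(0, int(np.floor((snapped - bin_s) * sample_rate_hz)))
        i1 = min(x.size, int(np.ceil((snapped + bin_s) * sample_rate_hz)))
        hits = np.flatnonzero(above[i0:i1]) + i0
        bin_n = int(round(bin_s * sample_rate_hz))
        min_sustained = max(2, int(0.05 * bin_n))
        start = None
        for h in hits:
            if np.count_nonzero(above[h : h + bin_n]) >= min_sustained:
                start = h / sample_rate_hz
                break
        if start is None:
            start = hits[0] / sample_rate_hz if hits.size else snapped
        start = min(start, r.end_s - params.min_envelope_s)
        envelopes.append(
            SeizureEnvelope(channel=channel, start_s=float(start), end_s=float(r.end_s))
        )
    envelopes.sort(key=lambda e: e.start_s)
    if params.merge_gap_s > 0 and len(envelopes) > 1:
        out = [envelopes[0]]
        for env in envelopes[1:]:
            if env.start_s - out[-1].end_s < params.merge_gap_s:
                out[-1] = replace(out[-1], end_s=max(out[-1].end_s, env.end_s))
            else:
                out.append(env)
        envelopes = out
    return envelopes


def detect_recording_envelopes(
    recording: Recording,
    params: SeizureParams = SeizureParams(),
    channels: Optional[Sequence[ChannelID]] = None,
) -> Dict[ChannelID, List[SeizureEnvelope]]:
    """Run envelope detection on every (or the given) channel of a
    recording; degenerate channels yield empty lists with a warning."""
    result: Dict[ChannelID, List[SeizureEnvelope]] = {}
    for ch in channels if channels is not None else recording.channels:
        trace = recording.trace(ch)
        try:
            result[ch] = detect_seizure_envelopes(
                trace, recording.sample_rate_hz, params, channel=ch
            )
        except ValidationError:
            warnings.warn(f"channel {ch}: degenerate trace, skipped")
            result[ch] = []
    return result


def _earliest_start(
    envelopes: Dict[ChannelID, List[SeizureEnvelope]], window: TimeRange
) -> Dict[ChannelID, float]:
    """Earliest envelope start per channel among envelopes intersecting
    the window."""
    firsts = {}
    for ch, envs in envelopes.items():
        starts = [
            max(e.start_s, window.start_s)
            for e in envs
            if e.end_s > window.start_s and e.start_s < window.end_s
        ]
        if starts:
            firsts[ch] = min(starts)
    return firsts


def find_initiators(
    envelopes: Dict[ChannelID, List[SeizureEnvelope]],
    window: TimeRange,
    bin_s: float = 1.0,
) -> Set[ChannelID]:
    """Channels whose earliest envelope start falls in the same STFT bin
    as the globally earliest start ("similar start times")."""
    firsts = _earliest_start(envelopes, window)
    if not firsts:
        raise ValidationError("no seizure envelopes intersect the window")
    t_min = min(firsts.values())
    bin_min = int(np.floor(t_min / bin_s))
    return {ch for ch, t in firsts.items() if int(np.floor(t / bin_s)) == bin_min}


def max_spread_distance(
    participating: Set[ChannelID],
    initiators: Set[ChannelID],
    pitch_um: float,
) -> float:
    """Maximum Euclidean grid distance (× pitch) from any initiator to any
    participating channel, in micrometers."""
    if not participating or not initiators:
        raise ValidationError("participating and initiator sets must be non-empty")
    if not initiators <= participating:
        raise ValidationError("initiators must be a subset of participating channels")
    return max(
        i.distance_to(p, pitch_um) for i in initiators for p in participating
    )


def sle_durations(
    envelopes: Dict[ChannelID, List[SeizureEnvelope]], window: TimeRange
) -> Tuple[Dict[ChannelID, float], float, float]:
    """Per-channel SLE durations (end − start) within the window, and
    their mean and max over participating channels."""
    durations = {}
    for ch, envs in envelopes.items():
        total = sum(
            min(e.end_s, window.end_s) - max(e.start_s, window.start_s)
            for e in envs
            if e.end_s > window.start_s and e.start_s < window.end_s
        )
        if total > 0:
            durations[ch] = total
    if not durations:
        raise ValidationError("no envelopes in window")
    vals = list(durations.values())
    return durations, float(np.mean(vals)), float(np.max(vals))


def propagation_speed(
    envelopes: Dict[ChannelID, List[SeizureEnvelope]],
    window: TimeRange,
    initiators: Set[ChannelID],
    max_distance_um: float,
    pitch_um: float,
    lag_stat: str = "farthest",
) -> Tuple[Optional[float], bool]:
    """Seizure propagation speed in µm/s.

    Speed = max spread distance / mean onset lag, where onset lags are
    start-time differences relative to the earliest start.  With
    ``lag_stat="farthest"`` (default) the mean is over the maximally
    distant participating channel(s) — the channels that define the
    spread distance; with ``"mean"`` it is over all non-initiator
    participants.  Returns ``(speed, defined)``; the speed is undefined
    when there are no non-initiator participants or the mean lag is zero.
    """
    firsts = _earliest_start(envelopes, window)
    if not firsts:
        raise ValidationError("no envelopes in window")
    t_init = min(firsts.values())
    non_init = {ch: t for ch, t in firsts.items() if ch not in initiators}
    if not non_init:
        return None, False
    if lag_stat == "mean":
        lags = np.array([t - t_init for t in non_init.values()])
    else:
        dist = {
            ch: max(i.distance_to(ch, pitch_um) for i in initiators)
            for ch in firsts
        }
        dmax = max(dist.values())
        farthest = [ch for ch, d in dist.items() if d >= dmax - 1e-9 and ch not in initiators]
        if not farthest:
            return None, False
        lags = np.array([firsts[ch] - t_init for ch in farthest])
    mean_lag = float(np.mean(lags))
    if mean_lag <= 0:
        return None, False
    return max_distance_um / mean_lag, True


def sle_group_metrics(
    envelopes: Dict[ChannelID, List[SeizureEnvelope]],
    group: ChannelGroup,
    window: TimeRange,
    pitch_um: float,
    params: SeizureParams = SeizureParams(),
) -> SLEGroupMetrics:
    """Network metrics for one group over an analysis window.

    Participating channels are the group members with an envelope
    intersecting the window; a group with no participants yields a
    "no SLE" result with undefined metrics.
    """
    if not group.members:
        raise ValidationError("empty group")
    group_envs = {ch: envelopes.get(ch, []) for ch in group.members}
    firsts = _earliest_start(group_envs, window)
    participating = set(firsts)
    if not participating:
        return SLEGroupMetrics(
            group=group,
            window=window,
            initiators=set(),
            participating=set(),
            max_distance_um=None,
            mean_duration_s=None,
            max_duration_s=None,
            propagation_speed_um_s=None,
            speed_defined=False,
        )
    initiators = find_initiators(group_envs, window, bin_s=params.initiator_bin_s)
    max_dist = max_spread_distance(participating, initiators, pitch_um)
    _, mean_dur, max_dur = sle_durations(group_envs, window)
    speed, defined = propagation_speed(
        group_envs, window, initiators, max_dist, pitch_um, lag_stat=params.lag_stat
    )
    return SLEGroupMetrics(
        group=group,
        window=window,
        initiators=initiators,
        participating=participating,
        max_distance_um=max_dist,
        mean_duration_s=mean_dur,
        max_duration_s=max_dur,
        propagation_speed_um_s=speed,
        speed_defined=defined,
    )
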