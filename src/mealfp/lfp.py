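"""LFP peak detection, per-channel metrics, group summaries, and rasters.

A *peak* is a strict local extremum whose amplitude relative to the
channel baseline reaches the detection threshold and whose full width at
the baseline level reaches the minimum duration.  The baseline is the
median of the analysed trace segment, which is robust to sparse activity.

Width rule: the peak's width is the distance between the baseline
crossings on either side of the apex (trace edges when the trace never
returns to baseline).  The width of a given apex is therefore independent
of the detection threshold, which makes the detected peak count monotone
non-increasing in both the threshold and the minimum duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dsp import BandDefinition, band_power
from .recording import ChannelGroup, ChannelID, TimeRange, ValidationError


@dataclass(frozen=True)
class DetectionParams:
    """Threshold/duration rule for LFP peak marking.

    Defaults follow the analysis platform's defaults: 0.07 mV amplitude
    from baseline sustained over at least 0.02 s, both polarities.
    """

    threshold_mv: float = 0.07
    min_duration_s: float = 0.02
    polarity: str = "both"  # "positive" | "negative" | "both"

    def __post_init__(self) -> None:
        if self.threshold_mv <= 0:
            raise ValidationError("threshold_mv must be positive")
        if self.min_duration_s < 0:
            raise ValidationError("min_duration_s must be >= 0")
        if self.polarity not in ("positive", "negative", "both"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class LFPPeak:
    """A detected LFP event."""

    time_s: float  # apex time
    amplitude_mv: float  # |apex - baseline|
    width_s: float  # full width at the baseline level
    polarity: int = 1  # +1 maxima, -1 minima
    channel: Optional[ChannelID] = None


@dataclass
class ChannelMetrics:
    """Per-channel summary of detected LFP activity."""

    channel: ChannelID
    peak_count: int
    peak_count_per_s: float
    mean_amplitude_mv: Optional[float]
    mean_duration_s: Optional[float]
    band_powers: Dict[str, float]


@dataclass
class GroupSummary:
    """Group-level summary measures.

    ``active_channels`` counts channels with strictly more than
    ``active_min_peaks`` peaks in the analysed interval; the ``topN``
    statistics are computed over the N most active channels (largest peak
    count, ties broken by lower linear index).
    """

    group: ChannelGroup
    total_channels: int
    active_channels: int
    total_peak_count_per_s: float
    topN_peak_count_per_s: Optional[float]
    topN_mean_amplitude_mv: Optional[float]
    topN_mean_duration_s: Optional[float]
    N: int = 20


def _one_polarity_peaks(
    x: np.ndarray,
    sample_rate_hz: float,
    baseline: float,
    threshold_mv: float,
    min_duration_s: float,
    sign: int,
) -> List[Tuple[int, float, float]]:
    """(apex index, amplitude, width) for one polarity, vectorized."""
    y = x if sign > 0 else -x
    b = baseline if sign > 0 else -baseline
    if y.size < 3:
        return []
    interior = y[1:-1]
    apex = np.flatnonzero((interior > y[:-2]) & (interior > y[2:])) + 1
    if apex.size == 0:
        return []
    amp = y[apex] - b
    keep = amp >= threshold_mv
    apex, amp = apex[keep], amp[keep]
    if apex.size == 0:
        return []
    below = np.flatnonzero(y <= b)
    pos = np.searchsorted(below, apex)
    left = np.where(pos > 0, below[np.maximum(pos - 1, 0)], 0)
    right = np.where(pos < below.size, below[np.minimum(pos, below.size - 1)], y.size - 1)
    width = (right - left) / sample_rate_hz
    keep = width >= min_duration_s
    return [
        (int(i), float(a), float(w))
        for i, a, w in zip(apex[keep], amp[keep], width[keep])
    ]


def detect_lfp_peaks(
    trace,
    sample_rate_hz: float,
    params: DetectionParams = DetectionParams(),
    baseline: Optional[float] = None,
) -> List[LFPPeak]:
    """Detect LFP peaks by the threshold/duration rule.

    Maxima and minima are detected separately and merged; when two
    opposite-polarity apexes fall within ``min_duration_s`` of each other
    (the two phases of one biphasic event) only the larger-amplitude one
    is kept.  No upper limit is placed on amplitude or width.  Peaks are
    returned sorted by time.
    """
    x = np.asarray(trace, dtype=np.float64)
    if sample_rate_hz <= 0:
        raise ValidationError("sample rate must be positive")
    if x.size < 3:
        return []
    if baseline is None:
        baseline = float(np.median(x))
    raw: List[Tuple[int, float, float, int]] = []
    if params.polarity in ("positive", "both"):
        raw += [
            (i, a, w, 1)
            for i, a, w in _one_polarity_peaks(
                x, sample_rate_hz, baseline, params.threshold_mv, params.min_duration_s, 1
            )
        ]
    if params.polarity in ("negative", "both"):
        raw += [
            (i, a, w, -1)
            for i, a, w in _one_polarity_peaks(
                x, sample_rate_hz, baseline, params.threshold_mv, params.min_duration_s, -1
            )
        ]
    raw.sort(key=lambda p: p[0])
    merged: List[Tuple[int, float, float, int]] = []
    for cand in raw:
        if (
            merged
            and cand[3] != merged[-1][3]
            and (cand[0] - merged[-1][0]) / sample_rate_hz < params.min_duration_s
        ):
            if cand[1] > merged[-1][1]:
                merged[-1] = cand
            continue
        merged.append(cand)
    return [
        LFPPeak(time_s=i / sample_rate_hz, amplitude_mv=a, width_s=w, polarity=s)
        for i, a, w, s in merged
    ]


def channel_metrics(
    peaks: Sequence[LFPPeak],
    trace,
    sample_rate_hz: float,
    time_range: TimeRange,
    bands: Optional[Sequence[BandDefinition]] = None,
    channel: Optional[ChannelID] = None,
) -> ChannelMetrics:
    """Per-channel metrics over an analysed window.

    ``trace`` is the segment corresponding to ``time_range``; peak times
    are relative to the segment start.  Mean amplitude/duration are
    undefined (None) when no peaks were detected.
    """
    x = np.asarray(trace, dtype=np.float64)
    duration = time_range.duration_s
    if x.size / sample_rate_hz < duration - 1.0 / sample_rate_hz - 1e-9:
        raise ValidationError("trace shorter than the requested time range")
    count = len(peaks)
    if count:
        mean_amp = float(np.mean([p.amplitude_mv for p in peaks]))
        mean_dur = float(np.mean([p.width_s for p in peaks]))
    else:
        mean_amp = mean_dur = None
    powers = band_power(x, sample_rate_hz, bands)
    if channel is None and count and peaks[0].channel is not None:
        channel = peaks[0].channel
    return ChannelMetrics(
        channel=channel,
        peak_count=count,
        peak_count_per_s=count / duration,
        mean_amplitude_mv=mean_amp,
        mean_duration_s=mean_dur,
        band_powers=powers,
    )


def group_summary(
    metrics: Sequence[ChannelMetrics],
    group: ChannelGroup,
    duration_s: float,
    N: int = 20,
    active_min_peaks: int = 20,
) -> GroupSummary:
    """Summary measures for one channel group.

    A channel is *active* when its peak count is strictly greater than
    ``active_min_peaks``.  Top-N statistics are computed over the
    min(N, active channels) channels with the largest peak counts; the
    group mean amplitude/duration is the mean of per-channel means over
    those channels.
    """
    if not group.members:
        raise ValidationError("empty group")
    for m in metrics:
        if m.channel not in group.members:
            raise ValidationError(f"channel {m.channel} not in group {group.name!r}")
    total = len(group.members)
    active = [m for m in metrics if m.peak_count > active_min_peaks]
    total_rate = sum(m.peak_count for m in metrics) / duration_s
    top = sorted(active, key=lambda m: (-m.peak_count, m.channel.linear_index))[:N]
    if top:
        top_rate = sum(m.peak_count for m in top) / duration_s / len(top)
        amps = [m.mean_amplitude_mv for m in top if m.mean_amplitude_mv is not None]
        durs = [m.mean_duration_s for m in top if m.mean_duration_s is not None]
        top_amp = float(np.mean(amps)) if amps else None
        top_dur = float(np.mean(durs)) if durs else None
    else:
        top_rate = top_amp = top_dur = None
    return GroupSummary(
        group=group,
        total_channels=total,
        active_channels=len(active),
        total_peak_count_per_s=total_rate,
        topN_peak_count_per_s=top_rate,
        topN_mean_amplitude_mv=top_amp,
        topN_mean_duration_s=top_dur,
        N=N,
    )


@dataclass
class Raster:
    """Event raster: per-channel sorted event times plus a binned count
    matrix (channels ordered by linear index)."""

    channels: List[ChannelID]
    event_times: Dict[ChannelID, np.ndarray]
    bin_edges_s: np.ndarray
    counts: np.ndarray  # (n_channels, n_bins)


def build_raster(
    peaks_by_channel: Dict[ChannelID, Sequence[LFPPeak]],
    time_range: TimeRange,
    bin_s: float = 1.0,
) -> Raster:
    """Build the all-channel raster; binned counts conserve total events."""
    if bin_s <= 0:
        raise ValidationError("bin_s must be positive")
    channels = sorted(peaks_by_channel, key=lambda c: c.linear_index)
    n_bins = int(np.ceil(time_range.duration_s / bin_s))
    edges = time_range.start_s + np.arange(n_bins + 1) * bin_s
    counts = np.zeros((len(channels), n_bins), dtype=int)
    times: Dict[ChannelID, np.ndarray] = {}
    for i, ch in enumerate(channels):
        t = np.sort([p.time_s for p in peaks_by_channel[ch]])
        inside = t[(t >= time_range.start_s) & (t < time_range.end_s)]
        times[ch] = inside
        if inside.size:
            idx = np.minimum(
                ((inside - time_range.start_s) / bin_s).astype(int), n_bins - 1
            )
            np.add.at(counts[i], idx, 1)
    return Raster(channels=channels, event_times=times, bin_edges_s=edges, counts=counts)
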