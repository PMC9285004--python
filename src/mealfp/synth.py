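"""Seedable synthetic MEA recordings with ground truth.

Emulates the phenomenology of a low-Mg²⁺ brain-slice recording on a
grid-addressed array: Gaussian background noise, sparse biphasic
interictal spikes, and a seizure-like event that starts at a focal origin
and spreads radially at a fixed speed.  Each channel's SLE burst is a
large biphasic onset discharge followed by a 2 s amplitude-ramped
sustained oscillation carrying Poisson "spike rider" transients — so both
the spectral (sustained power) and the LFP (discrete suprathreshold
peaks) branches of the detector are exercised.

A single master seed drives everything; per-channel substreams are
derived deterministically from (seed, linear index), so the output is
independent of channel iteration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .recording import ChannelID, Recording, ValidationError


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario."""

    rows: int = 20
    cols: int = 20
    duration_s: float = 180.0
    sample_rate_hz: float = 300.0
    noise_sd_mv: float = 0.02
    spike_rate_hz: float = 0.0  # interictal spikes per channel
    spike_amplitude_mv: float = 0.15
    spike_width_s: float = 0.05
    sle_origin: Optional[ChannelID] = ChannelID(3, 3)
    sle_onset_s: float = 90.0
    sle_speed_um_s: float = 1000.0
    sle_duration_s: float = 30.0
    sle_osc_freq_hz: float = 8.0
    sle_amplitude_mv: float = 0.5
    sle_ramp_s: float = 2.0
    pitch_um: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.rows > 64 or self.cols > 64:
            raise ValidationError("grid extent must be within 1..64")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValidationError("duration and sample rate must be positive")
        if self.noise_sd_mv < 0 or self.spike_rate_hz < 0:
            raise ValidationError("rates and noise SD must be non-negative")
        if self.sle_origin is not None:
            if self.sle_origin.row > self.rows or self.sle_origin.col > self.cols:
                raise ValidationError("SLE origin outside the configured grid")
            if self.sle_speed_um_s <= 0 or self.sle_duration_s <= 0:
                raise ValidationError("SLE speed and duration must be positive")

    def channels(self) -> List[ChannelID]:
        return [
            ChannelID(r, c)
            for r in range(1, self.rows + 1)
            for c in range(1, self.cols + 1)
        ]


@dataclass
class GroundTruth:
    """Event log of the injected activity."""

    origin: Optional[ChannelID] = None
    speed_um_s: Optional[float] = None
    onset_s: Dict[ChannelID, float] = field(default_factory=dict)
    offset_s: Dict[ChannelID, float] = field(default_factory=dict)
    spike_times_s: Dict[ChannelID, np.ndarray] = field(default_factory=dict)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "origin": [self.origin.row, self.origin.col] if self.origin else None,
            "speed_um_s": self.speed_um_s,
            "onset_s": {str(c.linear_index): t for c, t in sorted(
                self.onset_s.items(), key=lambda kv: kv[0].linear_index)},
            "offset_s": {str(c.linear_index): t for c, t in sorted(
                self.offset_s.items(), key=lambda kv: kv[0].linear_index)},
            "spike_times_s": {str(c.linear_index): list(map(float, t)) for c, t in sorted(
                self.spike_times_s.items(), key=lambda kv: kv[0].linear_index)},
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _channel_rng(seed: int, channel: ChannelID, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, channel.linear_index))
    )


def generate_background(config: ScenarioConfig) -> Recording:
    """Per-channel independent Gaussian noise; same seed → identical output."""
    channels = config.channels()
    n = int(round(config.duration_s * config.sample_rate_hz))
    traces = np.empty((len(channels), n), dtype=np.float32)
    for i, ch in enumerate(channels):
        rng = _channel_rng(config.seed, ch, 0)
        traces[i] = rng.normal(0.0, config.noise_sd_mv, size=n)
    return Recording(
        channels=channels,
        traces=traces,
        sample_rate_hz=config.sample_rate_hz,
        pitch_um=config.pitch_um,
    )


def _add_biphasic(
    trace: np.ndarray,
    sample_rate_hz: float,
    center: float,
    amplitude: float,
    width: float,
) -> None:
    """Add a biphasic transient (positive then negative half-sine spanning
    ``width`` seconds) in place; only the affected samples are touched."""
    t0 = center - width / 2
    i0 = max(0, int(np.ceil(t0 * sample_rate_hz)))
    i1 = min(trace.size, int(np.floor((t0 + width) * sample_rate_hz)) + 1)
    if i1 <= i0:
        return
    rel = (np.arange(i0, i1) / sample_rate_hz - t0) / width
    trace[i0:i1] += amplitude * np.sin(2 * np.pi * rel)


def inject_interictal_spikes(
    recording: Recording, config: ScenarioConfig
) -> Tuple[Recording, GroundTruth]:
    """Add seeded-Poisson biphasic spikes per channel; returns the truth log."""
    if config.spike_width_s * recording.sample_rate_hz < 2:
        raise ValidationError("spike width must span at least 2 samples")
    expected = config.spike_rate_hz * recording.duration_s
    if config.spike_rate_hz * config.spike_width_s > 0.5:
        raise ValidationError("spike rate too high for the spike width")
    truth = GroundTruth()
    traces = recording.traces.astype(np.float64)
    margin = config.spike_width_s
    for i, ch in enumerate(recording.channels):
        rng = _channel_rng(config.seed, ch, 1)
        n_spikes = rng.poisson(expected)
        times = np.sort(
            rng.uniform(margin, recording.duration_s - margin, size=n_spikes)
        )
        truth.spike_times_s[ch] = times
        for tc in times:
            _add_biphasic(
                traces[i], recording.sample_rate_hz, tc,
                config.spike_amplitude_mv, config.spike_width_s,
            )
    out = Recording(
        channels=list(recording.channels),
        traces=traces.astype(np.float32),
        sample_rate_hz=recording.sample_rate_hz,
        pitch_um=recording.pitch_um,
        start_time_s=recording.start_time_s,
    )
    return out, truth


def _add_burst(
    trace: np.ndarray,
    sample_rate_hz: float,
    onset: float,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> None:
    """Add one channel's SLE waveform starting at ``onset`` in place:
    onset discharge + ramped oscillation + Poisson spike riders."""
    dur = config.sle_duration_s
    i0 = max(0, int(np.ceil(onset * sample_rate_hz)))
    i1 = min(trace.size, int(np.floor((onset + dur) * sample_rate_hz)) + 1)
    if i1 > i0:
        rel = np.arange(i0, i1) / sample_rate_hz - onset
        env = np.clip(rel / max(config.sle_ramp_s, 1e-9), 0.0, 1.0)
        trace[i0:i1] += (
            config.sle_amplitude_mv * env
            * np.sin(2 * np.pi * config.sle_osc_freq_hz * rel)
        )
    # sharp onset discharge marks the exact start
    _add_biphasic(trace, sample_rate_hz, onset + 0.02, 2.0 * config.sle_amplitude_mv, 0.04)
    if dur <= 0.3:
        return
    n_riders = rng.poisson(1.0 * dur)
    rider_times = onset + np.sort(rng.uniform(0.1, dur - 0.1, size=n_riders))
    for tc in rider_times:
        _add_biphasic(trace, sample_rate_hz, tc, config.sle_amplitude_mv, 0.05)


def inject_traveling_sle(
    recording: Recording, config: ScenarioConfig
) -> Tuple[Recording, GroundTruth]:
    """Add a radially traveling SLE: a channel at grid distance d µm from
    the origin starts at ``sle_onset_s + d / sle_speed_um_s``."""
    if config.sle_origin is None:
        return recording, GroundTruth()
    origin = config.sle_origin
    max_lag = max(
        origin.distance_to(ch, config.pitch_um) for ch in recording.channels
    ) / config.sle_speed_um_s
    if config.sle_onset_s + config.sle_duration_s + max_lag > recording.duration_s:
        raise ValidationError("SLE wave exits the recording window")
    truth = GroundTruth(origin=origin, speed_um_s=config.sle_speed_um_s)
    traces = recording.traces.astype(np.float64)
    for i, ch in enumerate(recording.channels):
        lag = origin.distance_to(ch, config.pitch_um) / config.sle_speed_um_s
        onset = config.sle_onset_s + lag
        truth.onset_s[ch] = onset
        truth.offset_s[ch] = onset + config.sle_duration_s
        rng = _channel_rng(config.seed, ch, 2)
        _add_burst(traces[i], recording.sample_rate_hz, onset, config, rng)
    out = Recording(
        channels=list(recording.channels),
        traces=traces.astype(np.float32),
        sample_rate_hz=recording.sample_rate_hz,
        pitch_um=recording.pitch_um,
        start_time_s=recording.start_time_s,
    )
    return out, truth


def generate_scenario(config: ScenarioConfig) -> Tuple[Recording, GroundTruth]:
    """Background noise + interictal spikes + traveling SLE (if configured)."""
    rec = generate_background(config)
    rec, spike_truth = inject_interictal_spikes(rec, config)
    rec, sle_truth = inject_traveling_sle(rec, config)
    sle_truth.spike_times_s = spike_truth.spike_times_s
    return rec, sle_truth
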