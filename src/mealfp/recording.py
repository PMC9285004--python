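"""Domain model for grid-addressed multichannel MEA recordings.

Channels live on a fixed 64×64 electrode grid (1-based rows/columns,
linear index ``(row - 1) * 64 + col`` in 1..4096).  Voltages are in mV,
times in seconds from the start of the recording, and time intervals are
half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

GRID_SIZE = 64
N_CHANNELS = GRID_SIZE * GRID_SIZE
DEFAULT_PITCH_UM = 60.0


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True, order=True)
class ChannelID:
    """Electrode position on the 64×64 grid (1-based row and column)."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (1 <= self.row <= GRID_SIZE and 1 <= self.col <= GRID_SIZE):
            raise ValidationError(
                f"channel ({self.row}, {self.col}) outside the "
                f"{GRID_SIZE}x{GRID_SIZE} grid"
            )

    @property
    def linear_index(self) -> int:
        """1-based linear index, row-major: (row - 1) * 64 + col."""
        return (self.row - 1) * GRID_SIZE + self.col

    @classmethod
    def from_linear(cls, linear_index: int) -> "ChannelID":
        if not (1 <= linear_index <= N_CHANNELS):
            raise ValidationError(f"linear index {linear_index} outside 1..{N_CHANNELS}")
        row, col = divmod(linear_index - 1, GRID_SIZE)
        return cls(row + 1, col + 1)

    def distance_to(self, other: "ChannelID", pitch_um: float = DEFAULT_PITCH_UM) -> float:
        """Euclidean grid distance scaled by the electrode pitch (µm)."""
        return float(np.hypot(self.row - other.row, self.col - other.col)) * pitch_um


@dataclass(frozen=True)
class TimeRange:
    """Half-open time interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0 or not self.end_s > self.start_s:
            raise ValidationError(
                f"invalid time range [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class ChannelGroup:
    """Named set of channels analysed together (e.g. a brain region)."""

    name: str
    members: frozenset

    def __init__(self, name: str, members: Iterable[ChannelID]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))
        if not self.members:
            raise ValidationError(f"channel group {name!r} is empty")

    def sorted_members(self) -> list[ChannelID]:
        return sorted(self.members, key=lambda c: c.linear_index)


@dataclass
class Recording:
    """Multichannel voltage recording.

    ``traces`` is a (channels × samples) array in mV; row *i* belongs to
    ``channels[i]``.
    """

    channels: list[ChannelID]
    traces: np.ndarray
    sample_rate_hz: float
    pitch_um: float = DEFAULT_PITCH_UM
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float32)
        if self.traces.ndim != 2:
            raise ValidationError("traces must be a 2-D (channels x samples) array")
        if len(self.channels) != self.traces.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channels but {self.traces.shape[0]} trace rows"
            )
        if self.traces.shape[1] < 1:
            raise ValidationError("recording must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.pitch_um <= 0:
            raise ValidationError("pitch_um must be positive")
        seen = [c.linear_index for c in self.channels]
        if len(set(seen)) != len(seen):
            raise ValidationError("duplicate channel linear_index in recording")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (absolute, includes start_time_s)."""
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz

    def index_of(self, channel: ChannelID) -> int:
        for i, c in enumerate(self.channels):
            if c == channel:
                return i
        raise KeyError(f"channel {channel} not in recording")

    def trace(self, channel: ChannelID) -> np.ndarray:
        return self.traces[self.index_of(channel)]

    def subset(
        self,
        channels: Optional[Iterable[ChannelID]] = None,
        time_range: Optional[TimeRange] = None,
    ) -> "Recording":
        """In-memory channel/time subset with the same semantics as a
        selective :func:`mealfp.io.read_recording`."""
        traces = self.traces
        chans = list(self.channels)
        if channels is not None:
            wanted = set(channels)
            missing = wanted - set(chans)
            if missing:
                raise KeyError(f"channels not in recording: {sorted(missing)}")
            idx = [i for i, c in enumerate(chans) if c in wanted]
            chans = [chans[i] for i in idx]
            traces = traces[idx]
        start = self.start_time_s
        if time_range is not None:
            if time_range.end_s - self.start_time_s > self.duration_s + 1e-9:
                raise ValidationError("time range extends past end of recording")
            i0 = int(round((time_range.start_s - self.start_time_s) * self.sample_rate_hz))
            i1 = int(round((time_range.end_s - self.start_time_s) * self.sample_rate_hz))
            traces = traces[:, i0:i1]
            start = time_range.start_s
        return Recording(
            channels=chans,
            traces=traces.copy(),
            sample_rate_hz=self.sample_rate_hz,
            pitch_um=self.pitch_um,
            start_time_s=start,
        )
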