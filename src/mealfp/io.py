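"""HDF5 recording reader/writer, downsampling, and CSV metric export.

The HDF5 layout is open and documented (the vendor dialect used by
commercial MEA acquisition software is proprietary, so this package
defines its own; a vendor adapter can convert into it):

    /recording/traces          float32, channels x samples, mV
    /recording/sample_rate_hz  scalar, Hz
    /recording/pitch_um        scalar, micrometers
    /recording/start_time_s    scalar, seconds
    /recording/channels        table with columns row, col, linear_index

Selective reads index directly into the traces dataset so that a
channel/time subset never loads unrequested channels' full traces.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import h5py
import numpy as np
from scipy.signal import fftconvolve, firwin

from .recording import ChannelID, ChannelGroup, Recording, TimeRange, ValidationError

_CHANNEL_DTYPE = np.dtype(
    [("row", "<i4"), ("col", "<i4"), ("linear_index", "<i4")]
)


class FormatError(IOError):
    """Raised when an HDF5 file does not conform to the documented layout."""


def write_recording(recording: Recording, path) -> Path:
    """Write a :class:`Recording` to the documented HDF5 layout."""
    path = Path(path)
    table = np.array(
        [(c.row, c.col, c.linear_index) for c in recording.channels],
        dtype=_CHANNEL_DTYPE,
    )
    with h5py.File(path, "w") as f:
        grp = f.create_group("recording")
        grp.create_dataset("traces", data=recording.traces.astype(np.float32))
        grp.create_dataset("sample_rate_hz", data=float(recording.sample_rate_hz))
        grp.create_dataset("pitch_um", data=float(recording.pitch_um))
        grp.create_dataset("start_time_s", data=float(recording.start_time_s))
        grp.create_dataset("channels", data=table)
    return path


def read_recording(
    path,
    channels: Optional[Iterable[ChannelID]] = None,
    time_range: Optional[TimeRange] = None,
) -> Recording:
    """Read a recording, optionally restricted to a channel set and/or a
    half-open time window.

    Raises ``FileNotFoundError`` for a missing file, ``KeyError`` when a
    requested channel is absent and :class:`FormatError` for files that do
    not follow the documented layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        try:
            grp = f["recording"]
            traces_ds = grp["traces"]
            rate = float(grp["sample_rate_hz"][()])
            pitch = float(grp["pitch_um"][()])
            start0 = float(grp["start_time_s"][()])
            table = grp["channels"][()]
        except KeyError as exc:
            raise FormatError(f"{path} does not follow the mealfp HDF5 layout: {exc}")
        file_channels = [ChannelID(int(r["row"]), int(r["col"])) for r in table]
        if channels is not None:
            wanted = set(channels)
            missing = wanted - set(file_channels)
            if missing:
                raise KeyError(f"channels not present in {path}: {sorted(missing)}")
            idx = [i for i, c in enumerate(file_channels) if c in wanted]
        else:
            idx = list(range(len(file_channels)))

        n_samples = traces_ds.shape[1]
        start_time = start0
        if time_range is not None:
            i0 = int(round((time_range.start_s - start0) * rate))
            i1 = int(round((time_range.end_s - start0) * rate))
            if i0 < 0 or i1 > n_samples:
                raise ValidationError(
                    f"time range [{time_range.start_s}, {time_range.end_s}) outside file"
                )
            start_time = time_range.start_s
        else:
            i0, i1 = 0, n_samples
        # h5py requires sorted, unique row selections
        traces = traces_ds[np.asarray(idx, dtype=int), i0:i1]
    return Recording(
        channels=[file_channels[i] for i in idx],
        traces=traces,
        sample_rate_hz=rate,
        pitch_um=pitch,
        start_time_s=start_time,
    )


def downsample_recording(recording: Recording, target_rate_hz: float) -> Recording:
    """Anti-alias filter and decimate to (approximately) ``target_rate_hz``.

    The decimation factor is ``q = floor(source / target)``; the achieved
    rate ``source / q`` is reported on the returned recording and may
    differ from the request for non-integer ratios.  The anti-alias filter
    is a zero-phase (symmetric) Hamming-window FIR low-pass with cutoff
    0.4 × target rate.
    """
    if target_rate_hz <= 0:
        raise ValidationError("target rate must be positive")
    if target_rate_hz > recording.sample_rate_hz:
        raise ValidationError(
            f"target rate {target_rate_hz} Hz above source rate "
            f"{recording.sample_rate_hz} Hz"
        )
    q = int(recording.sample_rate_hz // target_rate_hz)
    if q == 1:
        return Recording(
            channels=list(recording.channels),
            traces=recording.traces.copy(),
            sample_rate_hz=recording.sample_rate_hz,
            pitch_um=recording.pitch_um,
            start_time_s=recording.start_time_s,
        )
    achieved = recording.sample_rate_hz / q
    n = recording.n_samples
    numtaps = 60 * q + 1
    max_taps = 2 * ((n - 1) // 2) + 1  # keep the kernel shorter than the trace
    numtaps = min(numtaps, max_taps)
    cutoff = 0.4 * achieved
    h = firwin(numtaps, cutoff, fs=recording.sample_rate_hz)
    half = numtaps // 2
    x = recording.traces.astype(np.float64)
    padded = np.pad(x, ((0, 0), (half, half)), mode="reflect")
    filtered = fftconvolve(padded, h[None, :], mode="valid", axes=1)
    out = filtered[:, ::q][:, : n // q].astype(np.float32)
    return Recording(
        channels=list(recording.channels),
        traces=out,
        sample_rate_hz=achieved,
        pitch_um=recording.pitch_um,
        start_time_s=recording.start_time_s,
    )


CSV_COLUMNS = [
    "group_number",
    "channel_number",
    "lfp_peak_count",
    "mean_peak_amplitude_mv",
    "mean_peak_duration_s",
    "power_delta_v2hz",
    "power_theta_v2hz",
    "power_alpha_v2hz",
    "power_beta_v2hz",
    "power_gamma_v2hz",
    "time_start_s",
    "time_end_s",
]

_BAND_ORDER = ["delta", "theta", "alpha", "beta", "gamma"]


def _fmt(x) -> str:
    if x is None:
        return ""
    return format(float(x), ".9g")


def export_channel_metrics_csv(
    metrics: Sequence,
    groups: Sequence[ChannelGroup],
    time_range: TimeRange,
    path,
) -> Path:
    """Write one row per channel: peak count, mean amplitude/duration,
    band powers, channel and group number, plus the analysed time range.

    Channels with zero peaks get empty amplitude/duration fields (an
    explicit 0 would bias group means).  Rows are ordered by group then
    linear index, so re-export of the same inputs is byte-identical.
    """
    path = Path(path)
    group_of = {}
    for gi, g in enumerate(groups, start=1):
        for c in g.members:
            if c in group_of:
                raise ValidationError(
                    f"channel {c} appears in more than one group"
                )
            group_of[c] = gi
    rows = []
    for m in metrics:
        if m.channel not in group_of:
            raise ValidationError(f"channel {m.channel} is in no listed group")
        bp = m.band_powers or {}
        rows.append(
            (
                group_of[m.channel],
                m.channel.linear_index,
                [
                    str(group_of[m.channel]),
                    str(m.channel.linear_index),
                    str(m.peak_count),
                    _fmt(m.mean_amplitude_mv),
                    _fmt(m.mean_duration_s),
                    *(_fmt(bp.get(b)) for b in _BAND_ORDER),
                    _fmt(time_range.start_s),
                    _fmt(time_range.end_s),
                ],
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="", encoding="utf-8") as f:
        writer = csv.writer(f)
        writer.writerow(CSV_COLUMNS)
        for _, _, fields in rows:
            writer.writerow(fields)
    return path
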