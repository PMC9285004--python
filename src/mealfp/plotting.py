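"""Static plot generation (raster plots and seizure maps).

Plots are written as PNG files with the embedded creation date stripped
so that repeated runs produce identical bytes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .lfp import Raster
from .recording import ChannelID
from .seizure import SLEGroupMetrics


def plot_raster(raster: Raster, path, title: str = "LFP raster") -> Path:
    """Channels (by linear index) × time event raster."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(10, 6))
    positions = [raster.event_times[ch] for ch in raster.channels]
    if any(len(p) for p in positions):
        ax.eventplot(positions, colors="black", linewidths=0.5, lineoffsets=1, linelengths=0.9)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel (ordered by linear index)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path


def plot_seizure_map(
    metrics: SLEGroupMetrics,
    all_channels: Iterable[ChannelID],
    path,
) -> Path:
    """Grid map: participating channels red, non-participating in the
    group blue, unselected gray, initiators green."""
    path = Path(path)
    all_channels = list(all_channels)
    fig, ax = plt.subplots(figsize=(6, 6))

    def scatter(chs, color, label, size=30, zorder=2):
        chs = list(chs)
        if chs:
            ax.scatter(
                [c.col for c in chs], [c.row for c in chs],
                c=color, s=size, label=label, zorder=zorder,
            )

    group = set(metrics.group.members)
    outside = [c for c in all_channels if c not in group]
    non_part = group - metrics.participating
    part = metrics.participating - metrics.initiators
    scatter(outside, "lightgray", "unselected", size=12, zorder=1)
    scatter(non_part, "tab:blue", "no SLE")
    scatter(part, "tab:red", "SLE")
    scatter(metrics.initiators, "tab:green", "initiation", size=60, zorder=3)
    ax.invert_yaxis()
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    title = f"group {metrics.group.name}"
    if metrics.max_distance_um is not None:
        title += f": spread {metrics.max_distance_um:.0f} um"
    if metrics.propagation_speed_um_s is not None:
        title += f", {metrics.propagation_speed_um_s:.0f} um/s"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path
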