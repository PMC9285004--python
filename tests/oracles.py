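"""Independent brute-force oracles used to cross-check the fast
implementations.  Everything here is deliberately naive (pure-Python
loops, O(N²) transforms) and shares no code with the package internals.
"""

from __future__ import annotations

import cmath
import statistics
from typing import List, Tuple


def brute_force_peaks(
    x,
    sample_rate_hz: float,
    threshold: float,
    min_duration: float,
    polarity: str = "both",
) -> List[Tuple[float, float, float, int]]:
    """Exhaustive local-extrema scan with the amplitude/width rules.

    Returns (time_s, amplitude, width_s, polarity) sorted by time, after
    the same opposite-polarity merge rule as the detector: walking the
    candidates in time order, an event of opposite polarity closer than
    ``min_duration`` to the previously kept event replaces it only if its
    amplitude is larger.
    """
    xs = [float(v) for v in x]
    n = len(xs)
    if n < 3:
        return []
    b = statistics.median(xs)
    signs = {"positive": [1], "negative": [-1], "both": [1, -1]}[polarity]
    candidates = []
    for sign in signs:
        y = [sign * v for v in xs]
        bb = sign * b
        for i in range(1, n - 1):
            if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
                continue
            amp = y[i] - bb
            if amp < threshold:
                continue
            left = i
            while left > 0 and y[left] > bb:
                left -= 1
            if y[left] > bb:
                left = 0
            right = i
            while right < n - 1 and y[right] > bb:
                right += 1
            if y[right] > bb:
                right = n - 1
            width = (right - left) / sample_rate_hz
            if width >= min_duration:
                candidates.append((i, amp, width, sign))
    candidates.sort(key=lambda p: p[0])
    kept: List[Tuple[int, float, float, int]] = []
    for cand in candidates:
        if kept:
            prev = kept[-1]
            if cand[3] != prev[3] and (cand[0] - prev[0]) / sample_rate_hz < min_duration:
                if cand[1] > prev[1]:
                    kept[-1] = cand
                continue
        kept.append(cand)
    return [(i / sample_rate_hz, a, w, s) for i, a, w, s in kept]


def naive_dft_amplitudes(x) -> List[float]:
    """O(N²) one-sided DFT amplitude spectrum with the sine-amplitude
    normalization (interior bins 2/N, DC and Nyquist 1/N)."""
    xs = [float(v) for v in x]
    n = len(xs)
    n_bins = n // 2 + 1
    amps = []
    for k in range(n_bins):
        acc = 0j
        for j, v in enumerate(xs):
            acc += v * cmath.exp(-2j * cmath.pi * k * j / n)
        scale = 1.0 / n if (k == 0 or (n % 2 == 0 and k == n_bins - 1)) else 2.0 / n
        amps.append(abs(acc) * scale)
    return amps


def naive_continuity_intervals(
    active,
    window_short: int,
    window_long: int,
    cutoff_short: float,
    cutoff_long: float,
) -> List[Tuple[int, int]]:
    """Direct O(N·W) recomputation of the two-window continuity rule.

    Returns merged (start, end) index intervals, end exclusive.  The
    centered moving mean replicates zero-padded 'same' convolution
    alignment: the window for index i spans [i - W // 2, i - W // 2 + W).
    """
    a = [1.0 if v else 0.0 for v in active]
    n = len(a)

    def density(i: int, w: int) -> float:
        start = i - w // 2
        return sum(a[j] for j in range(max(0, start), min(n, start + w))) / w

    in_region = [density(i, window_short) >= cutoff_short for i in range(n)]
    runs = []
    i = 0
    while i < n:
        if in_region[i]:
            j = i
            while j < n and in_region[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged:
            gap_ok = all(
                density(k, window_long) >= cutoff_long
                for k in range(merged[-1][1], run[0])
            )
            if gap_ok and run[0] > merged[-1][1]:
                merged[-1][1] = run[1]
                continue
        merged.append(run)
    return [(s, e) for s, e in merged]
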