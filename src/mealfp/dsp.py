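"""Digital filtering, amplitude spectra, STFT magnitudes, and band powers.

All traces are voltage series in mV sampled uniformly at
``sample_rate_hz``.  Spectra follow an amplitude normalization: a pure
sine of amplitude A mV produces a spectral peak of amplitude A mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt, welch

from .recording import ValidationError

FilterKind = str  # "low-pass" | "high-pass" | "band-pass"


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter request (applied zero-phase, forward-backward)."""

    kind: FilterKind
    cutoff_hz: Tuple[float, ...]
    order: int = 4

    def __init__(self, kind: str, cutoff_hz, order: int = 4):
        if kind not in ("low-pass", "high-pass", "band-pass"):
            raise ValidationError(f"unknown filter kind {kind!r}")
        cutoffs = tuple(float(c) for c in np.atleast_1d(cutoff_hz))
        if kind == "band-pass":
            if len(cutoffs) != 2 or not cutoffs[0] < cutoffs[1]:
                raise ValidationError("band-pass needs cutoffs (low, high) with low < high")
        elif len(cutoffs) != 1:
            raise ValidationError(f"{kind} takes a single cutoff")
        if any(c <= 0 for c in cutoffs):
            raise ValidationError("cutoffs must be positive")
        if order < 1:
            raise ValidationError("order must be >= 1")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "cutoff_hz", cutoffs)
        object.__setattr__(self, "order", order)


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency band [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValidationError(f"band {self.name}: need 0 <= lo < hi")


#: Conventional EEG bands; gamma is clipped to the Nyquist frequency of the
#: trace it is applied to.
DEFAULT_BANDS = [
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
]


@dataclass
class SpectrogramFrame:
    """Hann-windowed STFT magnitudes over consecutive segments.

    ``summed_magnitude[t]`` is the per-segment sum of all magnitude
    components at frequencies strictly below half the sampling rate — the
    spectral-activity signal used by the seizure detector.
    """

    times_s: np.ndarray  # segment centers, s
    freqs_hz: np.ndarray
    magnitude: np.ndarray  # (n_times, n_freqs), >= 0
    summed_magnitude: np.ndarray  # (n_times,)
    segment_s: float = 1.0

    @property
    def bin_s(self) -> float:
        """Spacing between consecutive segment centers."""
        if len(self.times_s) > 1:
            return float(self.times_s[1] - self.times_s[0])
        return self.segment_s


def _validate_cutoffs(spec: FilterSpec, sample_rate_hz: float) -> FilterSpec:
    nyq = sample_rate_hz / 2.0
    cutoffs = spec.cutoff_hz
    if spec.kind == "band-pass" and cutoffs[1] >= nyq:
        # Filtering "40-150 Hz" at a 300 Hz working rate puts the upper edge
        # exactly at Nyquist; clip it just below instead of failing.
        clipped = 0.99 * nyq
        if cutoffs[0] >= clipped:
            raise ValidationError("band-pass low cutoff at or above Nyquist")
        warnings.warn(
            f"band-pass upper edge {cutoffs[1]} Hz >= Nyquist {nyq} Hz; "
            f"clipped to {clipped:.6g} Hz"
        )
        return FilterSpec("band-pass", (cutoffs[0], clipped), spec.order)
    if any(c >= nyq for c in cutoffs):
        raise ValidationError(
            f"cutoff {max(cutoffs)} Hz at or above Nyquist {nyq} Hz"
        )
    return spec


def apply_filter(trace, sample_rate_hz: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth filtering; output has the input's length."""
    x = np.asarray(trace, dtype=np.float64)
    if sample_rate_hz <= 0:
        raise ValidationError("sample rate must be positive")
    spec = _validate_cutoffs(spec, sample_rate_hz)
    btype = {"low-pass": "lowpass", "high-pass": "highpass", "band-pass": "bandpass"}[spec.kind]
    wn = spec.cutoff_hz if len(spec.cutoff_hz) > 1 else spec.cutoff_hz[0]
    sos = butter(spec.order, wn, btype=btype, fs=sample_rate_hz, output="sos")
    return sosfiltfilt(sos, x)


def amplitude_spectrum(trace, sample_rate_hz: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum.

    Normalized so a pure sine of amplitude A maps to a peak of amplitude
    A (interior bins scaled by 2/N; DC and Nyquist by 1/N).
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.size < 2:
        raise ValidationError("trace must have at least 2 samples")
    if sample_rate_hz <= 0:
        raise ValidationError("sample rate must be positive")
    n = x.size
    spec = np.abs(np.fft.rfft(x)) / n
    amps = spec.copy()
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    return freqs, amps


def stft_magnitude(
    trace,
    sample_rate_hz: float,
    segment_s: float = 1.0,
    overlap_fraction: float = 0.0,
) -> SpectrogramFrame:
    """Hann-windowed STFT magnitudes over consecutive segments.

    With zero overlap (the default used for seizure detection) the number
    of time bins is exactly ``floor(duration / segment_s)``; a trailing
    partial segment is discarded.
    """
    x = np.asarray(trace, dtype=np.float64)
    if sample_rate_hz <= 0:
        raise ValidationError("sample rate must be positive")
    if not (0 <= overlap_fraction < 1):
        raise ValidationError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(segment_s * sample_rate_hz))
    if nperseg < 2:
        raise ValidationError("segment too short: need >= 2 samples per segment")
    if nperseg > x.size:
        raise ValidationError("segment longer than trace")
    hop = max(1, int(round(nperseg * (1.0 - overlap_fraction))))
    n_bins = (x.size - nperseg) // hop + 1
    window = np.hanning(nperseg)
    starts = np.arange(n_bins) * hop
    segments = np.lib.stride_tricks.sliding_window_view(x, nperseg)[starts]
    spec = np.abs(np.fft.rfft(segments * window, axis=1)) / nperseg
    spec[:, 1:] *= 2.0
    if nperseg % 2 == 0:
        spec[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / sample_rate_hz)
    below_nyq = freqs < sample_rate_hz / 2.0
    summed = spec[:, below_nyq].sum(axis=1)
    times = (starts + nperseg / 2.0) / sample_rate_hz
    return SpectrogramFrame(
        times_s=times,
        freqs_hz=freqs,
        magnitude=spec,
        summed_magnitude=summed,
        segment_s=segment_s,
    )


def band_power(
    trace,
    sample_rate_hz: float,
    bands: Optional[Sequence[BandDefinition]] = None,
    segment_s: float = 1.0,
) -> Dict[str, float]:
    """Mean power spectral density per band, in V²/Hz.

    Welch PSD with Hann segments of ``segment_s`` and 50% overlap.  Traces
    are in mV, so the PSD is scaled by 1e-6 to express V²/Hz.  Band edges
    at or above Nyquist raise unless the band can be clipped (gamma at low
    sampling rates); a band entirely outside (0, Nyquist) is an error.
    """
    x = np.asarray(trace, dtype=np.float64)
    if sample_rate_hz <= 0:
        raise ValidationError("sample rate must be positive")
    if bands is None:
        bands = DEFAULT_BANDS
    nyq = sample_rate_hz / 2.0
    nperseg = min(int(round(segment_s * sample_rate_hz)), x.size)
    freqs, psd = welch(x * 1e-3, fs=sample_rate_hz, window="hann", nperseg=nperseg)
    out: Dict[str, float] = {}
    for band in bands:
        lo, hi = band.lo_hz, band.hi_hz
        if lo >= nyq:
            raise ValidationError(
                f"band {band.name} [{lo}, {hi}) entirely at/above Nyquist {nyq} Hz"
            )
        hi = min(hi, 0.99 * nyq)
        mask = (freqs >= lo) & (freqs < hi)
        out[band.name] = float(psd[mask].mean()) if mask.any() else 0.0
    return out
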