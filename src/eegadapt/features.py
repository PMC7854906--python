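"""Windowing, band decomposition and differential-entropy features.

EEG emotion work conventionally summarises each analysis window by the
differential entropy (DE) of the band-filtered signal.  Treating the
band-limited samples as Gaussian, DE has the closed form

    h = 1/2 * ln(2 * pi * e * sigma^2)   [nats]

so the feature reduces to a log-variance per window, channel and band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "EpochedEEG",
    "DEFeatures",
    "segment_windows",
    "band_filter_bank",
    "differential_entropy",
    "extract_de_features",
]

_LOG_2PIE = float(np.log(2.0 * np.pi * np.e))


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: require 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )


#: The five canonical EEG bands used throughout.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 30.0),
    BandSpec("gamma", 31.0, 50.0),
)


def _as_int_samples(value: float, what: str) -> int:
    rounded = round(value)
    if abs(value - rounded) > 1e-9:
        raise ValueError(f"{what} = {value} samples is not an integer; "
                         "choose window/overlap compatible with the sampling rate")
    return int(rounded)


@dataclass
class EpochedEEG:
    """Windowed multichannel EEG with per-window labels and domain ids.

    data : float array [n_windows, n_channels, n_samples]
    fs : sampling rate in Hz
    labels : int array [n_windows], class index per window
    domains : int array [n_windows], domain (day/subject) index per window
    channel_names : montage labels, one per channel
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    domains: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be [n_windows, n_channels, n_samples], got shape {self.data.shape}")
        self.labels = np.asarray(self.labels, dtype=int)
        self.domains = np.asarray(self.domains, dtype=int)
        n = self.data.shape[0]
        if self.labels.shape != (n,) or self.domains.shape != (n,):
            raise ValueError("labels and domains must both have length n_windows")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class DEFeatures:
    """Per-window, per-channel, per-band differential entropy (nats)."""

    values: np.ndarray                 # [n_windows, n_channels, n_bands]
    bands: tuple[BandSpec, ...]
    labels: np.ndarray
    domains: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be [n_windows, n_channels, n_bands]")
        if self.values.shape[2] != len(self.bands):
            raise ValueError("band axis must match the bands list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DE features must be finite")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def window_count(n_total: int, window: int, hop: int) -> int:
    """Number of left-aligned full windows of length `window` at stride `hop`."""
    if n_total < window:
        raise ValueError(f"signal of {n_total} samples is shorter than one window ({window})")
    return (n_total - window) // hop + 1


def segment_windows(
    signal: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    *,
    label: int = 0,
    domain: int = 0,
    channel_names: list[str] | None = None,
) -> EpochedEEG:
    """Cut a continuous [n_channels, n_total] record into overlapping windows.

    Windows are left-aligned starting at sample 0; a trailing partial window
    is dropped.  With 2-s windows overlapped by 50%, a 50-s record yields 49
    windows.  All windows of one record share `label` and `domain`.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    w = _as_int_samples(window_s * fs, f"window ({window_s} s x {fs} Hz)")
    h = _as_int_samples((1.0 - overlap_frac) * w,
                        f"hop ((1 - {overlap_frac}) x {w})")
    if h < 1:
        raise ValueError("hop must be at least one sample")
    n = window_count(signal.shape[1], w, h)
    starts = np.arange(n) * h
    data = np.stack([signal[:, s:s + w] for s in starts], axis=0)
    return EpochedEEG(
        data=data,
        fs=fs,
        labels=np.full(n, label, dtype=int),
        domains=np.full(n, domain, dtype=int),
        channel_names=list(channel_names) if channel_names else [],
    )


def _design_band_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    if band.hi >= fs / 2.0:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz is at/above Nyquist ({fs / 2.0} Hz)"
        )
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def band_filter_bank(
    epochs: EpochedEEG | np.ndarray,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    fs: float | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth decomposition into bands.

    Returns [n_windows, n_channels, n_bands, n_samples].  Each window is
    filtered independently (forward-backward, so no group delay between
    bands).
    """
    if isinstance(epochs, EpochedEEG):
        data, fs = epochs.data, epochs.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
        data = np.asarray(epochs, dtype=float)
    out = np.empty(data.shape[:2] + (len(bands),) + data.shape[2:], dtype=float)
    flat = data.reshape(-1, data.shape[-1])
    for b, band in enumerate(bands):
        sos = _design_band_sos(band, fs, order=order)
        out[:, :, b, :] = sps.sosfiltfilt(sos, flat, axis=-1).reshape(
            data.shape[0], data.shape[1], -1)
    return out


def differential_entropy(variance, floor: float = 1e-12):
    """DE of a Gaussian with the given variance, in nats: 0.5*ln(2*pi*e*var).

    Variances below `floor` are clamped (with a warning) so degenerate
    zero-variance windows stay finite rather than -inf.
    """
    var = np.asarray(variance, dtype=float)
    if np.any(var < 0):
        raise ValueError("variance must be nonnegative")
    if np.any(var < floor):
        warnings.warn(
            f"variance below floor {floor}; clamping to keep DE finite",
            RuntimeWarning,
            stacklevel=2,
        )
        var = np.maximum(var, floor)
    out = 0.5 * (_LOG_2PIE + np.log(var))
    return float(out) if np.isscalar(variance) else out


def extract_de_features(
    epochs: EpochedEEG,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    order: int = 4,
    variance_floor: float = 1e-12,
) -> DEFeatures:
    """Band-filter each window and take the DE of the per-band variance.

    The variance is the population variance over samples within the window
    (DE is a per-window descriptive statistic, not an inferential estimate).
    """
    banded = band_filter_bank(epochs, bands=bands, order=order)
    var = banded.var(axis=-1)          # population variance (ddof=0)
    values = differential_entropy(var, floor=variance_floor)
    return DEFeatures(
        values=values,
        bands=tuple(bands),
        labels=epochs.labels.copy(),
        domains=epochs.domains.copy(),
        channel_names=list(epochs.channel_names),
    )
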