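"""sEMG spectrum-image sequences for the comparative input modality.

Band-passed (20–450 Hz) surface EMG is converted, per channel, into a
sliding-window continuous-wavelet scalogram: a 100-sample window
(samples n-99 … n) stepped by 1 sample yields a 50x100 magnitude matrix at
each time instant (50 integer scales of an analytic Morlet wavelet).  The
scalograms of the two plantarflexor channels imaged by the transducer (LGS
and SOL) are stacked vertically into a single 100x100 spectrum image per
instant, synchronized 1:1 with the ultrasound frame clock.

Normalization is min–max with extrema frozen on the training split so the
validation and prediction images share the training scale (no label
leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sg

__all__ = [
    "DEFAULT_WAVELET",
    "EmgTrace",
    "SpectrumImage",
    "NormStats",
    "bandpass",
    "cwt_scalogram",
    "scalogram_pseudo_frequencies",
    "spectrum_image_sequence",
]

DEFAULT_WAVELET = "cmor1.5-1.0"  # analytic Morlet
DEFAULT_SCALES = 50
DEFAULT_WINDOW = 100
DEFAULT_CHANNELS = ("LGS", "SOL")


@dataclass(frozen=True)
class EmgTrace:
    """channels x samples sEMG matrix (mV) with channel names."""

    values: np.ndarray
    fs: float = 1000.0
    channel_names: tuple[str, ...] = ("LGS", "MGS", "SOL")

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if v.shape[0] != len(self.channel_names):
            raise ValueError("one name per channel required")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite sEMG samples")
        object.__setattr__(self, "values", v)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"unknown sEMG channel {name!r}; have {self.channel_names}"
            ) from None

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpectrumImage:
    """Merged two-channel scalogram image at one time instant.

    ``window_span`` is the (first, last) sample index of the contributing
    window, i.e. (n-99, n) for the default window length.
    """

    pixels: np.ndarray
    timestamp: float
    window_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("spectrum image must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("spectrum image pixels must be non-negative")


@dataclass
class NormStats:
    """Min–max extrema frozen on the training split."""

    lo: float
    hi: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.hi <= self.lo:
            return np.zeros_like(x)
        return (x - self.lo) / (self.hi - self.lo)


def bandpass(
    emg: EmgTrace, low: float = 20.0, high: float = 450.0, order: int = 4
) -> EmgTrace:
    """Zero-phase Butterworth band-pass applied per channel.

    Forward–backward filtering preserves the sEMG/moment timing relation;
    the output has the input's length.
    """
    nyq = emg.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = sg.butter(order, [low, high], btype="bandpass", fs=emg.fs, output="sos")
    filtered = sg.sosfiltfilt(sos, emg.values, axis=-1)
    return EmgTrace(filtered, emg.fs, emg.channel_names)


def cwt_scalogram(
    window: np.ndarray,
    n_scales: int = DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
    window_length: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """CWT magnitude matrix of one window: row s-1 = integer scale s.

    Returns an ``n_scales x window_length`` matrix of coefficient
    magnitudes (not squared power).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1 and window.size != window_length:
        raise ValueError(
            f"window must have exactly {window_length} samples, got {window.size}"
        )
    if window.ndim == 2 and window.shape[-1] != window_length:
        raise ValueError(
            f"windows must have exactly {window_length} samples, got {window.shape[-1]}"
        )
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    scales = np.arange(1, n_scales + 1)
    coeffs, _ = pywt.cwt(window, scales, wavelet, axis=-1)
    return np.abs(coeffs)


def scalogram_pseudo_frequencies(
    n_scales: int = DEFAULT_SCALES,
    fs: float = 1000.0,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Pseudo-frequency (Hz) of each integer scale row of the scalogram."""
    scales = np.arange(1, n_scales + 1)
    return pywt.scale2frequency(wavelet, scales) * fs


def spectrum_image_sequence(
    emg: EmgTrace,
    channels: tuple[str, str] = DEFAULT_CHANNELS,
    window: int = DEFAULT_WINDOW,
    step: int = 1,
    n_scales: int = DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
    norm: NormStats | None = None,
) -> tuple[list[SpectrumImage], NormStats]:
    """Merged two-channel scalogram image at every window position.

    An L-sample trace yields (L - window)//step + 1 images (L - 99 for the
    defaults).  Each image vertically stacks the first channel's scalogram
    above the second's; with 50 scales and a 100-sample window the result
    is exactly 100x100.  If ``norm`` is None the min–max extrema are fitted
    on this sequence (training use) and returned; otherwise the given
    (frozen) statistics are applied.
    """
    if emg.n_samples < window:
        raise ValueError(
            f"trace length {emg.n_samples} shorter than window {window}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    a = emg.channel(channels[0])
    b = emg.channel(channels[1])
    starts = np.arange(0, emg.n_samples - window + 1, step)
    # batch all windows through one vectorized CWT call per channel
    win_a = np.stack([a[s : s + window] for s in starts])
    win_b = np.stack([b[s : s + window] for s in starts])
    sc_a = cwt_scalogram(win_a, n_scales, wavelet, window)  # (scales, nwin, win)
    sc_b = cwt_scalogram(win_b, n_scales, wavelet, window)
    merged = np.concatenate([sc_a, sc_b], axis=0).transpose(1, 0, 2)
    if norm is None:
        norm = NormStats(lo=float(merged.min()), hi=float(merged.max()))
    images = [
        SpectrumImage(
            pixels=np.clip(norm.apply(merged[i]), 0.0, None),
            timestamp=(s + window - 1) / emg.fs,
            window_span=(int(s), int(s + window - 1)),
        )
        for i, s in enumerate(starts)
    ]
    return images, norm
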