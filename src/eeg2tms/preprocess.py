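"""Resting-EEG preprocessing: resampling, zero-phase FIR band-pass,
fixed-length epoching, and amplitude-based epoch rejection.

The chain mirrors the standard resting-state workflow for motor-cortex
studies: downsample the raw recording, band-pass 0.1–40 Hz with an FIR
filter, cut non-overlapping 2-s epochs, and drop any epoch whose amplitude
exceeds ±100 μV on any channel.  Ocular ICA and bad-channel interpolation
are deliberately out of scope; :func:`artifact_hook` lets callers splice an
external routine into the chain at the conventional position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import signal


class PreprocessError(ValueError):
    """Invalid preprocessing request (bad rates, bands, or durations)."""


class EmptyRecordingError(PreprocessError):
    """Every epoch was rejected; downstream analysis is impossible."""


@dataclass(frozen=True)
class RawRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in μV.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        One label per row of ``data`` (10-20 or HydroCel names).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise PreprocessError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise PreprocessError("sampling_rate must be positive")
        if len(self.channel_labels) != data.shape[0]:
            raise PreprocessError(
                f"{len(self.channel_labels)} labels for {data.shape[0]} channels"
            )
        if not np.all(np.isfinite(data)):
            raise PreprocessError("recording contains non-finite samples")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class EpochedRecording:
    """Fixed-length, non-overlapping epochs cut from a continuous recording.

    ``kept_epoch_indices`` indexes into the original epoch sequence so that
    rejection history survives; fresh epoching yields ``0..n_epochs-1``.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch), μV
    sampling_rate: float
    epoch_length: float
    channel_labels: tuple[str, ...]
    kept_epoch_indices: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise PreprocessError("epoched data must be 3-D")
        n_expected = int(round(self.epoch_length * self.sampling_rate))
        if data.shape[2] != n_expected:
            raise PreprocessError(
                f"epoch holds {data.shape[2]} samples, expected {n_expected}"
            )
        kept = tuple(self.kept_epoch_indices) or tuple(range(data.shape[0]))
        if len(kept) != data.shape[0]:
            raise PreprocessError("kept_epoch_indices length mismatch")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(self, "kept_epoch_indices", kept)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def resample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Anti-alias filter and polyphase-resample to ``target_rate``.

    Only downsampling (or the identity) is supported; the acquisition rate
    is always at least the analysis rate in this workflow.
    """
    if target_rate <= 0:
        raise PreprocessError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise PreprocessError(
            f"upsampling {rec.sampling_rate} -> {target_rate} Hz is not supported"
        )
    if target_rate == rec.sampling_rate:
        return rec
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(10_000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return RawRecording(out, float(target_rate), rec.channel_labels)


# --------------------------------------------------------------------------
# zero-phase FIR band-pass
# --------------------------------------------------------------------------

def _transition_width(edge: float) -> float:
    # the widely used heuristic: a quarter of the edge frequency, floored at
    # 2 Hz, never wider than the edge itself
    return min(max(edge * 0.25, 2.0), edge)


@lru_cache(maxsize=64)
def _fir_kernel(sampling_rate: float, lo: float, hi: float) -> np.ndarray:
    """Symmetric (type-I) windowed-sinc band-pass kernel, Hamming window."""
    nyq = sampling_rate / 2.0
    widths = []
    if lo > 0:
        widths.append(_transition_width(lo))
    widths.append(min(_transition_width(hi), nyq - hi))
    width = max(min(widths), 2.0 * sampling_rate / 1e6)
    numtaps = int(np.ceil(3.3 * sampling_rate / width))
    numtaps += 1 - numtaps % 2  # odd length -> exactly zero phase
    if lo > 0:
        return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=sampling_rate)
    return signal.firwin(numtaps, hi, pass_zero=True, fs=sampling_rate)


def bandpass_fir(rec: RawRecording, lo: float, hi: float) -> RawRecording:
    """Zero-phase FIR band-pass.

    A symmetric linear-phase kernel applied with centred convolution is
    exactly zero-phase, keeps passband gain within ±1 dB (Hamming ripple is
    far below that), and attenuates the stopband by ≥ 53 dB beyond one
    transition width.
    """
    if lo < 0 or lo >= hi:
        raise PreprocessError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    if hi >= rec.sampling_rate / 2.0:
        raise PreprocessError(
            f"hi={hi} Hz reaches Nyquist ({rec.sampling_rate / 2} Hz)"
        )
    kernel = _fir_kernel(float(rec.sampling_rate), float(lo), float(hi))
    out = filter_array(rec.data, kernel)
    return RawRecording(out, rec.sampling_rate, rec.channel_labels)


def filter_array(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel along the last axis, zero phase."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    shape = data.shape
    flat = data.reshape(-1, shape[-1])
    out = signal.fftconvolve(flat, kernel[None, :], mode="same", axes=-1)
    return out.reshape(shape)


# --------------------------------------------------------------------------
# epoching and rejection
# --------------------------------------------------------------------------

def epoch(rec: RawRecording, epoch_length: float = 2.0) -> EpochedRecording:
    """Cut non-overlapping consecutive epochs; a trailing partial epoch is
    discarded."""
    if epoch_length <= 0:
        raise PreprocessError("epoch_length must be positive")
    n_per = int(round(epoch_length * rec.sampling_rate))
    if n_per < 1 or rec.n_samples < n_per:
        raise PreprocessError(
            f"recording of {rec.duration:.3f}s shorter than one "
            f"{epoch_length}s epoch"
        )
    n_epochs = rec.n_samples // n_per
    cut = rec.data[:, : n_epochs * n_per]
    data = cut.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedRecording(
        data, rec.sampling_rate, epoch_length, rec.channel_labels,
        tuple(range(n_epochs)),
    )


def reject_epochs(
    epochs: EpochedRecording, threshold: float = 100.0
) -> EpochedRecording:
    """Drop every epoch in which any channel sample exceeds ±``threshold`` μV.

    Raises
    ------
    EmptyRecordingError
        If no epoch survives.
    """
    if threshold <= 0:
        raise PreprocessError("threshold must be positive")
    bad = np.any(np.abs(epochs.data) > threshold, axis=(1, 2))
    keep = ~bad
    if not np.any(keep):
        raise EmptyRecordingError(
            f"all {epochs.n_epochs} epochs exceed ±{threshold} μV"
        )
    kept_idx = tuple(
        idx for idx, k in zip(epochs.kept_epoch_indices, keep) if k
    )
    return EpochedRecording(
        epochs.data[keep], epochs.sampling_rate, epochs.epoch_length,
        epochs.channel_labels, kept_idx,
    )


def artifact_hook(
    epochs: EpochedRecording,
    routine: Callable[[EpochedRecording], EpochedRecording] | None,
) -> EpochedRecording:
    """Optional splice point for external artifact correction (e.g. ocular
    ICA, bad-channel interpolation).  ``None`` is the identity."""
    return epochs if routine is None else routine(epochs)


def preprocess_recording(
    rec: RawRecording,
    *,
    target_rate: float | None = None,
    band: tuple[float, float] = (0.1, 40.0),
    epoch_length: float = 2.0,
    reject_threshold: float = 100.0,
    artifact_routine: Callable[[EpochedRecording], EpochedRecording] | None = None,
) -> EpochedRecording:
    """Full chain: resample -> band-pass -> epoch -> reject -> hook."""
    if target_rate is not None:
        rec = resample(rec, target_rate)
    rec = bandpass_fir(rec, *band)
    epochs = epoch(rec, epoch_length)
    epochs = reject_epochs(epochs, reject_threshold)
    return artifact_hook(epochs, artifact_routine)
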