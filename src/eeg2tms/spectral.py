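"""Per-band FFT power and sensorimotor ROI averaging.

Band power is the mean-square contribution (μV²) of each frequency band,
computed per epoch from a Hann-tapered periodogram with density scaling and
integrated over half-open bins ``[lo, hi)``, then averaged across epochs.
With this convention the powers of a partition of the spectrum sum to the
total mean-square signal power (Parseval), and a pure tone of amplitude A
lands A²/2 in its band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EpochedRecording


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    """A named frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise SpectralError(f"invalid band {self.name}: ({self.lo}, {self.hi})")


#: The six canonical resting-state bands used throughout the package.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha1", 8.0, 10.0),
    Band("alpha2", 10.0, 13.0),
    Band("beta1", 13.0, 20.0),
    Band("beta2", 20.0, 30.0),
)


@dataclass(frozen=True)
class RoiSpec:
    """A named set of channel labels, e.g. the cluster around C4 standing in
    for the right sensorimotor region."""

    name: str
    channel_labels: frozenset[str]

    def __post_init__(self) -> None:
        labels = frozenset(self.channel_labels)
        if not labels:
            raise SpectralError("ROI must contain at least one channel")
        object.__setattr__(self, "channel_labels", labels)

    def indices(self, channel_labels: tuple[str, ...]) -> np.ndarray:
        unknown = self.channel_labels - set(channel_labels)
        if unknown:
            raise SpectralError(
                f"ROI '{self.name}' channels not in recording: {sorted(unknown)}"
            )
        return np.array(
            [i for i, lab in enumerate(channel_labels) if lab in self.channel_labels]
        )


@dataclass(frozen=True)
class BandPowerTable:
    """Channel × band mean-square power (μV²)."""

    power: np.ndarray
    bands: tuple[Band, ...]
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        power = np.asarray(self.power, dtype=np.float64)
        if power.shape != (len(self.channel_labels), len(self.bands)):
            raise SpectralError("power must be channels x bands")
        if not np.all(np.isfinite(power)) or np.any(power < 0):
            raise SpectralError("band powers must be finite and non-negative")
        object.__setattr__(self, "power", power)


def band_power(
    epochs: EpochedRecording, bands: tuple[Band, ...] = DEFAULT_BANDS
) -> BandPowerTable:
    """Per-channel band power averaged over epochs.

    Each epoch/channel is Hann-tapered; the periodogram (density scaling,
    hence taper-power corrected) is summed over bins with ``lo <= f < hi``
    and multiplied by the bin width, yielding μV².
    """
    nyq = epochs.sampling_rate / 2.0
    for band in bands:
        if band.hi > nyq:
            raise SpectralError(f"band {band.name} exceeds Nyquist {nyq} Hz")
        if epochs.epoch_length < 1.0 / band.lo:
            raise SpectralError(
                f"epoch of {epochs.epoch_length}s cannot resolve {band.lo} Hz"
            )
    freqs, pxx = signal.periodogram(
        epochs.data, fs=epochs.sampling_rate, window="hann",
        scaling="density", axis=-1,
    )
    df = freqs[1] - freqs[0]
    per_epoch = np.empty((epochs.n_epochs, epochs.n_channels, len(bands)))
    for b, band in enumerate(bands):
        mask = (freqs >= band.lo) & (freqs < band.hi)
        per_epoch[:, :, b] = pxx[:, :, mask].sum(axis=-1) * df
    return BandPowerTable(per_epoch.mean(axis=0), tuple(bands), epochs.channel_labels)


def total_power(epochs: EpochedRecording) -> np.ndarray:
    """Mean-square signal power per channel (μV²), averaged over epochs."""
    return np.mean(epochs.data**2, axis=(0, 2))


def roi_average(table: BandPowerTable, roi: RoiSpec) -> dict[str, float]:
    """Arithmetic mean of the ROI channels' power, per band."""
    idx = roi.indices(table.channel_labels)
    means = table.power[idx].mean(axis=0)
    return {band.name: float(m) for band, m in zip(table.bands, means)}
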