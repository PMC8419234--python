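"""Phase-lag-index (PLI) functional connectivity.

For a channel pair with instantaneous phases φ_i(t), φ_j(t) the PLI is

    PLI = | < sign( sin(φ_i(t_k) − φ_j(t_k)) ) >_k |

the absolute time-average of the sign of the phase-difference sine.  It is 0
when the phase difference is symmetric around 0 or π (no consistent lag —
including pure volume conduction, which produces zero-lag coupling) and 1
when one signal consistently leads the other; the value always lies in
[0, 1].  Phases come from the analytic signal (Hilbert transform) of the
band-pass-filtered data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EpochedRecording, PreprocessError, _fir_kernel, filter_array
from .spectral import Band

#: |sin Δφ| below this is treated as exactly zero, so that in-phase and
#: anti-phase lags both contribute sign 0 instead of float noise.
_SIN_TOL = 1e-9


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseTensor:
    """Instantaneous phase per epoch/channel/sample, wrapped to (−π, π].

    ``retained`` is the sample slice kept for PLI averaging; the first and
    last ``edge_fraction`` of every epoch are excluded to avoid the
    filter/Hilbert edge transients.
    """

    phase: np.ndarray  # (n_epochs, n_channels, n_samples), radians
    band: Band
    channel_labels: tuple[str, ...]
    retained: slice

    @property
    def n_retained(self) -> int:
        return len(range(*self.retained.indices(self.phase.shape[-1])))


@dataclass(frozen=True)
class PLIMatrix:
    """Symmetric channel × channel PLI in [0, 1] for one band."""

    pli: np.ndarray
    band: Band
    channel_labels: tuple[str, ...]
    n_epochs_used: int

    def __post_init__(self) -> None:
        pli = np.asarray(self.pli, dtype=np.float64)
        if pli.ndim != 2 or pli.shape[0] != pli.shape[1]:
            raise ConnectivityError("PLI matrix must be square")
        if not np.allclose(pli, pli.T):
            raise ConnectivityError("PLI matrix must be symmetric")
        if np.any(pli < 0) or np.any(pli > 1):
            raise ConnectivityError("PLI values must lie in [0, 1]")
        object.__setattr__(self, "pli", pli)


def instantaneous_phase(
    epochs: EpochedRecording, band: Band, edge_fraction: float = 0.1
) -> PhaseTensor:
    """Band-pass each epoch and extract the analytic-signal phase.

    Band filtering reuses the preprocessing FIR contract (same kernel
    design), applied per epoch; the Hilbert transform then yields the
    instantaneous phase.  ``edge_fraction`` of samples at each epoch edge is
    flagged for exclusion from PLI averaging.
    """
    nyq = epochs.sampling_rate / 2.0
    if not 0 < band.lo < band.hi < nyq:
        raise ConnectivityError(f"band {band.name} invalid at fs={epochs.sampling_rate}")
    if not 0 <= edge_fraction < 0.5:
        raise ConnectivityError("edge_fraction must lie in [0, 0.5)")
    kernel = _fir_kernel(float(epochs.sampling_rate), float(band.lo), float(band.hi))
    filtered = filter_array(epochs.data, kernel)
    phase = np.angle(signal.hilbert(filtered, axis=-1))
    n = epochs.n_samples
    margin = int(round(edge_fraction * n))
    return PhaseTensor(
        phase, band, epochs.channel_labels, slice(margin, n - margin)
    )


def _signed_lag(delta_phi: np.ndarray) -> np.ndarray:
    s = np.sin(delta_phi)
    s[np.abs(s) < _SIN_TOL] = 0.0
    return np.sign(s)


def pli_matrix(phases: PhaseTensor, average: str = "epochs") -> PLIMatrix:
    """Eq.-style PLI for every channel pair.

    ``average="epochs"`` (default) computes |⟨sign sin Δφ⟩| per epoch and
    averages the per-epoch PLI across epochs; ``average="pooled"`` pools all
    retained samples of all epochs into a single time average.
    """
    if average not in ("epochs", "pooled"):
        raise ConnectivityError(f"unknown averaging mode {average!r}")
    phi = phases.phase[:, :, phases.retained]
    n_epochs, n_ch, n_samp = phi.shape
    if n_epochs < 1 or n_ch < 2:
        raise ConnectivityError("need at least 1 epoch and 2 channels")
    if n_samp == 0:
        raise ConnectivityError("all samples excluded by the edge margin")
    iu, ju = np.triu_indices(n_ch, k=1)
    # (n_epochs, n_pairs, n_samples) signed lag tensor
    lag = _signed_lag(phi[:, iu, :] - phi[:, ju, :])
    if average == "epochs":
        vals = np.abs(lag.mean(axis=-1)).mean(axis=0)
    else:
        vals = np.abs(lag.mean(axis=(0, 2)))
    pli = np.zeros((n_ch, n_ch))
    pli[iu, ju] = vals
    pli[ju, iu] = vals
    return PLIMatrix(pli, phases.band, phases.channel_labels, n_epochs)


def band_pli(
    epochs: EpochedRecording,
    band: Band,
    edge_fraction: float = 0.1,
    average: str = "epochs",
) -> PLIMatrix:
    """Convenience: phase extraction followed by the PLI matrix."""
    return pli_matrix(instantaneous_phase(epochs, band, edge_fraction), average)
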