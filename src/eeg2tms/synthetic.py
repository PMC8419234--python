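"""Synthetic resting-EEG cohorts with known ground truth.

Each subject's recording is a 1/f-scaled Gaussian background plus one
band-limited sinusoid per canonical band and channel, with subject-specific
log-normal amplitude factors.  Two planted-coupling mechanisms provide
known connectivity structure:

* ``coupling_pairs`` — isolated channel pairs sharing a common band-limited
  oscillation at a fixed phase lag and mixing strength, so the phase-lag
  index of those pairs is known by construction;
* ``ensemble`` — a variable-size set of channels (default: the cluster
  around C4) sharing one alpha2 oscillation at distinct per-member lags.
  The number of active members follows a per-subject latent variable, so
  the subject's alpha2 network density — and with it the binarised global
  efficiency of the thresholded PLI graph — varies across the cohort.

A configurable fraction of 2-s windows receives a large square-pulse offset
so the ±100 μV rejection rule has something to reject.  Motor thresholds
(RMT/AMT, %MSO) come from a linear latent-excitability model driven by the
subject's true alpha2 power and alpha2 coupling density, giving every
downstream stage a parameter-recovery target.

Everything is deterministic given ``(config, seed)``; subject ``i`` draws
from an independent stream seeded by ``(seed, i)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import RawRecording
from .spectral import DEFAULT_BANDS, Band

_BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}

#: 10-20-style labels for the default 8-channel montage: a right
#: sensorimotor cluster around C4 plus frontal/parietal/midline context.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "C4", "FC4", "CP4", "C2", "C6", "F4", "P4", "Cz",
)
#: The cluster around C4 standing in for the right sensorimotor region.
DEFAULT_ROI: tuple[str, ...] = ("C4", "FC4", "CP4", "C2", "C6")

#: Band sinusoid amplitudes (μV) whose mean-square powers sit at the
#: magnitudes typical of eyes-closed resting EEG band-power tables.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 2.03, "theta": 1.58, "alpha1": 1.68,
    "alpha2": 1.65, "beta1": 1.21, "beta2": 1.00,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CouplingSpec:
    """A planted constant-phase-lag coupling between two channels.

    The pair shares a sinusoid within ``band``; channel ``j`` receives it
    delayed by ``lag`` radians, mixed into each channel's band oscillation
    with weight ``strength`` (1 = pure shared oscillation, PLI → 1).
    """

    i: int
    j: int
    band: str
    lag: float
    strength: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise SimulationError("coupling requires two distinct channels")
        if not 0 <= self.strength <= 1:
            raise SimulationError("coupling strength must lie in [0, 1]")
        if self.band not in _BAND_BY_NAME:
            raise SimulationError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class CouplingEnsemble:
    """A shared-oscillation clique whose size varies across subjects.

    All active members mix the same band oscillation (weight ``strength``)
    at distinct per-member lags spread over ``lag_range``, so every active
    pair shows a constant non-zero, non-π phase-difference and hence a high
    PLI.  A subject with latent u ∈ [0, 1] activates
    ``min_active + round(u · (len(members) − min_active))`` members.
    """

    band: str = "alpha2"
    members: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    strength: float = 0.85
    min_active: int = 3
    lag_range: tuple[float, float] = (0.4, 2.2)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members) or len(self.members) < 2:
            raise SimulationError("ensemble needs >= 2 distinct members")
        if not 2 <= self.min_active <= len(self.members):
            raise SimulationError("min_active must lie in [2, len(members)]")
        if not 0 <= self.strength <= 1:
            raise SimulationError("ensemble strength must lie in [0, 1]")
        if self.band not in _BAND_BY_NAME:
            raise SimulationError(f"unknown band {self.band!r}")

    def n_active(self, u: float) -> int:
        span = len(self.members) - self.min_active
        return self.min_active + int(round(float(u) * span))

    def lags(self) -> np.ndarray:
        return np.linspace(*self.lag_range, num=len(self.members))


@dataclass(frozen=True)
class ExcitabilityModel:
    """Linear latent model generating motor thresholds (%MSO).

    RMT_i = rmt_intercept + alpha2_power_slope · z(true alpha2 power_i)
          + alpha2_efficiency_slope · z(coupling density_i) + N(0, noise_sd);
    AMT uses the same slopes with a smaller intercept.  Negative slopes
    reproduce the inverse power/efficiency → threshold direction.
    """

    rmt_intercept: float = 46.25
    amt_intercept: float = 32.31
    alpha2_power_slope: float = -8.0
    alpha2_efficiency_slope: float = -5.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 32
    n_channels: int = 8
    sampling_rate: float = 250.0
    duration: float = 60.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    coupling_pairs: tuple[CouplingSpec, ...] = (
        CouplingSpec(6, 7, "theta", np.pi / 3, 0.5),
    )
    ensemble: CouplingEnsemble | None = field(default_factory=CouplingEnsemble)
    artifact_epoch_fraction: float = 0.1
    artifact_amplitude: float = 150.0
    artifact_epoch_length: float = 2.0
    excitability: ExcitabilityModel = field(default_factory=ExcitabilityModel)
    background_rms: float = 1.0
    background_exponent: float = 1.0
    subject_amplitude_sd: float = 0.3
    #: oscillation coherence time: frequency and phase are re-drawn every
    #: block, giving uncoupled channel pairs a finite-coherence PLI null
    #: instead of recording-long accidental phase locking
    oscillation_block_s: float = 2.0
    latent_range: tuple[float, float] = (0.0, 1.0)
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be >= 1")
        if self.n_channels < 2:
            raise SimulationError("n_channels must be >= 2")
        n_samples = self.duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise SimulationError("duration x sampling_rate must be an integer")
        n_per_epoch = self.artifact_epoch_length * self.sampling_rate
        if round(n_samples) < round(n_per_epoch):
            raise SimulationError("recording shorter than one epoch")
        for name, amp in self.band_amplitudes.items():
            if name not in _BAND_BY_NAME:
                raise SimulationError(f"unknown band {name!r}")
            if amp < 0:
                raise SimulationError("band amplitudes must be >= 0")
        occupied: set[tuple[int, str]] = set()
        if self.ensemble is not None:
            if max(self.ensemble.members) >= self.n_channels:
                raise SimulationError("ensemble member out of channel range")
            occupied |= {(m, self.ensemble.band) for m in self.ensemble.members}
        for cp in self.coupling_pairs:
            if not (0 <= cp.i < self.n_channels and 0 <= cp.j < self.n_channels):
                raise SimulationError(f"coupling channel out of range: {cp}")
            for ch in (cp.i, cp.j):
                if (ch, cp.band) in occupied:
                    raise SimulationError(
                        f"channel {ch} coupled twice in band {cp.band}"
                    )
                occupied.add((ch, cp.band))
        if not 0 <= self.artifact_epoch_fraction <= 1:
            raise SimulationError("artifact_epoch_fraction must lie in [0, 1]")
        labels = self.channel_labels
        if labels is None:
            if self.n_channels <= len(DEFAULT_CHANNELS):
                labels = DEFAULT_CHANNELS[: self.n_channels]
            else:
                labels = DEFAULT_CHANNELS + tuple(
                    f"EEG{k:03d}"
                    for k in range(self.n_channels - len(DEFAULT_CHANNELS))
                )
        if len(labels) != self.n_channels:
            raise SimulationError("channel_labels length != n_channels")
        object.__setattr__(self, "channel_labels", tuple(labels))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def n_artifact_epochs(self) -> int:
        n_epochs = int(self.duration // self.artifact_epoch_length)
        return int(round(self.artifact_epoch_fraction * n_epochs))

    def roi_labels(self) -> tuple[str, ...]:
        roi = tuple(lab for lab in self.channel_labels if lab in DEFAULT_ROI)
        return roi or self.channel_labels[:1]


@dataclass(frozen=True)
class SubjectTruth:
    """Per-subject generative ground truth."""

    subject_id: str
    band_factors: dict[str, float]       # log-normal amplitude factors
    alpha2_power: float                  # true band power A²/2 (μV²)
    latent: float                        # u_i driving the ensemble size
    coupling_density: float              # active pair fraction in the band
    active_members: tuple[int, ...]      # ensemble channels switched on
    artifact_epochs: tuple[int, ...]     # indices of planted-artifact windows
    rmt_true: float = np.nan             # pre-noise thresholds (%MSO)
    amt_true: float = np.nan


@dataclass(frozen=True)
class GroundTruth:
    """Cohort-level truth: subject rows plus planted coupling adjacency."""

    subjects: tuple[SubjectTruth, ...]
    coupling_adjacency: dict[str, np.ndarray]  # band -> symmetric strengths

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "subject_id": s.subject_id,
                "alpha2_power": s.alpha2_power,
                "latent": s.latent,
                "coupling_density": s.coupling_density,
                "n_active_members": len(s.active_members),
                "rmt_true": s.rmt_true,
                "amt_true": s.amt_true,
                "n_artifact_epochs": len(s.artifact_epochs),
            }
            for s in self.subjects
        ]).set_index("subject_id")


def coupling_adjacency(
    config: SimulationConfig, active_members: tuple[int, ...] | None = None
) -> dict[str, np.ndarray]:
    """Planted coupling strengths as one symmetric zero-diagonal matrix per
    band.  For the ensemble, either the full membership (default) or a
    subject's active subset is marked."""
    out: dict[str, np.ndarray] = {}
    for b in _BAND_BY_NAME:
        adj = np.zeros((config.n_channels, config.n_channels))
        for cp in config.coupling_pairs:
            if cp.band == b:
                adj[cp.i, cp.j] = adj[cp.j, cp.i] = cp.strength
        ens = config.ensemble
        if ens is not None and ens.band == b:
            members = ens.members if active_members is None else active_members
            for a in members:
                for c in members:
                    if a != c:
                        adj[a, c] = ens.strength
        out[b] = adj
    return out


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, subject_index])


def _pink_background(
    rng: np.random.Generator, n_channels: int, n_samples: int,
    sampling_rate: float, rms: float, exponent: float,
) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^exponent amplitude spectrum, scaled to
    the requested per-channel RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    f = np.maximum(f, 0.5)  # flatten below 0.5 Hz instead of diverging
    spec *= f ** (-exponent)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    scale = rms / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x * scale


def _band_interior(name: str, margin: float = 0.1) -> tuple[float, float]:
    band = _BAND_BY_NAME[name]
    w = band.hi - band.lo
    return band.lo + margin * w, band.hi - margin * w


def simulate_subject(
    config: SimulationConfig, subject_index: int
) -> tuple[RawRecording, SubjectTruth]:
    """One subject's recording plus its generative truth row.

    The recording is background + per-band sinusoids (subject-random
    amplitude, channel-random frequency/phase) + planted couplings +
    artifact pulses.  Deterministic given ``(config.seed, subject_index)``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise SimulationError(f"subject_index {subject_index} out of range")
    rng = _subject_rng(config, subject_index)
    n_ch, n_s = config.n_channels, config.n_samples
    fs = config.sampling_rate

    # blockwise oscillations: frequency/phase re-drawn every coherence block
    block_n = max(int(round(config.oscillation_block_s * fs)), 1)
    n_blocks = -(-n_s // block_n)  # ceil
    t_block = np.arange(block_n) / fs

    def block_tone(freqs: np.ndarray, phases: np.ndarray) -> np.ndarray:
        """(..., n_blocks) draws -> (..., n_samples) piecewise sinusoid."""
        arg = (2 * np.pi * freqs[..., None] * t_block + phases[..., None])
        out = np.sin(arg)
        return out.reshape(*freqs.shape[:-1], n_blocks * block_n)[..., :n_s]

    # subject-level draws, in a fixed order so the stream is stable
    band_factors = {
        name: float(rng.lognormal(mean=0.0, sigma=config.subject_amplitude_sd))
        for name in config.band_amplitudes
    }
    latent = float(rng.uniform(*config.latent_range))

    data = _pink_background(
        rng, n_ch, n_s, fs, config.background_rms, config.background_exponent
    )

    # shared oscillations: pairwise couplings, then the ensemble clique
    shared: dict[tuple[int, str], tuple[float, np.ndarray]] = {}
    for cp in config.coupling_pairs:
        f0 = rng.uniform(*_band_interior(cp.band), size=n_blocks)
        phi0 = rng.uniform(0, 2 * np.pi, size=n_blocks)
        shared[(cp.i, cp.band)] = (cp.strength, block_tone(f0, phi0))
        shared[(cp.j, cp.band)] = (cp.strength, block_tone(f0, phi0 + cp.lag))

    active_members: tuple[int, ...] = ()
    density = 0.0
    ens = config.ensemble
    if ens is not None:
        f0 = rng.uniform(*_band_interior(ens.band), size=n_blocks)
        phi0 = rng.uniform(0, 2 * np.pi, size=n_blocks)
        n_act = ens.n_active(latent)
        active_members = tuple(ens.members[:n_act])
        for m, lag in zip(ens.members, ens.lags()):
            if m in active_members:
                shared[(m, ens.band)] = (ens.strength,
                                         block_tone(f0, phi0 + lag))
        density = (n_act * (n_act - 1)) / (n_ch * (n_ch - 1))

    for name, base_amp in config.band_amplitudes.items():
        amp = base_amp * band_factors[name]
        lo_f, hi_f = _band_interior(name)
        for ch in range(n_ch):
            f_ch = rng.uniform(lo_f, hi_f, size=n_blocks)
            phi_ch = rng.uniform(0, 2 * np.pi, size=n_blocks)
            own = block_tone(f_ch, phi_ch)
            key = (ch, name)
            if key in shared:
                c, osc = shared[key]
                data[ch] += amp * ((1.0 - c) * own + c * osc)
            else:
                data[ch] += amp * own

    n_epochs = int(config.duration // config.artifact_epoch_length)
    n_art = config.n_artifact_epochs
    artifact_epochs: tuple[int, ...] = ()
    if n_art > 0:
        chosen = np.sort(rng.choice(n_epochs, size=n_art, replace=False))
        n_per = int(round(config.artifact_epoch_length * fs))
        for e in chosen:
            data[:, e * n_per : (e + 1) * n_per] += config.artifact_amplitude
        artifact_epochs = tuple(int(e) for e in chosen)

    alpha2_amp = config.band_amplitudes.get("alpha2", 0.0) * band_factors.get(
        "alpha2", 1.0
    )
    truth = SubjectTruth(
        subject_id=f"sub-{subject_index:03d}",
        band_factors=band_factors,
        alpha2_power=alpha2_amp**2 / 2.0,
        latent=latent,
        coupling_density=density,
        active_members=active_members,
        artifact_epochs=artifact_epochs,
    )
    rec = RawRecording(data, fs, config.channel_labels)
    return rec, truth


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[RawRecording], pd.DataFrame, GroundTruth]:
    """Full cohort: recordings, a (subject × RMT/AMT) target table, and the
    ground truth.

    Thresholds follow the latent excitability model on the standardised
    true alpha2 power and alpha2 coupling density, with independent
    Gaussian noise per target.
    """
    recordings: list[RawRecording] = []
    truths: list[SubjectTruth] = []
    for i in range(config.n_subjects):
        rec, truth = simulate_subject(config, i)
        recordings.append(rec)
        truths.append(truth)

    power = np.array([s.alpha2_power for s in truths])
    density = np.array([s.coupling_density for s in truths])
    z_pow = _standardize(power)
    z_den = _standardize(density)
    m = config.excitability
    rmt_true = (
        m.rmt_intercept
        + m.alpha2_power_slope * z_pow
        + m.alpha2_efficiency_slope * z_den
    )
    amt_true = (
        m.amt_intercept
        + m.alpha2_power_slope * z_pow
        + m.alpha2_efficiency_slope * z_den
    )
    rng = np.random.default_rng([config.seed, 2**20])
    rmt = rmt_true + rng.normal(0.0, m.noise_sd, size=len(truths))
    amt = amt_true + rng.normal(0.0, m.noise_sd, size=len(truths))
    rmt = np.maximum(rmt, 1.0)
    amt = np.maximum(amt, 1.0)

    truths = [
        dataclasses.replace(s, rmt_true=float(rt), amt_true=float(at))
        for s, rt, at in zip(truths, rmt_true, amt_true)
    ]
    targets = pd.DataFrame(
        {"RMT": rmt, "AMT": amt},
        index=pd.Index([s.subject_id for s in truths], name="subject_id"),
    )
    truth = GroundTruth(tuple(truths), coupling_adjacency(config))
    return recordings, targets, truth
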