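"""Synthetic dyadic EEG with controllable interbrain coupling.

Each subject's channel is a sum of 1/f background activity, band-limited
oscillations in the canonical EEG bands, broadband sensor noise and — during
feedback rounds only — a narrowband oscillator shared between the homologous
channels of the two partners. The shared fraction of target-band power is
``coupling_strength`` (kappa); each partner sees the shared source through an
independent slowly drifting phase jitter, so kappa and the jitter SD jointly
set the attainable phase coupling. Rest segments carry no shared component,
so a task-minus-rest contrast isolates the injected coupling by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeline import SessionTimeline, make_timeline

#: EMOTIV EPOC X montage (14 saline electrodes, 10-20 positions).
EPOC_CHANNELS = ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
                 "O2", "P8", "T8", "FC6", "F4", "F8", "AF4")

#: Canonical EEG bands (Hz) used throughout the pipeline.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 8.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 30.0),
}

#: Per-band oscillation RMS amplitudes in microvolt; alpha dominant, as in
#: typical resting scalp EEG.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "delta": 6.0,
    "theta": 4.0,
    "alpha": 8.0,
    "beta": 3.0,
}


@dataclass(frozen=True)
class DyadSimConfig:
    """Parameters of one simulated dyad.

    ``coupling_strength`` is the fraction of target-band power shared
    between partners during feedback rounds; ``target_band_amplitude`` is
    the RMS (microvolt) of that narrowband component (present, but fully
    private, during rest so task and rest have matched spectra).
    """

    fs: float = 128.0
    channel_labels: tuple[str, ...] = EPOC_CHANNELS
    coupling_strength: float = 0.0
    target_band: tuple[float, float] = (21.0, 23.0)
    target_band_amplitude: float = 5.0
    phase_jitter_sd: float = 0.2  # radians, slow per-subject drift
    background_exponent: float = 1.0
    background_rms: float = 10.0  # microvolt
    oscillation_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    noise_sd: float = 2.0  # microvolt, white sensor noise
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.fs <= 2.0 * self.target_band[1]:
            raise ValueError("fs must exceed twice the target band upper edge")
        if any(a < 0 for a in self.oscillation_amplitudes.values()):
            raise ValueError("oscillation amplitudes must be non-negative")
        if self.target_band_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class DyadRecording:
    """Two aligned multichannel EEG matrices (microvolt) plus metadata."""

    subject_a: np.ndarray  # (n_channels, n_samples)
    subject_b: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    timeline: SessionTimeline
    dyad_id: str = "dyad"
    group: str = "real"

    def __post_init__(self):
        if self.subject_a.shape != self.subject_b.shape:
            raise ValueError("subject matrices must have the same shape")
        if self.subject_a.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")

    @property
    def n_samples(self) -> int:
        return self.subject_a.shape[1]

    def subjects(self) -> tuple[np.ndarray, np.ndarray]:
        return self.subject_a, self.subject_b


def _band_mask(n: int, fs: float, f_lo: float, f_hi: float,
               transition: float) -> np.ndarray:
    """One-sided raised-cosine band mask over FFT frequencies."""
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    mask = np.zeros(n)
    pos = freqs > 0
    f = freqs[pos]
    m = np.zeros(f.shape)
    m[(f >= f_lo) & (f <= f_hi)] = 1.0
    ramp_lo = (f >= f_lo - transition) & (f < f_lo)
    ramp_hi = (f > f_hi) & (f <= f_hi + transition)
    m[ramp_lo] = 0.5 * (1 + np.cos(np.pi * (f_lo - f[ramp_lo]) / transition))
    m[ramp_hi] = 0.5 * (1 + np.cos(np.pi * (f[ramp_hi] - f_hi) / transition))
    mask[pos] = m
    return mask


def band_noise_batch(rng: np.random.Generator, shape: tuple[int, ...],
                     fs: float, f_lo: float, f_hi: float,
                     transition: float = 0.5) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise as complex analytic signals.

    ``shape = (..., n_samples)``. Built in the frequency domain: complex
    Gaussian spectrum restricted to [f_lo, f_hi] with raised-cosine edges
    of width ``transition`` Hz, one sided, so the inverse FFT is the
    analytic signal (real part is the oscillation; phase jitter can be
    applied by complex rotation). Normalized so each row's real part has
    unit RMS.
    """
    n = shape[-1]
    mask = _band_mask(n, fs, f_lo, f_hi, transition)
    spec = mask * (rng.standard_normal(shape)
                   + 1j * rng.standard_normal(shape))
    x = np.fft.ifft(spec, axis=-1)
    rms = np.sqrt(np.mean(x.real ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def band_noise(rng: np.random.Generator, n: int, fs: float,
               f_lo: float, f_hi: float, transition: float = 0.5) -> np.ndarray:
    """Single unit-RMS band-limited analytic noise series of length ``n``."""
    return band_noise_batch(rng, (int(n),), fs, f_lo, f_hi, transition)


def one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                     exponent: float = 1.0,
                     n_series: int | None = None) -> np.ndarray:
    """Real noise with power spectral density proportional to 1/f^exponent.

    Returns (n,) or, with ``n_series``, (n_series, n); each series is
    normalized to unit SD.
    """
    shape = (n,) if n_series is None else (n_series, n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(shape[:-1] + (freqs.size,))
                  + 1j * rng.standard_normal(shape[:-1] + (freqs.size,)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _slow_phase_jitter(rng: np.random.Generator, n: int, fs: float,
                       sd: float, cutoff_hz: float = 1.0) -> np.ndarray:
    """Zero-mean phase drift (radians) with SD ``sd``, band-limited below
    ``cutoff_hz`` so it varies on a ~1-s timescale."""
    if sd == 0:
        return np.zeros(n)
    theta = band_noise(rng, n, fs, 0.0, cutoff_hz, transition=0.2).real
    theta_sd = theta.std()
    if theta_sd == 0:
        return np.zeros(n)
    return sd * theta / theta_sd


def _round_mask(timeline: SessionTimeline, fs: float, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for seg in timeline.segments("round"):
        i0 = int(round(seg.onset * fs))
        i1 = int(round(seg.end * fs))
        mask[i0:i1] = True
    return mask


def simulate_dyad(config: DyadSimConfig,
                  timeline: SessionTimeline | None = None,
                  dyad_id: str = "dyad",
                  group: str = "real") -> DyadRecording:
    """Simulate one dyad's session.

    Reproducible from ``config.seed``; the same seed yields bit-identical
    recordings. See the module docstring for the generative model.
    """
    if timeline is None:
        timeline = make_timeline()
    fs = config.fs
    n = int(round(timeline.span * fs))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_ch = len(config.channel_labels)

    # Shared target-band oscillator, analytic form; one source drives all
    # homologous pairs. Mixed in only during rounds.
    shared = band_noise(rng, n, fs, *config.target_band)
    jitter_a = _slow_phase_jitter(rng, n, fs, config.phase_jitter_sd)
    jitter_b = _slow_phase_jitter(rng, n, fs, config.phase_jitter_sd)
    shared_a = (shared * np.exp(1j * jitter_a)).real
    shared_b = (shared * np.exp(1j * jitter_b)).real

    kappa = config.coupling_strength
    in_round = _round_mask(timeline, fs, n)
    w_shared = np.where(in_round, np.sqrt(kappa), 0.0)
    w_private = np.where(in_round, np.sqrt(1.0 - kappa), 1.0)

    out = []
    for shared_subj in (shared_a, shared_b):
        data = np.zeros((n_ch, n))
        if config.background_rms > 0:
            data += config.background_rms * one_over_f_noise(
                rng, n, fs, config.background_exponent, n_series=n_ch)
        for name, (lo, hi) in CANONICAL_BANDS.items():
            amp = config.oscillation_amplitudes.get(name, 0.0)
            if amp > 0:
                data += amp * band_noise_batch(rng, (n_ch, n), fs,
                                               lo, hi).real
        private = band_noise_batch(rng, (n_ch, n), fs,
                                   *config.target_band).real
        data += config.target_band_amplitude * (
            w_shared * shared_subj + w_private * private)
        if config.noise_sd > 0:
            data += config.noise_sd * rng.standard_normal((n_ch, n))
        out.append(data)

    return DyadRecording(out[0], out[1], fs, tuple(config.channel_labels),
                         timeline, dyad_id=dyad_id, group=group)


def sham_source(n_channels: int, n_samples: int, seed) -> np.ndarray:
    """I.i.d. uniform(0, 1) samples standing in for EEG in sham feedback.

    ``seed`` is an integer or tuple of integers (SeedSequence entropy);
    identical seeds give identical matrices.
    """
    if n_channels <= 0 or n_samples <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.uniform(0.0, 1.0, size=(n_channels, n_samples))
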