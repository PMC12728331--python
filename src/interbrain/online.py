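"""Real-time interbrain neurofeedback index.

At each update tick the most recent 3 s of time-aligned dyadic EEG are
band-pass filtered (causal IIR) into the four canonical bands, turned into
analytic signals via the Hilbert transform, and single-window magnitude
coherence is computed between homologous electrode pairs. The mean over the
14 pairs and 4 bands is the raw coupling index; a fixed [0, 0.3] min-max
normalization and the map ``distance = 1 - index`` drive the avatar display.
Sham mode pushes uniform(0, 1) noise through the identical pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import CANONICAL_BANDS, DyadRecording, sham_source

BAND_ORDER = tuple(CANONICAL_BANDS)  # delta, theta, alpha, beta

TRACE_COLUMNS = ["t", "round", "coh_delta", "coh_theta", "coh_alpha",
                 "coh_beta", "raw_index", "norm_index", "avatar_distance"]


def bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError(f"invalid band {band} for fs={fs}")
    return signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_iir(x: np.ndarray, band: tuple[float, float], fs: float,
                 order: int = 4) -> np.ndarray:
    """Causal Butterworth band-pass along the last axis (online context:
    zero-phase filtering is not available)."""
    return signal.sosfilt(bandpass_sos(band, fs, order), x, axis=-1)


def analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal along the last axis; real part equals the input."""
    return signal.hilbert(np.asarray(x, dtype=float), axis=-1)


def window_coherence(a: np.ndarray, b: np.ndarray) -> float:
    """Single-window magnitude coherence of two analytic windows.

    |sum a conj(b)| / sqrt(sum |a|^2 * sum |b|^2), in [0, 1]. Returns 0
    (with a warning) if either window has zero energy.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("window length mismatch")
    ea = np.sum(np.abs(a) ** 2)
    eb = np.sum(np.abs(b) ** 2)
    if ea == 0 or eb == 0:
        warnings.warn("zero-energy window in coherence; returning 0")
        return 0.0
    return float(np.abs(np.sum(a * np.conj(b))) / np.sqrt(ea * eb))


def coupling_index(win_a: np.ndarray, win_b: np.ndarray,
                   bad_channels: np.ndarray | list | None = None) -> float:
    """Mean homologous-pair coherence over bands.

    ``win_a``/``win_b``: complex arrays (n_bands, n_channels, n_samples).
    Channels flagged in ``bad_channels`` (indices or boolean mask) are
    dropped and the mean renormalized over the remaining pairs.
    """
    win_a = np.asarray(win_a)
    win_b = np.asarray(win_b)
    if win_a.shape != win_b.shape:
        raise ValueError("shape mismatch between subjects")
    n_ch = win_a.shape[1]
    keep = np.ones(n_ch, dtype=bool)
    if bad_channels is not None:
        bad = np.asarray(bad_channels)
        if bad.dtype == bool:
            keep = ~bad
        else:
            keep[bad.astype(int)] = False
    if not keep.any():
        raise ValueError("no valid channel pairs remain")
    vals = [window_coherence(win_a[b, c], win_b[b, c])
            for b in range(win_a.shape[0]) for c in np.nonzero(keep)[0]]
    return float(np.mean(vals))


def normalize_minmax(v: float, norm_max: float = 0.3) -> float:
    """Fixed-range min-max normalization: clip(v / norm_max, 0, 1)."""
    if v < 0:
        raise ValueError("raw index must be non-negative")
    return float(np.clip(v / norm_max, 0.0, 1.0))


def avatar_distance(norm_index: float) -> float:
    """Normalized avatar separation: 1 at zero coupling, 0 at full overlap."""
    if not 0.0 <= norm_index <= 1.0:
        raise ValueError("normalized index must lie in [0, 1]")
    return 1.0 - norm_index


@dataclass
class FeedbackTrace:
    """Per-tick feedback values for one session."""

    frames: pd.DataFrame  # TRACE_COLUMNS
    mode: str  # real | sham
    window_s: float
    update_rate_hz: float
    dyad_id: str = "dyad"

    def __post_init__(self):
        t = self.frames["t"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("frames must be strictly increasing in t")


def _band_pair_coherence(xa: np.ndarray, xb: np.ndarray, fs: float,
                         window: int, tick_ends: np.ndarray,
                         order: int = 4) -> np.ndarray:
    """Coherence per band/channel/tick for one segment.

    ``xa``/``xb``: (n_channels, n_samples) raw segment. Causal filtering of
    the whole segment once is exactly equivalent to streaming the filter
    state across ticks. Returns (n_bands, n_channels, n_ticks).
    """
    n_ch = xa.shape[0]
    out = np.empty((len(BAND_ORDER), n_ch, len(tick_ends)))
    idx = tick_ends[:, None] + np.arange(-window, 0)[None, :]  # (ticks, win)
    chunk = 256  # ticks per Hilbert batch, bounds transient memory
    for bi, name in enumerate(BAND_ORDER):
        sos = bandpass_sos(CANONICAL_BANDS[name], fs, order)
        fa = signal.sosfilt(sos, xa, axis=-1)
        fb = signal.sosfilt(sos, xb, axis=-1)
        for j0 in range(0, len(tick_ends), chunk):
            sl = slice(j0, j0 + chunk)
            wa = signal.hilbert(fa[:, idx[sl]], axis=-1)  # (ch, ticks, win)
            wb = signal.hilbert(fb[:, idx[sl]], axis=-1)
            num = np.abs(np.einsum("ctw,ctw->ct", wa, np.conj(wb)))
            ea = np.sum(np.abs(wa) ** 2, axis=-1)
            eb = np.sum(np.abs(wb) ** 2, axis=-1)
            den = np.sqrt(ea * eb)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[bi, :, sl] = np.where(den > 0, num / den, 0.0)
    return out


def run_feedback_session(recording: DyadRecording, mode: str = "real",
                         window_s: float = 3.0, update_rate_hz: float = 12.0,
                         norm_max: float = 0.3, sham_seed: int = 0,
                         filter_order: int = 4) -> FeedbackTrace:
    """Replay the closed-loop feedback computation over the round segments.

    Frames are emitted at a fixed ``update_rate_hz`` tick, starting
    ``window_s`` after each round onset (buffer initialization). In sham
    mode the dyad's EEG is replaced by per-subject uniform-noise streams of
    the same shape, reproducible from ``sham_seed`` alone — the sham trace
    carries no information from the recording.
    """
    if mode not in ("real", "sham"):
        raise ValueError("mode must be 'real' or 'sham'")
    fs = recording.fs
    window = int(round(window_s * fs))
    if window > recording.n_samples:
        raise ValueError("window longer than available data")
    n_ch = len(recording.channel_labels)

    rows = []
    for ri, seg in enumerate(recording.timeline.segments("round")):
        i0 = int(round(seg.onset * fs))
        i1 = int(round(seg.end * fs))
        if mode == "real":
            xa = recording.subject_a[:, i0:i1]
            xb = recording.subject_b[:, i0:i1]
        else:
            base = tuple(np.atleast_1d(np.asarray(sham_seed, dtype=np.uint64)
                                       ).tolist())
            xa = sham_source(n_ch, i1 - i0, seed=(*base, 2 * ri))
            xb = sham_source(n_ch, i1 - i0, seed=(*base, 2 * ri + 1))
        # Ticks relative to round onset; first frame once the buffer is full.
        n_sec = (i1 - i0) / fs
        ticks = np.arange(np.ceil(window_s * update_rate_hz),
                          np.floor(n_sec * update_rate_hz) + 1) / update_rate_hz
        tick_ends = np.round(ticks * fs).astype(int)
        tick_ends = tick_ends[(tick_ends >= window) & (tick_ends <= i1 - i0)]
        coh = _band_pair_coherence(xa, xb, fs, window, tick_ends,
                                   order=filter_order)
        band_mean = coh.mean(axis=1)  # (bands, ticks)
        raw = band_mean.mean(axis=0)
        norm = np.clip(raw / norm_max, 0.0, 1.0)
        for j, te in enumerate(tick_ends):
            rows.append((seg.onset + te / fs, seg.label,
                         *band_mean[:, j], raw[j], norm[j], 1.0 - norm[j]))

    frames = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return FeedbackTrace(frames, mode=mode, window_s=window_s,
                         update_rate_hz=update_rate_hz,
                         dyad_id=recording.dyad_id)


def summarize_trace(trace: FeedbackTrace) -> float:
    """Mean raw coupling index over all frames of the feedback rounds."""
    if len(trace.frames) == 0:
        raise ValueError("empty feedback trace")
    return float(trace.frames["raw_index"].mean())
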