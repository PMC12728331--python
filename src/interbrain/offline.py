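"""Offline interbrain coupling via circular phase correlation.

Pipeline: light preprocessing (bad-channel drop, average re-reference,
0.5-Hz zero-phase high-pass), Morlet-wavelet phase extraction at 1-30 Hz in
1-Hz steps on each continuous segment, non-overlapping 3-s windows (the
last 10 s of each feedback round discarded against edge artifacts), the
circular correlation coefficient (CCorr) of the two partners' phase series
for every electrode combination, and |atanh(CCorr)| averaged over windows
and pairs, yielding a 30-bin coupling spectrum per dyad and session.
Task-related coupling is the task spectrum minus the rest spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .simulate import DyadRecording
from .timeline import SessionTimeline

DEFAULT_FREQS = np.arange(1, 31, dtype=float)  # Hz
ATANH_CLAMP = 1.0 - 1e-7


@dataclass
class CouplingSpectrum:
    """Per-dyad coupling values on a frequency grid for one session."""

    dyad_id: str
    session: str  # task | rest | task_related
    freqs: np.ndarray
    values: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")

    def to_frame(self) -> pd.DataFrame:
        row = {"dyad_id": self.dyad_id, "session": self.session,
               "group": self.group}
        row.update({f"f_{int(f)}": v for f, v in zip(self.freqs, self.values)})
        return pd.DataFrame([row])


def preprocess(recording: DyadRecording,
               bad_channels: list[str] | None = None,
               highpass_hz: float = 0.5,
               ica_hook=None) -> DyadRecording:
    """Drop bad channels, average re-reference, zero-phase high-pass.

    ``ica_hook``, if given, is called as ``hook(data, fs, labels) -> data``
    per subject after filtering; the default pipeline applies no component
    rejection.
    """
    bad = set(bad_channels or [])
    keep = [i for i, c in enumerate(recording.channel_labels) if c not in bad]
    if not keep:
        raise ValueError("all channels flagged bad")
    labels = tuple(recording.channel_labels[i] for i in keep)
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=recording.fs,
                        output="sos")
    out = []
    for data in recording.subjects():
        x = data[keep]
        x = x - x.mean(axis=0, keepdims=True)  # average reference
        x = signal.sosfiltfilt(sos, x, axis=-1)
        if ica_hook is not None:
            x = ica_hook(x, recording.fs, labels)
        out.append(x)
    return DyadRecording(out[0], out[1], recording.fs, labels,
                         recording.timeline, dyad_id=recording.dyad_id,
                         group=recording.group)


def epoch_windows(timeline: SessionTimeline, fs: float, session: str,
                  window_s: float = 3.0,
                  discard_tail_s: float = 10.0) -> list[tuple[int, int]]:
    """Sample-index ranges of non-overlapping analysis windows.

    ``session='task'``: per feedback round, consecutive windows covering the
    round minus its last ``discard_tail_s`` seconds (edge-artifact guard).
    ``session='rest'``: windows tile each rest segment fully.
    """
    if session == "task":
        segs = timeline.segments("round")
        trim = discard_tail_s
    elif session == "rest":
        segs = timeline.segments("rest")
        trim = 0.0
    else:
        raise ValueError("session must be 'task' or 'rest'")
    if not segs:
        raise ValueError(f"timeline has no {session} segments")
    win = int(round(window_s * fs))
    out = []
    for seg in segs:
        usable = seg.duration - trim
        if usable < window_s:
            raise ValueError(f"segment {seg.label} shorter than one window")
        i0 = int(round(seg.onset * fs))
        n_win = int(np.floor(usable / window_s))
        out.extend((i0 + k * win, i0 + (k + 1) * win) for k in range(n_win))
    return out


def morlet_analytic(x: np.ndarray, freqs: np.ndarray, fs: float,
                    n_cycles: float = 6.0,
                    dtype=np.complex128) -> np.ndarray:
    """Complex Morlet wavelet coefficients of a continuous real segment.

    ``x``: (..., n_samples); returns (n_freqs, ..., n_samples) complex
    coefficients whose angle is the instantaneous phase. The wavelet at
    frequency f has a Gaussian envelope with sigma_t = n_cycles/(2 pi f)
    (analytic: positive frequencies only); the segment is mirror-padded by
    the widest half-support, so segments must be at least that long.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    n = x.shape[-1]
    sigmas = n_cycles / (2 * np.pi * freqs)
    half = int(np.ceil(4 * sigmas.max() * fs))
    if n < half:
        raise ValueError("segment shorter than the widest wavelet support")
    xp = np.concatenate([x[..., half - 1::-1], x, x[..., :-half - 1:-1]],
                        axis=-1)
    m = xp.shape[-1]
    nfft = sp_fft.next_fast_len(m)
    Xf = sp_fft.fft(xp, n=nfft, axis=-1).astype(dtype)
    f_axis = sp_fft.fftfreq(nfft, d=1.0 / fs)
    out = np.empty((len(freqs),) + x.shape, dtype=dtype)
    for i, (f0, sig) in enumerate(zip(freqs, sigmas)):
        # Analytic Morlet in the frequency domain: Gaussian at +f0 only.
        kernel = np.exp(-0.5 * ((f_axis - f0) * 2 * np.pi * sig) ** 2)
        kernel[f_axis < 0] = 0.0
        conv = sp_fft.ifft(Xf * kernel.astype(dtype), axis=-1)
        out[i] = conv[..., half:half + n]
    return out


def morlet_phase(x: np.ndarray, freqs: np.ndarray, fs: float,
                 n_cycles: float = 6.0) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] from the Morlet coefficients;
    shaped (n_freqs, ..., n_samples)."""
    return np.angle(morlet_analytic(x, freqs, fs, n_cycles))


def circular_mean(phi: np.ndarray, axis=-1, keepdims=False) -> np.ndarray:
    """Angle of the mean resultant vector."""
    return np.angle(np.mean(np.exp(1j * phi), axis=axis, keepdims=keepdims))


def ccorr(phi: np.ndarray, omega: np.ndarray) -> float:
    """Circular correlation of two phase series.

    sum sin(phi_k - phi_bar) sin(omega_k - omega_bar) /
    sqrt(sum sin^2(phi_k - phi_bar) * sum sin^2(omega_k - omega_bar)),
    with the bars denoting circular means. NaN when either series has zero
    circular variance (undefined; callers exclude such windows).
    """
    phi = np.asarray(phi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if phi.shape != omega.shape:
        raise ValueError("phase series must have equal length")
    sp = np.sin(phi - circular_mean(phi))
    so = np.sin(omega - circular_mean(omega))
    ss_p = np.sum(sp ** 2)
    ss_o = np.sum(so ** 2)
    # zero circular variance up to rounding of the circular mean
    if ss_p < 1e-24 * len(phi) or ss_o < 1e-24 * len(omega):
        return float("nan")
    return float(np.sum(sp * so) / np.sqrt(ss_p * ss_o))


def zccorr_abs(r: float | np.ndarray) -> float | np.ndarray:
    """|atanh(r)|, the coupling contribution of one window; r clamped to
    +/- (1 - 1e-7) so identical signals stay finite."""
    r = np.clip(r, -ATANH_CLAMP, ATANH_CLAMP)
    return np.abs(np.arctanh(r))


def _sin_deviations(u: np.ndarray) -> np.ndarray:
    """sin(phase - circular mean) per window from unit phasors.

    ``u``: (ch, n_win, len) unit-magnitude complex phasors e^{i phi};
    sin(phi - phibar) = Im(u * conj(R/|R|)) with R the window's mean
    resultant. Degenerate windows (|R| = 0) come out all-zero, which the
    caller maps to NaN via a zero sum of squares.
    """
    R = u.mean(axis=-1, keepdims=True)
    mag = np.abs(R)
    with np.errstate(invalid="ignore", divide="ignore"):
        Rn = np.where(mag > 0, R / mag, 0.0)
    # Im(u * conj(Rn)) in real arithmetic (cheaper than complex multiply)
    return u.imag * Rn.real - u.real * Rn.imag


def _window_ccorr_all_pairs(ua: np.ndarray, ub: np.ndarray,
                            bounds: list[tuple[int, int]],
                            offset: int) -> np.ndarray:
    """CCorr for every channel combination and window, all frequencies.

    ``ua``/``ub``: (..., n_channels, n_samples) unit phasors of one
    continuous segment starting at absolute sample ``offset``; the leading
    axes (typically frequency) broadcast through. Returns
    (..., n_a, n_b, n_windows); degenerate windows are NaN.
    """
    win_len = bounds[0][1] - bounds[0][0]
    starts = np.array([b[0] - offset for b in bounds])
    n_win = len(starts)
    if np.array_equal(starts, starts[0] + win_len * np.arange(n_win)):
        # contiguous tiling: reshape is a view, no gather needed
        def windows(u):
            s0 = int(starts[0])
            v = u[..., s0:s0 + n_win * win_len]
            return v.reshape(v.shape[:-1] + (n_win, win_len))
    else:
        idx = starts[:, None] + np.arange(win_len)[None, :]

        def windows(u):
            return u[..., idx]

    sa = _sin_deviations(windows(ua))  # (..., ch, n_win, len) real
    sb = _sin_deviations(windows(ub))
    ss_a = np.sum(sa ** 2, axis=-1)  # (..., ch, n_win)
    ss_b = np.sum(sb ** 2, axis=-1)
    # num[..., i, j, w] = sum_t sa[..., i, w, t] * sb[..., j, w, t]
    num = np.swapaxes(
        np.matmul(np.swapaxes(sa, -3, -2),  # (..., w, i, t)
                  np.swapaxes(sb, -3, -2).swapaxes(-2, -1)),  # (..., w, t, j)
        -3, -1).swapaxes(-3, -2)  # -> (..., i, j, w)
    # threshold well below the O(n/2) sum of squares of genuine phase
    # windows but above float32 rounding of degenerate ones
    eps = 1e-6 * win_len
    den = np.sqrt(ss_a[..., :, None, :] * ss_b[..., None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > eps, num / den, np.nan)
    return r


def dyad_spectrum(recording: DyadRecording,
                  session: str,
                  freqs: np.ndarray = DEFAULT_FREQS,
                  window_s: float = 3.0,
                  discard_tail_s: float = 10.0,
                  n_cycles: float = 6.0,
                  abs_before_average: bool = True) -> CouplingSpectrum:
    """Coupling spectrum of one dyad for one session.

    Per frequency: mean over all ordered channel combinations (14 x 14 for
    the full montage) and all windows of |atanh(CCorr)|. Wavelet convolution
    runs on each continuous segment (round or rest block) before windowing.
    ``abs_before_average=False`` instead averages the signed CCorr over
    windows/pairs first and applies |atanh| to the mean.
    """
    fs = recording.fs
    timeline = recording.timeline
    bounds = epoch_windows(timeline, fs, session, window_s, discard_tail_s)
    segs = timeline.segments("round" if session == "task" else "rest")

    n_f = len(freqs)
    acc = np.zeros(n_f)
    cnt = np.zeros(n_f)
    for seg in segs:
        i0 = int(round(seg.onset * fs))
        i1 = int(round(seg.end * fs))
        seg_bounds = [b for b in bounds if b[0] >= i0 and b[1] <= i1]
        if not seg_bounds:
            continue
        ua = morlet_analytic(recording.subject_a[:, i0:i1], freqs, fs,
                             n_cycles, dtype=np.complex64)
        ub = morlet_analytic(recording.subject_b[:, i0:i1], freqs, fs,
                             n_cycles, dtype=np.complex64)
        for w in (ua, ub):  # normalize to unit phasors in place
            mag = np.abs(w)
            np.maximum(mag, np.float32(1e-30), out=mag)
            w /= mag
        r = _window_ccorr_all_pairs(ua, ub, seg_bounds, i0)  # (f, i, j, w)
        vals = zccorr_abs(r) if abs_before_average else r
        acc += np.nansum(vals, axis=(1, 2, 3))
        cnt += np.sum(np.isfinite(vals), axis=(1, 2, 3))
    if not cnt.any():
        raise ValueError("no valid analysis windows")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    values = mean if abs_before_average else np.asarray(zccorr_abs(mean))
    return CouplingSpectrum(recording.dyad_id, session, freqs, values,
                            group=recording.group)


def task_related(task: CouplingSpectrum,
                 rest: CouplingSpectrum) -> CouplingSpectrum:
    """Element-wise task minus rest coupling for one dyad."""
    if task.dyad_id != rest.dyad_id:
        raise ValueError("spectra belong to different dyads")
    if not np.array_equal(task.freqs, rest.freqs):
        raise ValueError("frequency grids differ")
    return CouplingSpectrum(task.dyad_id, "task_related", task.freqs,
                            task.values - rest.values, group=task.group)


def band_average(spectrum: CouplingSpectrum,
                 band: tuple[float, float]) -> float:
    """Mean of the integer-frequency bins inside [f_lo, f_hi], inclusive."""
    f_lo, f_hi = band
    sel = (spectrum.freqs >= f_lo) & (spectrum.freqs <= f_hi)
    if not sel.any():
        raise ValueError("band contains no frequency bins")
    return float(spectrum.values[sel].mean())


def spectra_to_frame(spectra: list[CouplingSpectrum]) -> pd.DataFrame:
    """Stack spectra into one table (dyad_id, session, group, f_1..f_N)."""
    return pd.concat([s.to_frame() for s in spectra], ignore_index=True)
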