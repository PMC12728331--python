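"""Minimal EDF writing and reading for multichannel EEG.

Writing produces a plain EDF file (256-byte global header, one signal
header block, 16-bit little-endian data records of 1 s); reading delegates
to ``mne.io.read_raw_edf``, which also serves as an independent check on
the writer in the test suite. Amplitudes are in microvolt; EDF's 16-bit
quantization limits round-trip fidelity to (phys range) / 65535.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, fs: float,
              labels: list[str] | tuple[str, ...],
              phys_dim: str = "uV") -> None:
    """Write a (n_channels, n_samples) microvolt matrix as EDF.

    The record duration is 1 s, so ``fs`` must be a positive integer and
    the data are zero-padded to a whole number of records.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise ValueError("data must be (n_channels, n_samples) matching labels")
    if fs <= 0 or fs != int(fs):
        raise ValueError("fs must be a positive integer for 1-s EDF records")
    spr = int(fs)
    n_ch, n = data.shape
    n_rec = int(np.ceil(n / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n] = data

    pmax = float(np.max(np.abs(padded)))
    pmax = max(pmax, 1.0)
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate X X X X", 80))
        f.write(_pad(now.strftime("%d.%m.%y"), 8))
        f.write(_pad(now.strftime("%H.%M.%S"), 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_ch), 4))
        for lab in labels:
            f.write(_pad(str(lab), 16))
        for _ in labels:
            f.write(_pad("", 80))  # transducer
        for _ in labels:
            f.write(_pad(phys_dim, 8))
        for _ in labels:
            f.write(_pad(f"{pmin:.4f}"[:8], 8))
        for _ in labels:
            f.write(_pad(f"{pmax:.4f}"[:8], 8))
        for _ in labels:
            f.write(_pad(str(dmin), 8))
        for _ in labels:
            f.write(_pad(str(dmax), 8))
        for _ in labels:
            f.write(_pad("", 80))  # prefiltering
        for _ in labels:
            f.write(_pad(str(spr), 8))
        for _ in labels:
            f.write(_pad("", 32))
        # data records: per record, per signal, spr int16 samples
        rec = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(rec).tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (microvolt matrix, fs, labels)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
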