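"""File formats, run configuration and seed plumbing.

Recordings interchange as EDF (one file per subject) or as delimited text
(first line: tab-separated channel labels; then one row of samples per
channel). Timelines and score tables are plain CSV. A run is described by
a single YAML-serializable :class:`RunConfig` whose root seed feeds named
substreams so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_edf import read_edf, write_edf
from .scores import SCORE_COLUMNS
from .simulate import EPOC_CHANNELS, DyadRecording, DyadSimConfig
from .timeline import SessionTimeline, TimelineEntry

# ----------------------------------------------------------- recordings


def write_matrix_delimited(path, data: np.ndarray, labels, sep: str = "\t"):
    with open(path, "w") as f:
        f.write(sep.join(labels) + "\n")
        np.savetxt(f, np.asarray(data), delimiter=sep, fmt="%.6f")


def read_matrix_delimited(path, sep: str = "\t"):
    with open(path) as f:
        labels = f.readline().strip().split(sep)
        data = np.loadtxt(f, delimiter=sep)
    data = np.atleast_2d(data)
    if data.shape[0] != len(labels):
        raise ValueError(
            f"{path}: {len(labels)} labels but {data.shape[0]} rows")
    return data, labels


def write_timeline_csv(path, timeline: SessionTimeline):
    pd.DataFrame(timeline.to_records()).to_csv(path, index=False)


def read_timeline_csv(path) -> SessionTimeline:
    df = pd.read_csv(path)
    return SessionTimeline(tuple(
        TimelineEntry(r.label, float(r.onset_s), float(r.duration_s))
        for r in df.itertuples()))


def write_recording(recording: DyadRecording, directory,
                    fmt: str = "delimited") -> dict[str, Path]:
    """Write a dyad recording plus its timeline; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = "edf" if fmt == "edf" else "tsv"
    paths = {"subject_a": directory / f"{recording.dyad_id}_a.{ext}",
             "subject_b": directory / f"{recording.dyad_id}_b.{ext}",
             "timeline": directory / f"{recording.dyad_id}_timeline.csv"}
    for key, data in (("subject_a", recording.subject_a),
                      ("subject_b", recording.subject_b)):
        if fmt == "edf":
            write_edf(paths[key], data, recording.fs,
                      recording.channel_labels)
        elif fmt == "delimited":
            write_matrix_delimited(paths[key], data, recording.channel_labels)
        else:
            raise ValueError("format must be 'edf' or 'delimited'")
    write_timeline_csv(paths["timeline"], recording.timeline)
    return paths


def _read_subject(path, fmt):
    if fmt == "edf":
        data, fs, labels = read_edf(path)
        return data, fs, labels
    data, labels = read_matrix_delimited(path)
    return data, None, labels


def read_recording(path_a, path_b, timeline_path, fmt: str | None = None,
                   fs: float = 128.0,
                   expected_labels=EPOC_CHANNELS,
                   dyad_id: str | None = None,
                   group: str = "real") -> DyadRecording:
    """Load a dyad recording from per-subject files plus a timeline CSV.

    ``fmt`` defaults from the file extension. Channel labels are validated
    against ``expected_labels`` when given: missing labels raise, unknown
    extra labels warn.
    """
    path_a, path_b = Path(path_a), Path(path_b)
    if fmt is None:
        fmt = "edf" if path_a.suffix.lower() == ".edf" else "delimited"
    da, fs_a, labels_a = _read_subject(path_a, fmt)
    db, fs_b, labels_b = _read_subject(path_b, fmt)
    if labels_a != labels_b:
        raise ValueError("subject files have different channel labels")
    if fs_a is not None:
        fs = fs_a
    if expected_labels is not None:
        missing = [c for c in expected_labels if c not in labels_a]
        if missing:
            raise ValueError(f"missing expected channels: {missing}")
        extra = [c for c in labels_a if c not in expected_labels]
        if extra:
            warnings.warn(f"unknown channel labels: {extra}")
    timeline = read_timeline_csv(timeline_path)
    n = int(round(timeline.span * fs))
    return DyadRecording(da[:, :n], db[:, :n], fs, tuple(labels_a), timeline,
                         dyad_id=dyad_id or path_a.stem.rsplit("_", 1)[0],
                         group=group)


# ----------------------------------------------------------- score table

def write_scores_csv(path, scores: pd.DataFrame):
    scores[SCORE_COLUMNS].to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    return df[SCORE_COLUMNS]


# -------------------------------------------------------- configuration

SUBSTREAMS = ("sim", "sham", "scores", "bootstrap")


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic experiment."""

    seed: int = 0
    n_per_arm: int = 20
    kappa_real: float = 0.8
    kappa_sham: float = 0.0
    target_band: tuple[float, float] = (21.0, 23.0)
    # timeline
    n_rounds: int = 6
    round_s: float = 100.0
    break_s: float = 20.0
    rest_s: float = 120.0
    # online
    window_s: float = 3.0
    rate_hz: float = 12.0
    norm_max: float = 0.3
    # offline
    freq_lo: float = 1.0
    freq_hi: float = 30.0
    n_cycles: float = 6.0
    discard_tail_s: float = 10.0
    # stats
    n_boot: int = 5000
    fdr_q: float = 0.05
    levene_gate: float = 0.05
    # score generation: offsets giving a pre/post main effect of time
    delta_intercepts: tuple[float, float, float] = (0.3, 0.3, 0.3)
    likert: bool = False

    def substream_seed(self, name: str, index: int = 0) -> np.random.SeedSequence:
        if name not in SUBSTREAMS:
            raise KeyError(f"unknown substream {name!r}")
        return np.random.SeedSequence(
            (int(self.seed), SUBSTREAMS.index(name), int(index)))

    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = yaml.safe_load(text)
        for k in ("target_band", "delta_intercepts"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
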