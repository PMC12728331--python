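"""Session timeline for a dyadic neurofeedback experiment.

The canonical session is a 4-min resting state (2 min eyes closed, then
2 min eyes open) followed by a 12-min feedback block of six 100-s training
rounds, each followed by a 20-s break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REST_EC = "rest_ec"
REST_EO = "rest_eo"
BREAK = "break"


def round_label(k: int) -> str:
    return f"round_{k}"


@dataclass(frozen=True)
class TimelineEntry:
    label: str
    onset: float  # seconds from session start
    duration: float  # seconds

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SessionTimeline:
    """Ordered, non-overlapping labelled segments of one session."""

    entries: tuple[TimelineEntry, ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        prev_end = -1e-9
        for e in self.entries:
            if e.duration <= 0:
                raise ValueError(f"non-positive duration for {e.label}")
            if e.onset < prev_end - 1e-9:
                raise ValueError("timeline entries overlap or are unsorted")
            prev_end = e.end

    @property
    def span(self) -> float:
        """Total session length in seconds (end of last entry)."""
        return self.entries[-1].end if self.entries else 0.0

    def segments(self, kind: str) -> list[TimelineEntry]:
        """Entries of one kind: 'round', 'rest', 'break', or an exact label."""
        if kind == "round":
            return [e for e in self.entries if e.label.startswith("round_")]
        if kind == "rest":
            return [e for e in self.entries if e.label in (REST_EC, REST_EO)]
        if kind == "break":
            return [e for e in self.entries if e.label == BREAK]
        return [e for e in self.entries if e.label == kind]

    @property
    def task_span(self) -> float:
        """Duration of the feedback block (rounds plus breaks), seconds."""
        return sum(e.duration for e in self.entries
                   if e.label.startswith("round_") or e.label == BREAK)

    def to_records(self) -> list[dict]:
        return [{"label": e.label, "onset_s": e.onset, "duration_s": e.duration}
                for e in self.entries]


def make_timeline(
    rest_first: bool = True,
    n_rounds: int = 6,
    round_s: float = 100.0,
    break_s: float = 20.0,
    rest_s: float = 120.0,
    break_after_last: bool = True,
) -> SessionTimeline:
    """Build the study timeline.

    Defaults give 120 s eyes-closed rest, 120 s eyes-open rest, then six
    100-s rounds each followed by a 20-s break (break after the last round
    included, so the feedback block totals 720 s = 12 min).
    ``break_after_last=False`` drops the final break (700-s block).
    """
    entries: list[TimelineEntry] = []
    t = 0.0

    def add(label: str, dur: float):
        nonlocal t
        entries.append(TimelineEntry(label, t, dur))
        t += dur

    if rest_first:
        add(REST_EC, rest_s)
        add(REST_EO, rest_s)
    for k in range(1, n_rounds + 1):
        add(round_label(k), round_s)
        if k < n_rounds or break_after_last:
            add(BREAK, break_s)
    if not rest_first:
        add(REST_EC, rest_s)
        add(REST_EO, rest_s)
    return SessionTimeline(tuple(entries))
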