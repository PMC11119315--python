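"""Event schedules and event-locked epoching.

Labels follow the three-code convention: 1 = no activity (rest),
2 = mental drawing (MD), 3 = spatial navigation (SN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_LABELS = (1, 2, 3)
LABEL_REST, LABEL_MD, LABEL_SN = VALID_LABELS


@dataclass
class EventSchedule:
    """Trial onsets/durations in seconds with integer class labels."""

    onsets: np.ndarray
    durations: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (self.onsets.shape == self.durations.shape == self.labels.shape):
            raise ValueError("onsets, durations and labels must have equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            raise ValueError("event onsets must be non-decreasing")
        bad = set(np.unique(self.labels)) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown event label code(s) {sorted(bad)}; valid codes are {VALID_LABELS}")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class TrialEpoch:
    """One event-locked channel-by-sample data window carrying its class label."""

    data: np.ndarray  # (n_channels, n_samples)
    label: int
    window: tuple[float, float]  # (start offset from onset, length), seconds


def epoch(
    series: np.ndarray,
    fs: float,
    events: EventSchedule,
    window_s: float = 10.0,
    start_offset_s: float = 0.0,
) -> list[TrialEpoch]:
    """Cut one fixed-length epoch per event from a channel-by-sample matrix.

    Each epoch starts ``start_offset_s`` after the event onset (onset rounded
    to the nearest sample) and spans ``round(window_s * fs)`` samples.
    Overlapping epochs are permitted.  An epoch extending past the end of the
    recording is an error.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    n_len = int(round(window_s * fs))
    n_total = series.shape[1]
    out: list[TrialEpoch] = []
    for i in range(len(events)):
        start = int(round((events.onsets[i] + start_offset_s) * fs))
        stop = start + n_len
        if start < 0 or stop > n_total:
            raise ValueError(
                f"epoch for event {i} (onset {events.onsets[i]:g} s, label "
                f"{events.labels[i]}) spans samples [{start}, {stop}) outside "
                f"the recording of {n_total} samples"
            )
        out.append(
            TrialEpoch(series[:, start:stop].copy(), int(events.labels[i]), (start_offset_s, window_s))
        )
    return out
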