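"""Optode montage modeling and channel enumeration.

A continuous-wave fNIRS montage is a set of light *source* and *detector*
optodes placed on the scalp at 10-20 system positions.  Every source-detector
pair forms a measurement channel whose sensitivity depends on the
inter-optode distance: channels much longer than ~40 mm carry too little
light for a usable signal and are conventionally excluded.

The packaged default montage is the 3-source x 6-detector left-motor-cortex
layout (sources FC3, C3, CP3; detectors FC5, C5, CP5, FC1, C1, CP1) with
standard scalp coordinates, which enumerates to 18 channels of which 14
survive a 60 mm distance cut.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Optode",
    "Montage",
    "Channel",
    "ChannelSet",
    "enumerate_channels",
    "filter_by_distance",
    "default_montage",
]


@dataclass(frozen=True)
class Optode:
    """A single source or detector with a 3-D scalp position in millimetres."""

    label: str
    role: str  # "source" | "detector"
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.role not in ("source", "detector"):
            raise ValueError(f"optode {self.label!r}: role must be 'source' or 'detector', got {self.role!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"optode {self.label!r}: position must be a finite 3-vector")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Montage:
    """An ordered collection of optodes with unique labels."""

    optodes: list[Optode] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [o.label for o in self.optodes]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate optode labels in montage: {dupes}")

    @property
    def sources(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "source"]

    @property
    def detectors(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "detector"]

    def __getitem__(self, label: str) -> Optode:
        for o in self.optodes:
            if o.label == label:
                return o
        raise KeyError(label)


@dataclass(frozen=True)
class Channel:
    """A source-detector pair; distance is the Euclidean optode separation in mm."""

    source: str
    detector: str
    distance: float

    @property
    def label(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass
class ChannelSet:
    """An ordered, duplicate-free list of channels.

    Order is stable: sources-major in montage order, detectors inner.  All
    downstream channel indices (``ch00``, ``ch01``, ...) refer to this order.
    """

    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(c.source, c.detector) for c in self.channels]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (source, detector) pairs in channel set")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    def __getitem__(self, i: int) -> Channel:
        return self.channels[i]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def distances(self) -> np.ndarray:
        return np.array([c.distance for c in self.channels], dtype=float)


def enumerate_channels(montage: Montage) -> ChannelSet:
    """Enumerate every source x detector pair as a channel.

    Order is deterministic: sources outer, detectors inner, both in montage
    order.  The default 3 x 6 motor layout therefore yields 18 channels.
    """
    sources, detectors = montage.sources, montage.detectors
    if not sources or not detectors:
        raise ValueError(
            f"montage needs at least one source and one detector "
            f"(got {len(sources)} sources, {len(detectors)} detectors)"
        )
    channels = [
        Channel(s.label, d.label, float(np.linalg.norm(s.xyz - d.xyz)))
        for s in sources
        for d in detectors
    ]
    return ChannelSet(channels)


def filter_by_distance(channels: ChannelSet, max_mm: float = 60.0) -> ChannelSet:
    """Keep channels with inter-optode distance <= ``max_mm``, order preserved."""
    if max_mm <= 0:
        raise ValueError(f"max_mm must be positive, got {max_mm}")
    return ChannelSet([c for c in channels if c.distance <= max_mm])


def default_montage() -> Montage:
    """The packaged 9-optode left-motor montage with standard 10-20 coordinates."""
    from .io import parse_montage_text

    text = (
        importlib.resources.files("nirsfuse")
        .joinpath("data/montage_1020.csv")
        .read_text()
    )
    return parse_montage_text(text)
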