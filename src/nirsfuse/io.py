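"""Delimited-text readers and writers for raw sessions.

Three sidecar files describe a session:

* raw data:   header ``channel,wavelength_nm,<s0>,<s1>,...``; one row per
  channel x wavelength; a comment line ``# fs_hz=<float>`` carries the
  sampling rate.  Channel identifiers are ``SOURCE-DETECTOR`` labels.
* montage:    ``label,role,x_mm,y_mm,z_mm``
* events:     ``onset_s,duration_s,label``

Comma or tab delimiters are autodetected.  An optional SNIRF reader can be
registered via :func:`register_raw_reader` behind the same RawScan contract.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .epochs import EventSchedule
from .montage import Channel, ChannelSet, Montage, Optode

WAVELENGTHS = (760, 850)


@dataclass
class RawScan:
    """Two-wavelength raw intensity recording.

    Rows are channel-major with the wavelength pair (760, 850) inner, so row
    ``2*i`` is channel ``i`` at 760 nm and row ``2*i + 1`` at 850 nm.
    Intensities are strictly positive (arbitrary units).
    """

    values: np.ndarray  # (2 * n_channels, n_samples)
    wavelengths: np.ndarray  # per row, nm
    fs: float
    channels: ChannelSet  # one entry per channel (not per row)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=int)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n_ch = len(self.channels)
        if self.values.shape[0] != 2 * n_ch or self.wavelengths.shape[0] != 2 * n_ch:
            raise ValueError(
                f"expected {2 * n_ch} rows (both wavelengths for each of "
                f"{n_ch} channels), got {self.values.shape[0]}"
            )
        expected = np.tile(np.array(WAVELENGTHS), n_ch)
        if not np.array_equal(self.wavelengths, expected):
            raise ValueError("rows must be channel-major with wavelengths (760, 850) per channel")
        bad = np.argwhere(~(self.values > 0))
        if bad.size:
            r, c = bad[0]
            ch = self.channels[int(r) // 2].label
            raise ValueError(
                f"non-positive intensity {self.values[r, c]:g} at channel "
                f"{ch}, wavelength {self.wavelengths[r]} nm, sample {c}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])

    def channel_pair(self, i: int) -> np.ndarray:
        """(2, n_samples) intensities of channel ``i`` at (760, 850) nm."""
        return self.values[2 * i : 2 * i + 2]


# ---------------------------------------------------------------------------
# parsing helpers

def _sniff_sep(text: str) -> str:
    first = text.lstrip().splitlines()[0]
    return "\t" if "\t" in first else ","


def parse_montage_text(text: str) -> Montage:
    df = pd.read_csv(_io.StringIO(text), sep=_sniff_sep(text), comment="#", float_precision="round_trip")
    required = {"label", "role", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage file must have columns {sorted(required)}, got {list(df.columns)}")
    optodes = [
        Optode(str(r.label), str(r.role), (float(r.x_mm), float(r.y_mm), float(r.z_mm)))
        for r in df.itertuples()
    ]
    return Montage(optodes)


def load_montage(path: str | Path) -> Montage:
    return parse_montage_text(Path(path).read_text())


def load_events(path: str | Path) -> EventSchedule:
    text = Path(path).read_text()
    df = pd.read_csv(_io.StringIO(text), sep=_sniff_sep(text), comment="#", float_precision="round_trip")
    required = {"onset_s", "duration_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"events file must have columns {sorted(required)}, got {list(df.columns)}")
    return EventSchedule(df["onset_s"].to_numpy(), df["duration_s"].to_numpy(), df["label"].to_numpy())


def load_raw(
    data_path: str | Path,
    montage_path: str | Path,
    events_path: str | Path,
    fs: float | None = None,
) -> tuple[RawScan, EventSchedule]:
    """Read a session (raw intensities + montage + events) with validation.

    The sampling rate is taken from a ``# fs_hz=...`` comment line in the raw
    file unless ``fs`` is given explicitly.  Row labels must reference
    montage optodes; each referenced channel must appear at both 760 and
    850 nm.
    """
    montage = load_montage(montage_path)
    events = load_events(events_path)

    text = Path(data_path).read_text()
    if fs is None:
        for line in text.splitlines():
            if line.startswith("#") and "fs_hz=" in line:
                fs = float(line.split("fs_hz=")[1].strip())
                break
        else:
            raise ValueError(f"{data_path}: no '# fs_hz=' line and no explicit fs given")

    df = pd.read_csv(_io.StringIO(text), sep=_sniff_sep(text), comment="#", float_precision="round_trip")
    if df.columns[0] != "channel" or df.columns[1] != "wavelength_nm":
        raise ValueError(f"{data_path}: header must start with 'channel,wavelength_nm'")

    # group rows into channels, preserving first-appearance channel order
    chan_labels: list[str] = []
    for lab in df["channel"]:
        if lab not in chan_labels:
            chan_labels.append(lab)

    samples = df.iloc[:, 2:].to_numpy(dtype=float)
    rows_by_key = {(r.channel, int(r.wavelength_nm)): idx for idx, r in enumerate(df.itertuples(index=False))}

    channels = []
    values = np.empty((2 * len(chan_labels), samples.shape[1]))
    wavelengths = np.empty(2 * len(chan_labels), dtype=int)
    for i, lab in enumerate(chan_labels):
        try:
            src_lab, det_lab = lab.split("-")
        except ValueError:
            raise ValueError(f"{data_path}: channel label {lab!r} is not 'SOURCE-DETECTOR'") from None
        try:
            src, det = montage[src_lab], montage[det_lab]
        except KeyError as e:
            raise ValueError(f"{data_path}: channel {lab!r} references unknown optode {e.args[0]!r}") from None
        channels.append(Channel(src.label, det.label, float(np.linalg.norm(src.xyz - det.xyz))))
        for j, wl in enumerate(WAVELENGTHS):
            key = (lab, wl)
            if key not in rows_by_key:
                raise ValueError(f"{data_path}: channel {lab!r} is missing its {wl} nm row")
            values[2 * i + j] = samples[rows_by_key[key]]
            wavelengths[2 * i + j] = wl

    raw = RawScan(values, wavelengths, float(fs), ChannelSet(channels))
    return raw, events


# ---------------------------------------------------------------------------
# writers (used by the synthetic-session fixture emitter)

def write_raw(raw: RawScan, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as f:
        f.write(f"# fs_hz={raw.fs:g}\n")
        cols = ",".join(f"s{i}" for i in range(raw.n_samples))
        f.write(f"channel,wavelength_nm,{cols}\n")
        for i, ch in enumerate(raw.channels):
            for j, wl in enumerate(WAVELENGTHS):
                row = ",".join(repr(float(v)) for v in raw.values[2 * i + j])
                f.write(f"{ch.label},{wl},{row}\n")
    return path


def write_montage(montage: Montage, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as f:
        f.write("label,role,x_mm,y_mm,z_mm\n")
        for o in montage.optodes:
            x, y, z = (float(v) for v in o.xyz)
            f.write(f"{o.label},{o.role},{x!r},{y!r},{z!r}\n")
    return path


def write_events(events: EventSchedule, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as f:
        f.write("onset_s,duration_s,label\n")
        for i in range(len(events)):
            f.write(
                f"{float(events.onsets[i])!r},{float(events.durations[i])!r},{int(events.labels[i])}\n"
            )
    return path


# optional alternate raw readers (e.g. SNIRF) keyed by format name
_RAW_READERS: dict[str, Callable[..., tuple[RawScan, EventSchedule]]] = {}


def register_raw_reader(name: str, reader: Callable[..., tuple[RawScan, EventSchedule]]) -> None:
    _RAW_READERS[name] = reader


def get_raw_reader(name: str) -> Callable[..., tuple[RawScan, EventSchedule]]:
    if name not in _RAW_READERS:
        raise KeyError(f"no raw reader registered under {name!r}; available: {sorted(_RAW_READERS)}")
    return _RAW_READERS[name]
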