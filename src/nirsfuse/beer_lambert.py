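"""Modified Beer-Lambert conversion: raw intensity -> optical density -> Hb.

For a continuous-wave measurement at wavelength lambda,

    OD(t, lambda) = -log10( I(t, lambda) / I0(lambda) )
                  = sum_i eps_i(lambda) * c_i(t) * DPF(lambda) * d + G(lambda)

with chromophores i in {HbO, HbR}, molar extinction coefficient ``eps`` in
1/(mM*mm), concentration ``c`` in mM, source-detector distance ``d`` in mm,
differential pathlength factor ``DPF`` (dimensionless) and an unknown
scattering offset ``G``.  Referencing intensities against a baseline window
makes the measurement differential (Delta-OD), which cancels G; the 2x2
linear system per channel and sample then yields (Delta-HbO, Delta-HbR).

Concentrations are reported in micromolar throughout.
"""

from __future__ import annotations

import importlib.resources
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import WAVELENGTHS, RawScan
from .montage import ChannelSet

_COND_LIMIT = 1e8


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients eps(lambda, chromophore), 1/(mM*mm)."""

    eps: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        for wl in WAVELENGTHS:
            for chrom in ("HbO", "HbR"):
                if (wl, chrom) not in self.eps:
                    raise ValueError(f"extinction table missing eps({wl} nm, {chrom})")
        if abs(np.linalg.det(self.matrix())) < 1e-12:
            raise ValueError("extinction coefficient matrix is singular")

    def matrix(self) -> np.ndarray:
        """2x2 matrix, rows = wavelengths (760, 850), cols = (HbO, HbR)."""
        return np.array(
            [[self.eps[(wl, "HbO")], self.eps[(wl, "HbR")]] for wl in WAVELENGTHS]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtinctionTable":
        return cls._from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """Packaged standard HbO/HbR coefficients at 760 and 850 nm."""
        text = (
            importlib.resources.files("nirsfuse")
            .joinpath("data/extinction_hb.csv")
            .read_text()
        )
        return cls._from_frame(pd.read_csv(_io.StringIO(text)))

    @classmethod
    def _from_frame(cls, df: pd.DataFrame) -> "ExtinctionTable":
        eps = {
            (int(r.wavelength_nm), str(r.chromophore)): float(r.epsilon_per_mM_mm)
            for r in df.itertuples()
        }
        return cls(eps)


@dataclass
class BeerLambertConfig:
    """Differential pathlength factors per wavelength and the baseline window.

    DPF defaults to 6.0 at both wavelengths (a common adult-head value).  The
    baseline window (seconds from recording start) defines the reference
    intensities I0 that make Delta-OD differential and cancel G.
    """

    dpf: dict[int, float] = field(default_factory=lambda: {760: 6.0, 850: 6.0})
    baseline_window: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for wl in WAVELENGTHS:
            if self.dpf.get(wl, 0.0) <= 0:
                raise ValueError(f"DPF({wl} nm) must be positive")
        lo, hi = self.baseline_window
        if not hi > lo:
            raise ValueError(f"baseline window {self.baseline_window} is empty")


@dataclass
class ODSeries:
    """Differential optical density per raw row (channel x wavelength)."""

    values: np.ndarray  # (2 * n_channels, n_samples), dimensionless
    wavelengths: np.ndarray
    fs: float
    channels: ChannelSet


@dataclass
class HbSeries:
    """Delta-HbO / Delta-HbR per channel per sample, micromolar."""

    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    fs: float
    channels: ChannelSet


@dataclass
class Stream:
    """A single-chromophore channel-by-sample stream (tag 'HbO' or 'HbR')."""

    data: np.ndarray
    fs: float
    channels: ChannelSet
    tag: str


def baseline_reference(raw: RawScan, window: tuple[float, float] | None = None) -> np.ndarray:
    """Mean intensity per row over the baseline window -> reference I0."""
    if window is None:
        window = BeerLambertConfig().baseline_window
    lo, hi = window
    i0, i1 = int(round(lo * raw.fs)), int(round(hi * raw.fs))
    if not (0 <= i0 < i1 <= raw.n_samples):
        raise ValueError(
            f"baseline window [{lo:g}, {hi:g}) s maps to samples [{i0}, {i1}) "
            f"outside the recording of {raw.n_samples} samples"
        )
    return raw.values[:, i0:i1].mean(axis=1)


def intensity_to_od(raw: RawScan, i0: np.ndarray) -> ODSeries:
    """Delta-OD(t) = -log10(I(t) / I0), elementwise per row."""
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("reference intensities I0 must be strictly positive")
    od = -np.log10(raw.values / i0[:, None])
    return ODSeries(od, raw.wavelengths.copy(), raw.fs, raw.channels)


def _system_matrix(ext: ExtinctionTable, cfg: BeerLambertConfig, distance_mm: float) -> np.ndarray:
    # rows: wavelengths; cols: (HbO, HbR); eps scaled mM->uM so concentrations come out in uM
    e = ext.matrix() / 1000.0
    dpf = np.array([cfg.dpf[wl] for wl in WAVELENGTHS])
    return e * dpf[:, None] * distance_mm


def od_to_hb(
    od: ODSeries,
    ext: ExtinctionTable | None = None,
    cfg: BeerLambertConfig | None = None,
) -> HbSeries:
    """Invert the 2-equation Beer-Lambert system per channel and sample.

    Channel distances come from the ODSeries' own channel set.  Raises if the
    eps*DPF*d system is ill-conditioned (condition number > 1e8).
    """
    ext = ext or ExtinctionTable.default()
    cfg = cfg or BeerLambertConfig()
    n_ch = len(od.channels)
    hbo = np.empty((n_ch, od.values.shape[1]))
    hbr = np.empty_like(hbo)
    for i, ch in enumerate(od.channels):
        m = _system_matrix(ext, cfg, ch.distance)
        if np.linalg.cond(m) > _COND_LIMIT:
            raise ValueError(
                f"Beer-Lambert system for channel {ch.label} is ill-conditioned "
                f"(cond {np.linalg.cond(m):.3g} > {_COND_LIMIT:g})"
            )
        conc = np.linalg.solve(m, od.values[2 * i : 2 * i + 2])
        hbo[i], hbr[i] = conc[0], conc[1]
    return HbSeries(hbo, hbr, od.fs, od.channels)


def hb_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    channels: ChannelSet,
    ext: ExtinctionTable | None = None,
    cfg: BeerLambertConfig | None = None,
) -> np.ndarray:
    """Forward model: concentrations (uM) -> Delta-OD rows (channel-major).

    This is the generator's forward path and the round-trip oracle for
    :func:`od_to_hb`.
    """
    ext = ext or ExtinctionTable.default()
    cfg = cfg or BeerLambertConfig()
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    n_ch = len(channels)
    od = np.empty((2 * n_ch, hbo.shape[1]))
    for i, ch in enumerate(channels):
        m = _system_matrix(ext, cfg, ch.distance)
        od[2 * i : 2 * i + 2] = m @ np.vstack([hbo[i], hbr[i]])
    return od


def split_streams(hb: HbSeries) -> tuple[Stream, Stream]:
    """Split into independent HbO and HbR streams for per-stream analysis."""
    return (
        Stream(hb.hbo.copy(), hb.fs, hb.channels, "HbO"),
        Stream(hb.hbr.copy(), hb.fs, hb.channels, "HbR"),
    )


def merge_streams(hbo: Stream, hbr: Stream) -> HbSeries:
    if hbo.tag != "HbO" or hbr.tag != "HbR":
        raise ValueError("merge_streams expects (HbO, HbR) in that order")
    return HbSeries(hbo.data.copy(), hbr.data.copy(), hbo.fs, hbo.channels)
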