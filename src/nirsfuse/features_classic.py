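"""Classical per-epoch features: time-domain moments and PSD descriptors.

The four time-domain statistics follow the exact printed conventions of the
decoding method this package implements:

    mean      mu    = (1/N) sum x_i
    variance  a2    = (1/N) sum (x_i - mu)^2
    skewness  S     = [(1/N) sum (x_i - mu)^3] / [(1/(N-1)) sum (x_i - mu)^2]^(3/2)
    kurtosis  K     = [(1/N) sum (x_i - mu)^4] / [(1/(N-1)) sum (x_i - mu)^2]^2 - 3

i.e. skewness and kurtosis mix a 1/N numerator with 1/(N-1) inner variance
(the distinction from the textbook g1/g2 vanishes for large N, but the
printed forms are kept deliberately).  Kurtosis is excess (Gaussian -> 0).

Frequency-domain features come from an averaged modified periodogram (Welch)
estimate: peak frequency, peak power, and the mean power over the
full-width-half-maximum (FWHM) band around the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .beer_lambert import Stream
from .epochs import TrialEpoch


@dataclass
class PSDEstimate:
    frequencies: np.ndarray  # Hz, ascending
    power: np.ndarray  # signal^2 / Hz

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power spectral density cannot be negative")


def time_domain_features(x: np.ndarray, context: str = "") -> dict[str, float]:
    """Mean, variance (1/N), skewness and excess kurtosis of a sample vector."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    where = f" ({context})" if context else ""
    if n < 4:
        raise ValueError(f"need >= 4 samples for stable moments, got {n}{where}")
    mu = x.mean()
    d = x - mu
    var_n = float(np.mean(d**2))
    var_n1 = float(np.sum(d**2) / (n - 1))
    if var_n == 0.0:
        raise ValueError(f"zero variance: skewness/kurtosis undefined{where}")
    skew = float(np.mean(d**3) / var_n1**1.5)
    kurt = float(np.mean(d**4) / var_n1**2 - 3.0)
    return {"mean": float(mu), "variance": var_n, "skewness": skew, "kurtosis": kurt}


def psd(
    x: np.ndarray,
    fs: float,
    segment_length: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
) -> PSDEstimate:
    """Averaged modified periodogram (Welch) with mean-removal detrending.

    Default segment is ``min(N, 256)`` samples with 50% overlap and a Hann
    window.  By Parseval, the integrated PSD approximates the signal
    variance (to within windowing loss).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if segment_length is None:
        segment_length = min(n, 256)
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds signal length {n}")
    noverlap = int(round(overlap * segment_length))
    f, p = signal.welch(
        x, fs=fs, window=window, nperseg=segment_length, noverlap=noverlap, detrend="constant"
    )
    return PSDEstimate(f, p)


def frequency_features(p: PSDEstimate) -> dict[str, float]:
    """Peak frequency/power and mean power over the FWHM band.

    The FWHM band is the contiguous run of bins around the peak whose power
    stays at or above half the peak, resolved at bin resolution.  Ties for
    the maximum go to the lowest frequency.
    """
    if p.power.size == 0:
        raise ValueError("empty PSD")
    if np.all(p.power == 0):
        raise ValueError("all-zero PSD: peak frequency undefined")
    k = int(np.argmax(p.power))  # argmax takes the first (lowest-frequency) maximum
    half = p.power[k] / 2.0
    lo = k
    while lo > 0 and p.power[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < p.power.size - 1 and p.power[hi + 1] >= half:
        hi += 1
    return {
        "peak_frequency": float(p.frequencies[k]),
        "peak_power": float(p.power[k]),
        "fwhm_band_power": float(p.power[lo : hi + 1].mean()),
    }


CLASSIC_FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "peak_frequency",
    "peak_power",
    "fwhm_band_power",
)


def classic_feature_table(
    epochs: list[TrialEpoch],
    fs: float,
    stream_tag: str,
    psd_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Per-epoch, per-channel classical feature table.

    Columns are ``ch<ii>_<feature>`` for every channel and feature name, plus
    ``label``.  Attributes ``stream`` and ``feature_set`` tag the table.
    """
    psd_kwargs = psd_kwargs or {}
    rows = []
    for e_idx, ep in enumerate(epochs):
        row: dict[str, float] = {}
        for c in range(ep.data.shape[0]):
            x = ep.data[c]
            td = time_domain_features(x, context=f"epoch {e_idx}, channel {c}")
            fd = frequency_features(psd(x, fs, **psd_kwargs))
            for name, val in {**td, **fd}.items():
                row[f"ch{c:02d}_{name}"] = val
        row["label"] = ep.label
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["stream"] = stream_tag
    df.attrs["feature_set"] = "classical"
    return df


def as_feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, labels, feature names)."""
    names = [c for c in table.columns if c != "label"]
    return table[names].to_numpy(dtype=float), table["label"].to_numpy(dtype=int), names


def stream_feature_table(stream: Stream, epochs: list[TrialEpoch], **kw) -> pd.DataFrame:
    return classic_feature_table(epochs, stream.fs, stream.tag, **kw)
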