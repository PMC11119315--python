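"""Synthetic two-wavelength fNIRS session generator with ground truth.

Emulates the study conditions the pipeline is designed for: 14 retained
channels sampled at 12.5 Hz, trials of three classes (rest, mental drawing,
spatial navigation) with event-locked hemodynamic responses, physiological
nuisance oscillations, motion artifacts, and a forward Beer-Lambert model so
the emitted data are raw *intensities* — every pipeline stage from optical
density onward is exercised end-to-end.

Generative model per channel:

* true Delta-HbO = class boxcar convolved with a canonical double-gamma HRF
  (peak 6 s, undershoot 16 s, undershoot ratio 1/6), scaled by the class
  activity map (MD drives channels {3,4,5}; SN drives {9,10,11}; 0-based
  indices into the retained channel order); Delta-HbR = -0.3 x Delta-HbO
  (anticorrelated, attenuated — the physiological HbO/HbR asymmetry).
* additive physiological oscillations with seeded random phases per channel:
  cardiac 1.1 Hz, respiratory 0.25 Hz, Mayer waves 0.1 Hz, plus white noise.
  Amplitudes are in micromolar and apply to both chromophores, so the
  attenuated HbR response has the lower signal-to-noise ratio.
* motion artifacts: exponentially decaying spikes (Poisson arrivals) and
  rare step baseline shifts, logged in the ground truth.
* forward model: Delta-OD = eps * c * DPF * d per wavelength, intensities
  I = 10**(-Delta-OD) around a unit baseline (I0 = 1).

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import io as nio
from .beer_lambert import BeerLambertConfig, ExtinctionTable, hb_to_od
from .epochs import EventSchedule
from .io import RawScan
from .montage import ChannelSet, default_montage, enumerate_channels, filter_by_distance


@dataclass
class HRFParams:
    """Canonical double-gamma hemodynamic response, unit peak amplitude."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


def hrf(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Double-gamma kernel evaluated at times t >= 0 (unit peak)."""
    params = params or HRFParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is defined for t >= 0")
    # gamma pdf with scale 1 peaks at shape-1, so shape = peak + 1
    g1 = stats.gamma.pdf(t, params.peak_s + 1.0)
    g2 = stats.gamma.pdf(t, params.undershoot_s + 1.0)
    h = g1 - params.undershoot_ratio * g2
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


@dataclass
class SynthConfig:
    """Study conditions for one simulated session.

    Amplitudes are micromolar Delta-HbO; the activity maps give 0-based
    channel indices into the 14 retained channels.
    """

    n_trials_per_class: int = 20
    fs: float = 12.5
    n_channels: int = 14
    trial_s: float = 10.0
    iti_s: float = 10.0
    lead_in_s: float = 15.0
    hrf_params: HRFParams = field(default_factory=HRFParams)
    activity_map: dict[int, tuple[tuple[int, ...], float]] = field(
        default_factory=lambda: {2: ((3, 4, 5), 1.0), 3: ((9, 10, 11), 1.0)}
    )
    hbr_ratio: float = -0.3
    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.3
    resp_hz: float = 0.25
    resp_amp: float = 0.3
    mayer_hz: float = 0.1
    mayer_amp: float = 0.2
    white_sd: float = 0.2
    spike_rate_per_min: float = 0.5
    spike_amp: float = 5.0
    shift_prob: float = 0.02
    shift_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_trials_per_class < 1 or self.trial_s <= 0:
            raise ValueError("fs, n_trials_per_class and trial_s must be positive")
        for amp in (self.cardiac_amp, self.resp_amp, self.mayer_amp, self.white_sd,
                    self.spike_amp, self.shift_amp):
            if amp < 0:
                raise ValueError("noise and artifact amplitudes must be >= 0")
        for cls, (chs, amp) in self.activity_map.items():
            if cls not in (2, 3):
                raise ValueError(f"activity map class {cls} must be 2 (MD) or 3 (SN)")
            if amp < 0:
                raise ValueError("activity amplitudes must be >= 0")
            if any(not 0 <= c < self.n_channels for c in chs):
                raise ValueError(f"activity channels {chs} outside 0..{self.n_channels - 1}")

    @property
    def session_s(self) -> float:
        n = 3 * self.n_trials_per_class
        return self.lead_in_s + n * (self.trial_s + self.iti_s)


@dataclass
class SynthGroundTruth:
    """Everything needed to score a pipeline run against the generator."""

    events: EventSchedule
    true_hbo: np.ndarray  # noiseless event-locked response, (n_ch, n_samples), uM
    true_hbr: np.ndarray
    artifact_log: list[dict]
    active_channels: dict[int, tuple[int, ...]]
    seed: int
    config: SynthConfig


def _retained_channels(n: int) -> ChannelSet:
    chs = filter_by_distance(enumerate_channels(default_montage()), 60.0)
    if len(chs) < n:
        raise ValueError(f"default montage provides {len(chs)} channels < requested {n}")
    return ChannelSet(list(chs)[:n])


def build_schedule(cfg: SynthConfig, rng: np.random.Generator) -> EventSchedule:
    """Shuffled interleaving of the three class labels at fixed cadence."""
    labels = np.repeat([1, 2, 3], cfg.n_trials_per_class)
    rng.shuffle(labels)
    onsets = cfg.lead_in_s + np.arange(labels.size) * (cfg.trial_s + cfg.iti_s)
    durations = np.full(labels.size, cfg.trial_s)
    return EventSchedule(onsets, durations, labels)


def simulate_session(cfg: SynthConfig | None = None) -> tuple[RawScan, EventSchedule, SynthGroundTruth]:
    """Generate one session; bitwise-reproducible from (config, seed)."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    channels = _retained_channels(cfg.n_channels)
    n_samples = int(round(cfg.session_s * cfg.fs))
    t = np.arange(n_samples) / cfg.fs

    events = build_schedule(cfg, rng)

    # --- event-locked truth: boxcar per class convolved with the HRF
    kernel_t = np.arange(0, cfg.hrf_params.duration_s, 1.0 / cfg.fs)
    kernel = hrf(kernel_t, cfg.hrf_params)
    true_hbo = np.zeros((cfg.n_channels, n_samples))
    for cls, (chs, amp) in cfg.activity_map.items():
        boxcar = np.zeros(n_samples)
        for i in range(len(events)):
            if events.labels[i] == cls:
                a = int(round(events.onsets[i] * cfg.fs))
                b = min(n_samples, a + int(round(events.durations[i] * cfg.fs)))
                boxcar[a:b] = 1.0
        drive = np.convolve(boxcar, kernel)[:n_samples] / cfg.fs * amp
        # normalise so a sustained trial reaches ~amp at plateau
        plateau = kernel.sum() / cfg.fs
        if plateau > 0:
            drive = drive / plateau
        for c in chs:
            true_hbo[c] += drive
    true_hbr = cfg.hbr_ratio * true_hbo

    # --- physiological oscillations + white noise (per channel, seeded phases)
    hbo = true_hbo.copy()
    hbr = true_hbr.copy()
    for c in range(cfg.n_channels):
        osc = np.zeros(n_samples)
        for f_hz, amp in (
            (cfg.cardiac_hz, cfg.cardiac_amp),
            (cfg.resp_hz, cfg.resp_amp),
            (cfg.mayer_hz, cfg.mayer_amp),
        ):
            osc += amp * np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
        hbo[c] += osc + cfg.white_sd * rng.standard_normal(n_samples)
        osc2 = np.zeros(n_samples)
        for f_hz, amp in (
            (cfg.cardiac_hz, cfg.cardiac_amp),
            (cfg.resp_hz, cfg.resp_amp),
            (cfg.mayer_hz, cfg.mayer_amp),
        ):
            osc2 += amp * np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
        hbr[c] += osc2 + cfg.white_sd * rng.standard_normal(n_samples)

    # --- motion artifacts
    artifact_log: list[dict] = []
    n_spikes = rng.poisson(cfg.spike_rate_per_min * cfg.session_s / 60.0)
    decay = np.exp(-np.arange(int(cfg.fs * 2)) / (0.3 * cfg.fs))  # ~0.3 s decay
    for _ in range(n_spikes):
        c = int(rng.integers(cfg.n_channels))
        s0 = int(rng.integers(n_samples - decay.size))
        amp = cfg.spike_amp * rng.choice([-1.0, 1.0])
        hbo[c, s0 : s0 + decay.size] += amp * decay
        hbr[c, s0 : s0 + decay.size] += amp * decay
        artifact_log.append({"kind": "spike", "channel": c, "time_s": s0 / cfg.fs, "amp": amp})
    for i in range(len(events)):
        if rng.uniform() < cfg.shift_prob:
            c = int(rng.integers(cfg.n_channels))
            s0 = int(round(events.onsets[i] * cfg.fs))
            amp = cfg.shift_amp * rng.choice([-1.0, 1.0])
            hbo[c, s0:] += amp
            hbr[c, s0:] += amp
            artifact_log.append({"kind": "shift", "channel": c, "time_s": s0 / cfg.fs, "amp": amp})

    # --- forward Beer-Lambert to raw intensities around I0 = 1
    od = hb_to_od(hbo, hbr, channels, ExtinctionTable.default(), BeerLambertConfig())
    intensities = 10.0 ** (-od)
    wavelengths = np.tile(np.array(nio.WAVELENGTHS), cfg.n_channels)
    raw = RawScan(intensities, wavelengths, cfg.fs, channels)

    truth = SynthGroundTruth(
        events=events,
        true_hbo=true_hbo,
        true_hbr=true_hbr,
        artifact_log=artifact_log,
        active_channels={cls: chs for cls, (chs, _) in cfg.activity_map.items()},
        seed=cfg.seed,
        config=cfg,
    )
    return raw, events, truth


def write_fixture(
    session: tuple[RawScan, EventSchedule, SynthGroundTruth], directory: str | Path
) -> dict[str, Path]:
    """Write a session in the delimited session format; returns file paths."""
    raw, events, _ = session
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    return {
        "raw": nio.write_raw(raw, directory / "raw.csv"),
        "montage": nio.write_montage(montage, directory / "montage.csv"),
        "events": nio.write_events(events, directory / "events.csv"),
    }
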