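"""End-to-end orchestration: raw intensities -> decoded tasks + reports.

Stage order: acquisition (load or simulate) -> optical density -> hemoglobin
-> per-stream ICA cleaning -> epoching -> classical and fused feature tables
-> two binary classification tasks x streams x feature sets x learners ->
rank-test separability report.

Configuration is one YAML mapping with the per-stage sections below; unknown
keys are rejected before any computation.  A single global seed
deterministically derives every stage's sub-seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beer_lambert import (
    BeerLambertConfig,
    ExtinctionTable,
    baseline_reference,
    intensity_to_od,
    od_to_hb,
    split_streams,
)
from .classify import LearnerSpec, evaluate_tasks, reports_frame
from .epochs import epoch
from .features_classic import classic_feature_table
from .features_fused import FuseConfig, stream_fused_table
from .ica import clean_channels
from .io import load_raw
from .ranktests import separability_table
from .synth import SynthConfig, simulate_session

logger = logging.getLogger(__name__)


def derive_seed(master: int, name: str) -> int:
    """Stable per-stage sub-seed from the global seed and a stage name."""
    return int(
        np.random.SeedSequence([master & 0x7FFFFFFF, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    """Validated full-run configuration (see YAML section names)."""

    seed: int = 0
    data_path: str | None = None
    montage_path: str | None = None
    events_path: str | None = None
    out_dir: str = "nirsfuse_out"
    window_s: float = 10.0
    baseline_window: tuple[float, float] = (0.0, 10.0)
    dpf: dict[int, float] = field(default_factory=lambda: {760: 6.0, 850: 6.0})
    ica_method: str = "fastica"
    ica_n_components: int | None = None
    ica_tol: float = 1e-6
    ica_max_iter: int = 1000
    ica_kurtosis_threshold: float = 5.0
    psd_segment: int | None = None
    psd_overlap: float = 0.5
    psd_window: str = "hann"
    fuse: FuseConfig = field(default_factory=FuseConfig)
    cv_k_folds: int = 5
    learners: tuple[str, ...] = ("knn", "lda", "gbm_light", "gbm_xtreme")
    knn_k: int = 10
    rounds: int = 50
    rank_feature_limit: int | None = None
    synth: SynthConfig | None = field(default_factory=SynthConfig)

    _SECTION_KEYS = {
        "seed", "data_path", "montage_path", "events_path", "out_dir", "window_s",
        "baseline", "ica", "psd", "fuse", "hjorth", "cv", "learner", "rank", "synth",
    }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        unknown = set(d) - cls._SECTION_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")

        def section(name: str, allowed: set[str]) -> dict:
            sec = d.get(name, {}) or {}
            bad = set(sec) - allowed
            if bad:
                raise ValueError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
            return sec

        cfg = cls()
        cfg.seed = int(d.get("seed", 0))
        for k in ("data_path", "montage_path", "events_path"):
            if d.get(k) is not None:
                setattr(cfg, k, str(d[k]))
        cfg.out_dir = str(d.get("out_dir", cfg.out_dir))
        cfg.window_s = float(d.get("window_s", cfg.window_s))

        b = section("baseline", {"window"})
        if "window" in b:
            lo, hi = b["window"]
            cfg.baseline_window = (float(lo), float(hi))

        i = section("ica", {"method", "n_components", "tol", "max_iter", "reject_kurtosis_threshold"})
        cfg.ica_method = i.get("method", cfg.ica_method)
        cfg.ica_n_components = i.get("n_components", cfg.ica_n_components)
        cfg.ica_tol = float(i.get("tol", cfg.ica_tol))
        cfg.ica_max_iter = int(i.get("max_iter", cfg.ica_max_iter))
        cfg.ica_kurtosis_threshold = float(i.get("reject_kurtosis_threshold", cfg.ica_kurtosis_threshold))

        p = section("psd", {"segment", "overlap", "window"})
        cfg.psd_segment = p.get("segment", cfg.psd_segment)
        cfg.psd_overlap = float(p.get("overlap", cfg.psd_overlap))
        cfg.psd_window = p.get("window", cfg.psd_window)

        f = section(
            "fuse",
            {"wavelet", "levels", "trim_frac", "trim_tail", "weight_level", "symlet", "hilbert_output"},
        )
        h = section("hjorth", {"sqrt_mobility"})
        cfg.fuse = FuseConfig(
            wavelet=f.get("wavelet", "db4"),
            levels=int(f.get("levels", 5)),
            trim_frac=float(f.get("trim_frac", 0.25)),
            trim_tail=f.get("trim_tail", "largest"),
            weight_level=int(f.get("weight_level", 4)),
            symlet=f.get("symlet", "sym4"),
            hilbert_output=f.get("hilbert_output", "envelope"),
            sqrt_mobility=bool(h.get("sqrt_mobility", False)),
        )

        c = section("cv", {"k_folds"})
        cfg.cv_k_folds = int(c.get("k_folds", cfg.cv_k_folds))
        l = section("learner", {"kinds", "knn_k", "rounds"})
        if "kinds" in l:
            cfg.learners = tuple(l["kinds"])
        cfg.knn_k = int(l.get("knn_k", cfg.knn_k))
        cfg.rounds = int(l.get("rounds", cfg.rounds))

        r = section("rank", {"feature_limit"})
        cfg.rank_feature_limit = r.get("feature_limit", cfg.rank_feature_limit)

        s = d.get("synth", {})
        if s is None:
            cfg.synth = None
        else:
            valid = {fld for fld in SynthConfig.__dataclass_fields__} - {"hrf_params", "activity_map"}
            bad = set(s) - valid
            if bad:
                raise ValueError(f"unknown key(s) in section 'synth': {sorted(bad)}")
            cfg.synth = SynthConfig(**{k: v for k, v in s.items()})
            cfg.synth.seed = derive_seed(cfg.seed, "synth")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Serializable record of one full pipeline run."""

    config_hash: str
    seed: int
    version: str
    stage_seconds: dict[str, float]
    cv_table: pd.DataFrame
    summary: dict[str, float]  # (task|stream|feature_set|learner) -> mean accuracy
    rank_table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stage_seconds": self.stage_seconds,
            "summary": self.summary,
            "n_rank_rejections_at_0.05": int((self.rank_table["decision_at_0.05"] == "reject").sum())
            if len(self.rank_table)
            else 0,
        }


def run_pipeline(config: PipelineConfig, write_outputs: bool = False) -> RunReport:
    """Execute every stage and return the collected report.

    With ``write_outputs`` the CV fold table, rank table and JSON summary are
    written under ``config.out_dir``.
    """
    timings: dict[str, float] = {}

    def _tic(name: str, t0: float) -> None:
        timings[name] = round(time.perf_counter() - t0, 4)
        logger.info("stage=%s seconds=%.3f", name, timings[name])

    # --- acquisition
    t0 = time.perf_counter()
    if config.data_path is not None:
        if config.montage_path is None or config.events_path is None:
            raise ValueError("data_path requires montage_path and events_path")
        raw, events = load_raw(config.data_path, config.montage_path, config.events_path)
    elif config.synth is not None:
        raw, events, _truth = simulate_session(config.synth)
    else:
        raise ValueError("config must provide input paths or a synth section")
    _tic("acquisition", t0)

    # --- hemodynamics
    t0 = time.perf_counter()
    blcfg = BeerLambertConfig(dpf=dict(config.dpf), baseline_window=config.baseline_window)
    i0 = baseline_reference(raw, blcfg.baseline_window)
    od = intensity_to_od(raw, i0)
    hb = od_to_hb(od, ExtinctionTable.default(), blcfg)
    streams = split_streams(hb)
    _tic("hemodynamics", t0)

    # --- ICA cleaning per stream (on continuous data, before epoching)
    t0 = time.perf_counter()
    cleaned = []
    for st in streams:
        data, _model, _mask = clean_channels(
            st.data,
            n_components=config.ica_n_components,
            seed=derive_seed(config.seed, f"ica-{st.tag}"),
            tol=config.ica_tol,
            max_iter=config.ica_max_iter,
            method=config.ica_method,
            kurtosis_threshold=config.ica_kurtosis_threshold,
        )
        st.data = data
        cleaned.append(st)
    _tic("ica", t0)

    # --- features
    t0 = time.perf_counter()
    psd_kwargs = {
        "segment_length": config.psd_segment,
        "overlap": config.psd_overlap,
        "window": config.psd_window,
    }
    tables: list[pd.DataFrame] = []
    for st in cleaned:
        eps = epoch(st.data, st.fs, events, config.window_s)
        tables.append(classic_feature_table(eps, st.fs, st.tag, psd_kwargs=psd_kwargs))
        tables.append(stream_fused_table(st, events, config.window_s, config.fuse))
    _tic("features", t0)

    # --- classification
    t0 = time.perf_counter()
    specs = [
        LearnerSpec(kind=k, knn_k=config.knn_k, rounds=config.rounds, seed=derive_seed(config.seed, f"learner-{k}"))
        for k in config.learners
    ]
    reports = []
    for table in tables:
        reports.extend(
            evaluate_tasks(table, specs, k_folds=config.cv_k_folds, seed=derive_seed(config.seed, "cv"))
        )
    cv_table = reports_frame(reports)
    summary = {
        f"{r.task}|{r.stream}|{r.feature_set}|{r.learner}": r.mean_accuracy for r in reports
    }
    _tic("classify", t0)

    # --- rank tests on the fused HbO table
    t0 = time.perf_counter()
    fused_hbo = next(
        t for t in tables if t.attrs.get("feature_set") == "fused" and t.attrs.get("stream") == "HbO"
    )
    names = [c for c in fused_hbo.columns if c != "label"]
    if config.rank_feature_limit:
        names = names[: config.rank_feature_limit]
    rank_table = separability_table(fused_hbo, names)
    _tic("rank_tests", t0)

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        stage_seconds=timings,
        cv_table=cv_table,
        summary=summary,
        rank_table=rank_table,
    )

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cv_table.to_csv(out / "cv_folds.csv", index=False)
        rank_table.to_csv(out / "rank_tests.csv", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    return report
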