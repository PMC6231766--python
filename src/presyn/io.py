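"""File formats, pipeline configuration and orchestration.

Trains, traces and event tables travel as plain CSV; summaries and reports
as JSON; images as single-channel grayscale TIFF.  Times are in ms, trace
currents in pA, train amplitudes in nA.  A :class:`PipelineConfig` describes
which stages to run (a stage runs when its block is present); the config and
seed are echoed into the report and every output file carries a short hash
of its generating config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import events as ev
from . import imaging as im
from . import intervals as iv
from . import synthetic as syn
from . import trains as tr

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineStageError",
    "run_pipeline",
    "write_train_csv",
    "read_train_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_events_csv",
    "read_events_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_json",
    "read_json",
]

log = logging.getLogger("presyn")

STAGE_ORDER = (
    "simulate_train",
    "simulate_minis",
    "simulate_images",
    "detect",
    "intervals",
    "train_analysis",
    "coloc",
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; names the stage and carries the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# CSV / TIFF / JSON round-trips
# ---------------------------------------------------------------------------

def write_train_csv(train: tr.EPSCTrain, path) -> None:
    df = pd.DataFrame(
        {
            "stim_index": np.arange(1, train.n_stim + 1),
            "time_ms": train.times_ms,
            "amplitude_nA": train.amplitudes_nA,
        }
    )
    df.to_csv(path, index=False)


def read_train_csv(path) -> tr.EPSCTrain:
    df = pd.read_csv(path)
    for col in ("stim_index", "time_ms", "amplitude_nA"):
        if col not in df.columns:
            raise ValueError(f"train CSV missing column '{col}'")
    df = df.sort_values("stim_index")
    t = df["time_ms"].to_numpy(float)
    if t.size < 2:
        raise ValueError("train CSV must contain at least two stimuli")
    ipi = float(np.median(np.diff(t)))
    return tr.EPSCTrain(ipi_ms=ipi, amplitudes_nA=df["amplitude_nA"].to_numpy(float))


def write_trace_csv(trace: ev.Trace, path) -> None:
    pd.DataFrame({"time_ms": trace.times_ms, "current_pA": trace.samples}).to_csv(
        path, index=False
    )


def read_trace_csv(path) -> ev.Trace:
    df = pd.read_csv(path)
    for col in ("time_ms", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column '{col}'")
    t = df["time_ms"].to_numpy(float)
    if t.size < 2:
        raise ValueError("trace CSV must contain at least two samples")
    dt_ms = float(np.median(np.diff(t)))
    return ev.Trace(
        samples=df["current_pA"].to_numpy(float), fs_hz=1000.0 / dt_ms, t0_ms=float(t[0])
    )


_EVENT_COLS = ("peak_time_ms", "amplitude_pA", "rise_10_90_ms", "decay_half_ms", "area_pA_ms")


def write_events_csv(events: list[ev.MiniEvent], path) -> None:
    pd.DataFrame(
        {col: [getattr(e, col) for e in events] for col in _EVENT_COLS}
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[ev.MiniEvent]:
    df = pd.read_csv(path)
    for col in _EVENT_COLS:
        if col not in df.columns:
            raise ValueError(f"events CSV missing column '{col}'")
    return [ev.MiniEvent(**{c: float(row[c]) for c in _EVENT_COLS})
            for _, row in df.iterrows()]


def write_image_tiff(image: np.ndarray, path, dtype: str = "uint8") -> None:
    if dtype not in ("uint8", "uint16"):
        raise ValueError("dtype must be 'uint8' or 'uint16'")
    lim = 255 if dtype == "uint8" else 65535
    tifffile.imwrite(path, np.clip(np.round(image), 0, lim).astype(dtype))


def read_image_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _strict(cls, d: dict, ctx: str):
    """Build a dataclass from a dict, rejecting unknown keys with a field path."""
    if not isinstance(d, dict):
        raise ValueError(f"{ctx}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"{ctx}: unknown key(s) {sorted(unknown)}; allowed: {sorted(names)}")
    try:
        return cls(**d)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{ctx}: {e}") from e


@dataclass(frozen=True)
class SimulateTrainConfig:
    pool: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    mode: str = "deterministic"

    def __post_init__(self):
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"mode must be deterministic|stochastic, got {self.mode!r}")
        # Validate eagerly so malformed configs fail at load time with context.
        object.__setattr__(self, "pool_params",
                           _strict(syn.ReleasePoolParams, self.pool, "simulate_train.pool"))
        object.__setattr__(self, "protocol_params",
                           _strict(syn.StimProtocol, self.protocol, "simulate_train.protocol"))


@dataclass(frozen=True)
class SimulateMinisConfig:
    params: dict = field(default_factory=dict)
    kernel: dict = field(default_factory=dict)
    duration_ms: float = 30_000.0
    noise_sd_pA: float = 2.0
    fs_hz: float = 20_000.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("simulate_minis.duration_ms must be positive")
        object.__setattr__(self, "interval_params",
                           _strict(syn.MiniIntervalParams, self.params, "simulate_minis.params"))
        object.__setattr__(self, "kernel_params",
                           _strict(syn.MiniKernel, self.kernel, "simulate_minis.kernel"))


@dataclass(frozen=True)
class SimulateImagesConfig:
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        d = dict(self.params)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        object.__setattr__(self, "image_params",
                           _strict(syn.ImageSimParams, d, "simulate_images.params"))


@dataclass(frozen=True)
class DetectConfig:
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "detection_params",
                           _strict(ev.DetectionParams, self.params, "detect.params"))


@dataclass(frozen=True)
class IntervalsConfig:
    fit: bool = True
    min_n: int = 50


@dataclass(frozen=True)
class TrainAnalysisConfig:
    window: tuple[int, int] = (20, 30)
    exponential: bool = True

    def __post_init__(self):
        object.__setattr__(self, "window", tuple(int(v) for v in self.window))


@dataclass(frozen=True)
class ColocConfig:
    background: float = 16.0
    subtract: bool = True


_STAGE_CLASSES = {
    "simulate_train": SimulateTrainConfig,
    "simulate_minis": SimulateMinisConfig,
    "simulate_images": SimulateImagesConfig,
    "detect": DetectConfig,
    "intervals": IntervalsConfig,
    "train_analysis": TrainAnalysisConfig,
    "coloc": ColocConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline description; a stage runs when its block is present."""

    seed: int = 0
    out_dir: str = "presyn_out"
    stages: dict = field(default_factory=dict)  # stage name -> stage config

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if not isinstance(d, dict):
            raise ValueError("config root must be a mapping")
        known = {"seed", "out_dir"} | set(_STAGE_CLASSES)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config: unknown key(s) {sorted(unknown)}; allowed: {sorted(known)}")
        stages = {
            name: _strict(sc, d[name], name)
            for name, sc in _STAGE_CLASSES.items()
            if name in d
        }
        return cls(seed=int(d.get("seed", 0)), out_dir=str(d.get("out_dir", "presyn_out")),
                   stages=stages)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "out_dir": self.out_dir}
        for name, cfg in self.stages.items():
            block = {}
            for f in dataclasses.fields(cfg):
                v = getattr(cfg, f.name)
                block[f.name] = list(v) if isinstance(v, tuple) else v
            out[name] = block
        return out

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:8]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Per-stage outputs plus the parameter echo needed to regenerate them."""

    version: str
    seed: int
    config_hash: str
    config: dict
    stages: dict = field(default_factory=dict)  # stage name -> results dict

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": self.config,
            "stages": self.stages,
        }


def _seed_for(base_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute the configured stages in order and write their outputs.

    Order: simulate -> detect -> intervals -> train-analysis -> coloc.
    Partial pipelines are allowed; any stage failure raises
    :class:`PipelineStageError` naming the stage, with earlier outputs kept.
    """
    from . import __version__

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    report = RunReport(version=__version__, seed=config.seed, config_hash=h,
                       config=config.to_dict())

    ctx: dict = {}  # in-memory products shared between stages
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        cfg = config.stages[stage]
        try:
            results = _STAGE_RUNNERS[stage](cfg, config, ctx, out, h)
        except Exception as e:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineStageError(stage, e) from e
        report.stages[stage] = results
        log.info("stage %s: seed=%s outputs=%s", stage, config.seed,
                 sorted(results.get("files", [])))

    write_json(report.to_dict(), out / f"report_{h}.json")
    return report


def _run_simulate_train(cfg, config, ctx, out: Path, h: str) -> dict:
    if cfg.mode == "stochastic":
        train = syn.simulate_train_stochastic(
            cfg.pool_params, cfg.protocol_params, seed=_seed_for(config.seed, "simulate_train")
        )
    else:
        train = syn.simulate_train_deterministic(cfg.pool_params, cfg.protocol_params)
    path = out / f"train_{h}.csv"
    write_train_csv(train, path)
    ctx["train"] = train
    return {"files": [path.name], "n_stim": train.n_stim, "ipi_ms": train.ipi_ms,
            "mode": cfg.mode}


def _run_simulate_minis(cfg, config, ctx, out: Path, h: str) -> dict:
    seed = _seed_for(config.seed, "simulate_minis")
    times = syn.simulate_mini_times(cfg.interval_params, cfg.duration_ms, seed=seed)
    amps = syn.simulate_mini_amplitudes(cfg.interval_params, times.size, seed=seed + 1)
    trace = syn.render_trace(times, amps, cfg.kernel_params, cfg.noise_sd_pA,
                             fs_hz=cfg.fs_hz, seed=seed + 2, duration_ms=cfg.duration_ms)
    path = out / f"trace_{h}.csv"
    write_trace_csv(trace, path)
    ctx["trace"] = trace
    ctx["mini_truth_times"] = times
    return {"files": [path.name], "n_events": int(times.size),
            "duration_ms": cfg.duration_ms}


def _run_simulate_images(cfg, config, ctx, out: Path, h: str) -> dict:
    cha, chb = syn.simulate_image_pair(
        cfg.image_params, seed=_seed_for(config.seed, "simulate_images")
    )
    pa, pb = out / f"channel_a_{h}.tif", out / f"channel_b_{h}.tif"
    write_image_tiff(cha, pa)
    write_image_tiff(chb, pb)
    ctx["images"] = (cha, chb)
    return {"files": [pa.name, pb.name], "r_target": cfg.image_params.r_target}


def _run_detect(cfg, config, ctx, out: Path, h: str) -> dict:
    if "trace" not in ctx:
        raise ValueError("detect requires a trace (run simulate_minis or load one)")
    detected = ev.detect_minis(ctx["trace"], cfg.detection_params)
    path = out / f"events_{h}.csv"
    write_events_csv(detected, path)
    summary = ev.event_summary(detected, ctx["trace"].duration_ms)
    spath = out / f"event_summary_{h}.json"
    write_json(dataclasses.asdict(summary), spath)
    ctx["events"] = detected
    return {"files": [path.name, spath.name], "n_events": len(detected),
            "frequency_hz": summary.frequency_hz}


def _run_intervals(cfg, config, ctx, out: Path, h: str) -> dict:
    if "events" not in ctx:
        raise ValueError("intervals requires detected events (run detect first)")
    times = np.array([e.peak_time_ms for e in ctx["events"]])
    if times.size < 2:
        raise ValueError("need at least two events to form intervals")
    ivs = np.diff(times)
    results: dict = {"n_intervals": int(ivs.size),
                     "mean_interval_ms": float(np.mean(ivs))}
    files = []
    if cfg.fit and ivs.size >= cfg.min_n:
        fit = iv.fit_hyperexponential(ivs, n_min=cfg.min_n)
        fpath = out / f"interval_fit_{h}.json"
        write_json({"w_fast": fit.w_fast, "percent_fast": fit.percent_fast,
                    "tau_fast_ms": fit.tau_fast_ms, "tau_slow_ms": fit.tau_slow_ms,
                    "rss": fit.rss}, fpath)
        files.append(fpath.name)
        results["fit"] = {"w_fast": fit.w_fast, "tau_fast_ms": fit.tau_fast_ms,
                          "tau_slow_ms": fit.tau_slow_ms, "rss": fit.rss}
    results["files"] = files
    return results


def _run_train_analysis(cfg, config, ctx, out: Path, h: str) -> dict:
    if "train" not in ctx:
        raise ValueError("train_analysis requires a train (run simulate_train or load one)")
    train = ctx["train"]
    est = tr.estimate_quantal_train(train, window=cfg.window)
    results = {
        "ppr": tr.paired_pulse_ratio(train) if train.n_stim >= 2 else None,
        "rrp_nA": est.rrp_nA,
        "slope_pA_per_ms": est.slope_pA_per_ms,
        "pr1": est.pr1,
        "fit_window": list(est.fit_window),
        "flags": list(est.flags),
    }
    if cfg.exponential and train.n_stim >= 10:
        try:
            ex = tr.estimate_pr_exponential(train)
            results["exponential"] = {"tau_stim": ex.tau_stim, "pr": ex.pr,
                                      "fc": ex.fc, "rrp_nA": ex.rrp_nA}
        except tr.FitFailure as e:
            results["exponential"] = {"error": str(e)}
    path = out / f"train_estimates_{h}.json"
    write_json(results, path)
    results["files"] = [path.name]
    return results


def _run_coloc(cfg, config, ctx, out: Path, h: str) -> dict:
    if "images" not in ctx:
        raise ValueError("coloc requires images (run simulate_images or load them)")
    cha, chb = ctx["images"]
    if cfg.subtract:
        cha = im.subtract_background(cha, cfg.background)
        chb = im.subtract_background(chb, cfg.background)
    res = im.pearson(cha, chb)
    path = out / f"coloc_{h}.json"
    write_json({"r": res.r, "n_pixels": res.n_pixels,
                "background": cfg.background, "subtracted": cfg.subtract}, path)
    return {"files": [path.name], "r": res.r, "n_pixels": res.n_pixels}


_STAGE_RUNNERS = {
    "simulate_train": _run_simulate_train,
    "simulate_minis": _run_simulate_minis,
    "simulate_images": _run_simulate_images,
    "detect": _run_detect,
    "intervals": _run_intervals,
    "train_analysis": _run_train_analysis,
    "coloc": _run_coloc,
}
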