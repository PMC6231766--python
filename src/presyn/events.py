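"""Miniature EPSC detection and per-event shape statistics.

Spontaneous single-vesicle fusion events (mEPSCs) appear in voltage-clamp
recordings as brief inward (negative) current deflections of tens of pA.
The detector re-implements the threshold/peak-search scheme of conventional
mini-analysis tools as a deterministic algorithm:

1. subtract a running baseline (trailing 50 ms median) and find threshold
   crossings of the baseline-relative signal in the configured polarity;
2. locate the extremum within the peak-search window, smoothing the peak
   over a small number of points;
3. measure the event baseline as the mean over ``baseline_avg_ms`` ending
   ``baseline_lead_ms`` before the peak, and the amplitude as the absolute
   peak-baseline difference;
4. measure the 10-90% rise time, the time from peak to ``decay_fraction``
   of the amplitude, and the area of the baseline-subtracted event;
5. reject events failing the amplitude or area thresholds.

Defaults match the standard parameter set: threshold 10 pA, 20 ms peak
search, 5 ms baseline lead, 2 ms baseline average, 5 ms decay search, decay
fraction 0.5, area threshold 10 pA*ms, 3-point peak average, negative
polarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trace", "DetectionParams", "MiniEvent", "EventSummary", "detect_minis", "event_summary"]


@dataclass(frozen=True)
class Trace:
    """A signed current trace in pA sampled at ``fs_hz`` (inward current negative)."""

    samples: np.ndarray
    fs_hz: float = 20_000.0
    t0_ms: float = 0.0

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0 or not np.isfinite(self.fs_hz):
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if x.ndim != 1:
            raise ValueError("samples must be 1-D")
        if x.size and not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", x)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) * self.dt_ms


@dataclass(frozen=True)
class DetectionParams:
    threshold_pA: float = 10.0
    peak_search_ms: float = 20.0
    baseline_lead_ms: float = 5.0
    baseline_avg_ms: float = 2.0
    decay_search_ms: float = 5.0
    decay_fraction: float = 0.5
    area_threshold_pA_ms: float = 10.0
    peak_avg_points: int = 3
    polarity: str = "negative"
    baseline_window_ms: float = 50.0  # trailing running-baseline window

    def __post_init__(self):
        for name in ("peak_search_ms", "baseline_lead_ms", "baseline_avg_ms",
                     "decay_search_ms", "baseline_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.decay_fraction < 1:
            raise ValueError("decay_fraction must lie strictly between 0 and 1")
        if self.threshold_pA <= 0:
            raise ValueError("threshold_pA must be positive")
        if self.peak_avg_points < 1:
            raise ValueError("peak_avg_points must be >= 1")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")


@dataclass(frozen=True)
class MiniEvent:
    """One detected spontaneous event; amplitude is a positive magnitude."""

    peak_time_ms: float
    amplitude_pA: float
    rise_10_90_ms: float
    decay_half_ms: float
    area_pA_ms: float


@dataclass(frozen=True)
class EventSummary:
    n_events: int
    duration_ms: float
    frequency_hz: float
    amplitude_pA: dict
    rise_10_90_ms: dict
    decay_half_ms: dict
    area_pA_ms: dict


def _running_baseline(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Trailing median baseline; robust to brief events riding on slow drift."""
    return (
        pd.Series(x).rolling(window=window_samples, min_periods=1).median().to_numpy()
    )


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    """Linear interpolation of the time at which v crosses ``level`` between samples."""
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_minis(trace: Trace, params: DetectionParams | None = None) -> list[MiniEvent]:
    """Detect miniature EPSCs in a current trace.

    Returns events sorted by peak time; an empty list (not an error) when all
    candidates are rejected.  Raises ``ValueError`` for an empty trace or one
    shorter than the analysis windows.
    """
    if params is None:
        params = DetectionParams()
    x = trace.samples
    if x.size == 0:
        raise ValueError("cannot detect events in an empty trace")
    dt = trace.dt_ms
    longest_window_ms = max(
        params.peak_search_ms,
        params.baseline_lead_ms + params.baseline_avg_ms,
        params.decay_search_ms,
    )
    if trace.duration_ms <= longest_window_ms:
        raise ValueError("trace shorter than the detection windows")

    # Work in positive-deflection units: y is the rectified, baseline-relative signal.
    sgn = -1.0 if params.polarity == "negative" else 1.0
    baseline = _running_baseline(x, max(1, round(params.baseline_window_ms / dt)))
    y = sgn * (x - baseline)
    raw = sgn * x  # raw polarity-adjusted signal, for baseline-anchored measures

    above = y >= params.threshold_pA
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if onsets.size == 0:
        return []

    peak_w = max(1, round(params.peak_search_ms / dt))
    candidates: list[int] = []
    for i in onsets:
        j = i + int(np.argmax(y[i : i + peak_w]))
        candidates.append(j)

    # Merge candidates closer than one peak-search window: keep the larger extremum.
    peaks: list[int] = []
    for j in sorted(set(candidates)):
        if peaks and j - peaks[-1] < peak_w:
            if y[j] > y[peaks[-1]]:
                peaks[-1] = j
        else:
            peaks.append(j)

    lead = max(1, round(params.baseline_lead_ms / dt))
    avg = max(1, round(params.baseline_avg_ms / dt))
    half_pk = params.peak_avg_points // 2
    decay_w = max(1, round(params.decay_search_ms / dt))

    events: list[MiniEvent] = []
    for j in peaks:
        b1 = j - lead
        b0 = b1 - avg
        if b1 <= 0:
            continue  # not enough pre-event samples for a baseline
        base = float(np.mean(raw[max(b0, 0) : b1]))

        pk_lo = max(j - half_pk, 0)
        pk_hi = min(j + half_pk + 1, raw.size)
        peak_val = float(np.mean(raw[pk_lo:pk_hi]))
        amp = peak_val - base
        if amp < params.threshold_pA:
            continue

        rel = raw - base  # unsmoothed baseline-subtracted signal for this event

        # 10-90% rise time, interpolated while walking back from the peak.
        t90 = t10 = None
        for i in range(j, max(b1 - 1, 0), -1):
            if t90 is None and rel[i - 1] < 0.9 * amp <= rel[i]:
                t90 = _interp_crossing((i - 1) * dt, i * dt, rel[i - 1], rel[i], 0.9 * amp)
            if rel[i - 1] < 0.1 * amp <= rel[i]:
                t10 = _interp_crossing((i - 1) * dt, i * dt, rel[i - 1], rel[i], 0.1 * amp)
                break
        rise = (t90 - t10) if (t90 is not None and t10 is not None) else float("nan")

        # Time from peak to decay_fraction * amplitude, within the decay window.
        level = params.decay_fraction * amp
        decay = float("nan")
        for i in range(j + 1, min(j + decay_w + 1, rel.size)):
            if rel[i] <= level < rel[i - 1]:
                t_cross = _interp_crossing((i - 1) * dt, i * dt, rel[i - 1], rel[i], level)
                decay = t_cross - j * dt
                break

        # Event area: integral of the baseline-subtracted signal from the 10%
        # rise point to the return below 10% of the amplitude (capped at the
        # decay-search window past the peak).
        w0 = int(t10 / dt) if t10 is not None else max(b1, 0)
        w1 = min(j + decay_w + 1, rel.size)
        for i in range(j + 1, w1):
            if rel[i] <= 0.1 * amp:
                w1 = i + 1
                break
        area = float(np.trapezoid(rel[w0:w1], dx=dt))
        if area < params.area_threshold_pA_ms:
            continue

        events.append(
            MiniEvent(
                peak_time_ms=trace.t0_ms + j * dt,
                amplitude_pA=amp,
                rise_10_90_ms=rise,
                decay_half_ms=decay,
                area_pA_ms=area,
            )
        )
    events.sort(key=lambda e: e.peak_time_ms)
    return events


def _mean_sem(values: np.ndarray) -> dict:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"mean": None, "sem": None, "n": 0}
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return {"mean": float(np.mean(v)), "sem": sem, "n": int(v.size)}


def event_summary(events: list[MiniEvent], duration_ms: float) -> EventSummary:
    """Event frequency (Hz) and mean +/- SEM of the per-event shape statistics."""
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    freq = len(events) / (duration_ms / 1000.0)
    as_arr = lambda attr: np.array([getattr(e, attr) for e in events], dtype=float)
    return EventSummary(
        n_events=len(events),
        duration_ms=float(duration_ms),
        frequency_hz=float(freq),
        amplitude_pA=_mean_sem(as_arr("amplitude_pA")),
        rise_10_90_ms=_mean_sem(as_arr("rise_10_90_ms")),
        decay_half_ms=_mean_sem(as_arr("decay_half_ms")),
        area_pA_ms=_mean_sem(as_arr("area_pA_ms")),
    )
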