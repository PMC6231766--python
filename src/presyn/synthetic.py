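"""Synthetic data generators for evoked trains, spontaneous events and image pairs.

Three generative models make every analysis stage testable without recordings:

* A **depletion-replenishment release model** for evoked EPSC trains.  A
  standing pool of releasable vesicles (expressed as summed postsynaptic
  current N0, in nA) releases a fraction p per stimulus and is refilled at a
  constant rate r (pA/ms), capped at N0:

      E_k = p_k * N_k,    N_{k+1} = min(N0, N_k - E_k + r * ipi)

  The deterministic recursion has the fixed point E_ss = r*ipi, and its
  stochastic counterpart draws binomial release from an integer vesicle pool
  with Poisson replenishment and normally distributed quantal amplitudes.

* A **hyperexponential renewal process** for spontaneous (mini) event times:
  inter-event intervals are drawn from a two-component exponential mixture
  F(t) = 1 - [w*exp(-t/tau_fast) + (1-w)*exp(-t/tau_slow)], capturing the
  fast and slow populations of spontaneous release intervals.

* A **two-channel image synthesizer** producing fluorescence-like pixel
  arrays whose sample Pearson correlation equals a target r by construction
  (the second channel is built from the standardized first channel plus an
  orthogonalized noise field).

All stochastic generators require an explicit seed; there is no hidden
global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import Trace
from .trains import EPSCTrain

__all__ = [
    "ReleasePoolParams",
    "StimProtocol",
    "MiniIntervalParams",
    "MiniKernel",
    "ImageSimParams",
    "simulate_train_deterministic",
    "simulate_train_stochastic",
    "simulate_mini_times",
    "simulate_mini_amplitudes",
    "render_trace",
    "simulate_image_pair",
    "simulate_background_channel",
]


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit seed is required (no hidden global RNG)")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ReleasePoolParams:
    """Generative parameters of the vesicle pool.

    N0_nA is the readily releasable pool as summed postsynaptic current (nA),
    p the per-stimulus release fraction, r_pA_per_ms the replenishment rate,
    q_pA the quantal (single-vesicle) amplitude with coefficient of variation
    q_cv.  ``facilitation_df`` adds an increment to p after each stimulus that
    decays with time constant ``tau_f_ms`` (defaults off); it exists to
    exercise the facilitation-correction branch of the exponential estimator.
    """

    N0_nA: float
    p: float
    r_pA_per_ms: float
    q_pA: float = 50.0
    q_cv: float = 0.0
    facilitation_df: float = 0.0
    tau_f_ms: float = 0.0

    def __post_init__(self):
        vals = (self.N0_nA, self.p, self.r_pA_per_ms, self.q_pA, self.q_cv,
                self.facilitation_df, self.tau_f_ms)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("release-pool parameters must be finite")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.N0_nA <= 0:
            raise ValueError("N0_nA must be positive")
        if self.r_pA_per_ms < 0:
            raise ValueError("r_pA_per_ms must be non-negative")
        if self.q_pA <= 0:
            raise ValueError("q_pA must be positive")
        if self.q_cv < 0:
            raise ValueError("q_cv must be non-negative")


@dataclass(frozen=True)
class StimProtocol:
    """Stimulus count and inter-pulse interval (10 ms = 100 Hz, 5 ms = 200 Hz)."""

    n_stim: int
    ipi_ms: float

    def __post_init__(self):
        if self.n_stim < 1:
            raise ValueError("n_stim must be >= 1")
        if not np.isfinite(self.ipi_ms) or self.ipi_ms <= 0:
            raise ValueError("ipi_ms must be positive and finite")

    @property
    def frequency_hz(self) -> float:
        return 1000.0 / self.ipi_ms


@dataclass(frozen=True)
class MiniIntervalParams:
    """Hyperexponential inter-event-interval mixture plus event amplitudes."""

    w_fast: float
    tau_fast_ms: float
    tau_slow_ms: float
    amp_mean_pA: float = 40.0
    amp_sd_pA: float = 8.0

    def __post_init__(self):
        if not 0.0 <= self.w_fast <= 1.0:
            raise ValueError("w_fast must lie in [0, 1]")
        if self.tau_fast_ms <= 0 or self.tau_slow_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_fast_ms >= self.tau_slow_ms:
            raise ValueError("tau_fast_ms must be smaller than tau_slow_ms")
        if self.amp_mean_pA <= 0 or self.amp_sd_pA < 0:
            raise ValueError("invalid amplitude distribution")

    def interval_cdf(self, t_ms) -> np.ndarray:
        """Closed-form mixture CDF F(t) = 1 - [w e^(-t/tf) + (1-w) e^(-t/ts)]."""
        t = np.asarray(t_ms, dtype=float)
        return 1.0 - (
            self.w_fast * np.exp(-t / self.tau_fast_ms)
            + (1.0 - self.w_fast) * np.exp(-t / self.tau_slow_ms)
        )

    @property
    def mean_interval_ms(self) -> float:
        return self.w_fast * self.tau_fast_ms + (1.0 - self.w_fast) * self.tau_slow_ms


@dataclass(frozen=True)
class MiniKernel:
    """Biexponential unit-peak waveform (exp(-t/tau_decay) - exp(-t/tau_rise))/norm."""

    tau_rise_ms: float = 0.3
    tau_decay_ms: float = 3.0

    def __post_init__(self):
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise_ms must be smaller than tau_decay_ms")

    @property
    def t_peak_ms(self) -> float:
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * math.log(td / tr)

    def evaluate(self, t_ms) -> np.ndarray:
        """Kernel values for times since event onset; zero for t < 0; peak = 1."""
        t = np.asarray(t_ms, dtype=float)
        tp = self.t_peak_ms
        norm = math.exp(-tp / self.tau_decay_ms) - math.exp(-tp / self.tau_rise_ms)
        out = np.where(
            t >= 0.0,
            (np.exp(-t / self.tau_decay_ms) - np.exp(-t / self.tau_rise_ms)) / norm,
            0.0,
        )
        return out


@dataclass(frozen=True)
class ImageSimParams:
    """Two-channel image synthesis targeting a sample Pearson correlation."""

    shape: tuple[int, int] = (256, 256)
    r_target: float = 0.78
    signal_mean: float = 100.0
    signal_sd: float = 25.0
    bg_level: float = 16.0
    smooth_sigma_px: float = 1.0

    def __post_init__(self):
        if len(self.shape) != 2 or min(self.shape) < 16:
            raise ValueError("image shape must be at least 16x16")
        if not -1.0 <= self.r_target <= 1.0:
            raise ValueError("r_target must lie in [-1, 1]")
        if self.signal_sd <= 0:
            raise ValueError("signal_sd must be positive")


# ---------------------------------------------------------------------------
# Evoked trains
# ---------------------------------------------------------------------------

def _facilitated_p(pool: ReleasePoolParams, protocol: StimProtocol) -> np.ndarray:
    """Per-stimulus release fraction p_k with optional decaying facilitation."""
    p = np.full(protocol.n_stim, pool.p)
    if pool.facilitation_df > 0 and pool.tau_f_ms > 0:
        f = 0.0
        decay = math.exp(-protocol.ipi_ms / pool.tau_f_ms)
        for k in range(protocol.n_stim):
            p[k] = min(pool.p + f, 1.0)
            f = (f + pool.facilitation_df) * decay
    return p


def simulate_train_deterministic(
    pool: ReleasePoolParams, protocol: StimProtocol
) -> EPSCTrain:
    """Noise-free depletion-replenishment train; quantal parameters are ignored.

    The recursion E_k = p_k*N_k, N_{k+1} = min(N0, N_k - E_k + r*ipi) converges
    to the steady state E_ss = r*ipi (in nA) whenever E_1 > r*ipi.
    """
    p_k = _facilitated_p(pool, protocol)
    refill_nA = pool.r_pA_per_ms * protocol.ipi_ms / 1000.0
    n = pool.N0_nA
    amps = np.empty(protocol.n_stim)
    for k in range(protocol.n_stim):
        e = p_k[k] * n
        amps[k] = e
        n = min(pool.N0_nA, n - e + refill_nA)
    return EPSCTrain(ipi_ms=protocol.ipi_ms, amplitudes_nA=amps)


def simulate_train_stochastic(
    pool: ReleasePoolParams, protocol: StimProtocol, seed
) -> EPSCTrain:
    """Binomial-release counterpart of the deterministic train.

    The pool is an integer vesicle count M_k = round(1000*N_k/q_pA); each
    stimulus releases Binomial(M_k, p_k) vesicles whose amplitudes are
    Normal(q, q*q_cv) truncated at zero, and Poisson replenishment with mean
    1000*r*ipi/q vesicles refills the pool between stimuli (capped at M_0).
    Reproducible for a fixed seed; the mean over many trains approaches the
    deterministic train.
    """
    rng = _require_seed(seed)
    p_k = _facilitated_p(pool, protocol)
    m0 = int(round(1000.0 * pool.N0_nA / pool.q_pA))
    refill_mean = pool.r_pA_per_ms * protocol.ipi_ms / pool.q_pA  # r*ipi is in pA
    m = m0
    amps = np.empty(protocol.n_stim)
    for k in range(protocol.n_stim):
        released = rng.binomial(m, p_k[k]) if m > 0 else 0
        if released > 0 and pool.q_cv > 0:
            qs = rng.normal(pool.q_pA, pool.q_pA * pool.q_cv, released)
            amp_pA = float(np.sum(np.clip(qs, 0.0, None)))
        else:
            amp_pA = released * pool.q_pA
        amps[k] = amp_pA / 1000.0
        m = min(m0, m - released + int(rng.poisson(refill_mean)))
    return EPSCTrain(ipi_ms=protocol.ipi_ms, amplitudes_nA=amps)


# ---------------------------------------------------------------------------
# Spontaneous events
# ---------------------------------------------------------------------------

def simulate_mini_times(
    params: MiniIntervalParams, duration_ms: float, seed
) -> np.ndarray:
    """Event times of a renewal process with hyperexponential intervals.

    Strictly increasing times in [0, duration_ms]; the first event occurs one
    interval after the recording starts, so a duration shorter than the first
    sampled interval yields an empty array.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = _require_seed(seed)
    times: list[float] = []
    t = 0.0
    # Expected count plus slack; drawn in blocks for speed.
    while True:
        n_block = max(16, int(duration_ms / params.mean_interval_ms) + 8)
        fast = rng.random(n_block) < params.w_fast
        taus = np.where(fast, params.tau_fast_ms, params.tau_slow_ms)
        intervals = rng.exponential(taus)
        for iv in intervals:
            t += iv
            if t > duration_ms:
                return np.asarray(times)
            times.append(t)


def simulate_mini_amplitudes(params: MiniIntervalParams, n: int, seed) -> np.ndarray:
    """Event amplitudes (positive magnitudes, pA), normal truncated at zero."""
    rng = _require_seed(seed)
    return np.clip(rng.normal(params.amp_mean_pA, params.amp_sd_pA, n), 0.0, None)


def render_trace(
    times_ms,
    amplitudes_pA,
    kernel: MiniKernel | None = None,
    noise_sd_pA: float = 0.0,
    fs_hz: float = 20_000.0,
    seed=None,
    duration_ms: float | None = None,
) -> Trace:
    """Render events into a signed current trace (inward deflections negative).

    With zero noise, the trough of an isolated event equals -amplitude to
    within one sample of peak quantization.  ``seed`` is required only when
    ``noise_sd_pA`` > 0.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if kernel is None:
        kernel = MiniKernel()
    times = np.atleast_1d(np.asarray(times_ms, dtype=float))
    amps = np.atleast_1d(np.asarray(amplitudes_pA, dtype=float))
    if times.size != amps.size:
        raise ValueError("times and amplitudes must have equal length")
    if duration_ms is None:
        tail = 10.0 * kernel.tau_decay_ms
        duration_ms = (times.max() + tail) if times.size else tail
    if times.size and (times.min() < 0 or times.max() > duration_ms):
        raise ValueError("event times must lie within the trace duration")

    dt = 1000.0 / fs_hz
    n = int(round(duration_ms / dt))
    x = np.zeros(n)
    support = int(math.ceil(12.0 * kernel.tau_decay_ms / dt))
    for t0, a in zip(times, amps):
        i0 = int(math.floor(t0 / dt))
        i1 = min(i0 + support, n)
        if i0 >= n:
            continue
        tt = np.arange(i0, i1) * dt - t0
        x[i0:i1] -= a * kernel.evaluate(tt)
    if noise_sd_pA > 0:
        rng = _require_seed(seed)
        x = x + rng.normal(0.0, noise_sd_pA, n)
    return Trace(samples=x, fs_hz=fs_hz)


# ---------------------------------------------------------------------------
# Two-channel images
# ---------------------------------------------------------------------------

def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def simulate_image_pair(
    params: ImageSimParams, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Two grayscale channels whose full-frame sample Pearson r equals the target.

    Channel B is built as r*A_hat + sqrt(1-r^2)*eps_perp where A_hat is the
    standardized (lightly smoothed) channel A and eps_perp an independent
    noise field orthogonalized against A_hat, so the sample correlation is
    exact by construction before the final intensity rescaling and the
    clip to [0, 255].
    """
    rng = _require_seed(seed)
    a0 = rng.normal(0.0, 1.0, params.shape)
    e0 = rng.normal(0.0, 1.0, params.shape)
    if params.smooth_sigma_px > 0:
        a0 = gaussian_filter(a0, params.smooth_sigma_px)
        e0 = gaussian_filter(e0, params.smooth_sigma_px)
    a = _standardize(a0)
    # Orthogonalize the noise field against A so the sample correlation is exact.
    e = e0 - (np.sum(e0 * a) / np.sum(a * a)) * a
    e = _standardize(e)
    r = params.r_target
    b = r * a + math.sqrt(max(0.0, 1.0 - r * r)) * e

    to_img = lambda z: np.clip(
        params.bg_level + params.signal_mean + params.signal_sd * z, 0.0, 255.0
    )
    return to_img(a), to_img(b)


def simulate_background_channel(
    shape: tuple[int, int], bg_level: float = 16.0, noise_sd: float = 2.0, seed=None
) -> np.ndarray:
    """Background-only channel: the signal-elimination (nuclease-like) control.

    Pixel intensities are background plus camera noise with no structured
    signal, so its correlation with any signal channel is near zero and its
    ROI mean vanishes after background subtraction.
    """
    rng = _require_seed(seed)
    return np.clip(rng.normal(bg_level, noise_sd, shape), 0.0, 255.0)
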