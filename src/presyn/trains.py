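"""Evoked-train quantal analysis.

High-frequency stimulus trains at a depressing synapse deplete the readily
releasable pool (RRP) of vesicles while replenishment refills it at a roughly
constant rate.  Two classic estimators recover the underlying release
parameters from a train of EPSC peak amplitudes:

* **Cumulative-EPSC back-extrapolation** — the cumulative peak amplitude
  becomes linear once release reaches steady state; the y-intercept of a line
  fitted through the steady-state stimuli estimates the RRP (in nA of summed
  postsynaptic current), the slope estimates the replenishment rate, and the
  first-pulse release probability is Pr1 = P1 / RRP.

* **Exponential decay of peak amplitudes** — peak amplitude versus stimulus
  number is fitted with a single exponential; the decay constant tau (in
  stimulus units) gives Pr = 1 - exp(-1/tau), with an optional facilitation
  correction Fc = RP0/R0 applied when the measured first response R0 falls
  below the fitted curve's initial value RP0.

Amplitudes are exchanged as positive magnitudes in nA; replenishment rates are
reported in pA/ms to match conventional electrophysiology reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EPSCTrain",
    "TrainQuantalEstimate",
    "ExpFitEstimate",
    "FitFailure",
    "paired_pulse_ratio",
    "cumulative_epsc",
    "estimate_quantal_train",
    "estimate_pr_exponential",
    "normalize_train",
    "treatment_ratio",
    "replenishment_fold_change",
    "group_summary",
]


class FitFailure(RuntimeError):
    """A nonlinear fit failed to converge; carries the best attempt found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class EPSCTrain:
    """Ordered EPSC peak magnitudes P1..Pn for one stimulus train.

    Parameters
    ----------
    ipi_ms : float
        Inter-pulse interval in ms (10 ms = 100 Hz, 5 ms = 200 Hz).
    amplitudes_nA : array-like
        Positive peak magnitudes in nA, one per stimulus.
    """

    ipi_ms: float
    amplitudes_nA: np.ndarray

    def __post_init__(self):
        amps = np.asarray(self.amplitudes_nA, dtype=float)
        if not np.isfinite(self.ipi_ms) or self.ipi_ms <= 0:
            raise ValueError(f"ipi_ms must be positive and finite, got {self.ipi_ms}")
        if amps.ndim != 1 or amps.size < 1:
            raise ValueError("amplitudes_nA must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(amps)):
            raise ValueError("amplitudes_nA must be finite")
        if np.any(amps < 0):
            raise ValueError("amplitudes_nA are positive magnitudes; negatives found")
        object.__setattr__(self, "amplitudes_nA", amps)

    @property
    def n_stim(self) -> int:
        return int(self.amplitudes_nA.size)

    @property
    def frequency_hz(self) -> float:
        return 1000.0 / self.ipi_ms

    @property
    def times_ms(self) -> np.ndarray:
        """Stimulus onset times, first stimulus at t = 0."""
        return np.arange(self.n_stim) * self.ipi_ms


@dataclass(frozen=True)
class TrainQuantalEstimate:
    """Cumulative-EPSC (back-extrapolation) estimate for one train."""

    rrp_nA: float
    slope_pA_per_ms: float
    pr1: float
    fit_window: tuple[int, int]
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class ExpFitEstimate:
    """Exponential-decay estimate of release probability for one train."""

    tau_stim: float
    pr: float
    fc: float
    rp0_nA: float
    rrp_nA: float
    steady_state_nA: float
    rss: float


def paired_pulse_ratio(train: EPSCTrain) -> float:
    """Paired-pulse ratio P2/P1.

    Values < 1 indicate paired-pulse depression, > 1 facilitation.
    """
    if train.n_stim < 2:
        raise ValueError("paired_pulse_ratio needs at least two stimuli")
    p1, p2 = train.amplitudes_nA[0], train.amplitudes_nA[1]
    if p1 <= 0:
        raise ValueError("paired_pulse_ratio undefined for P1 = 0")
    return float(p2 / p1)


def cumulative_epsc(train: EPSCTrain) -> np.ndarray:
    """Cumulative peak amplitude C_k = sum_{i<=k} P_i (nA), non-decreasing."""
    return np.cumsum(train.amplitudes_nA)


def estimate_quantal_train(
    train: EPSCTrain, window: tuple[int, int] = (20, 30)
) -> TrainQuantalEstimate:
    """Estimate RRP, replenishment rate and Pr1 by cumulative back-extrapolation.

    An ordinary least-squares line is fitted through (k, C_k) for stimulus
    numbers k in the inclusive 1-based ``window``; its intercept at k = 0 is
    the RRP (nA), its slope per stimulus converted by 1000/ipi_ms is the
    replenishment rate (pA/ms), and Pr1 = P1/RRP.

    A negative intercept or a Pr1 outside [0, 1] does not raise; the estimate
    comes back flagged instead, so that batch analyses can screen cells.
    """
    lo, hi = int(window[0]), int(window[1])
    if lo < 1 or hi <= lo:
        raise ValueError(f"invalid fit window {window}")
    if train.n_stim < hi:
        raise ValueError(
            f"train has {train.n_stim} stimuli; window {window} requires >= {hi}"
        )
    k = np.arange(lo, hi + 1, dtype=float)
    c = cumulative_epsc(train)[lo - 1 : hi]
    slope_nA_per_stim, intercept_nA = np.polyfit(k, c, 1)
    slope_pA_per_ms = slope_nA_per_stim * 1000.0 / train.ipi_ms

    flags: list[str] = []
    if intercept_nA <= 0:
        flags.append("nonpositive_rrp")
        pr1 = float("nan")
    else:
        pr1 = float(train.amplitudes_nA[0] / intercept_nA)
        if not 0.0 <= pr1 <= 1.0:
            flags.append("pr1_out_of_range")
    return TrainQuantalEstimate(
        rrp_nA=float(intercept_nA),
        slope_pA_per_ms=float(slope_pA_per_ms),
        pr1=pr1,
        fit_window=(lo, hi),
        flags=tuple(flags),
    )


def _exp_model(k: np.ndarray, p_ss: float, a: float, tau: float) -> np.ndarray:
    return p_ss + a * np.exp(-(k - 1.0) / tau)


def estimate_pr_exponential(train: EPSCTrain) -> ExpFitEstimate:
    """Estimate release probability from the exponential decay of peak amplitudes.

    P_k is fitted with P_ss + A*exp(-(k-1)/tau) over stimuli k >= 2; the first
    response is excluded from the fit so that facilitation of the first pulse
    does not bias the extrapolated curve.  RP0 is the fitted value at k = 1;
    if the measured first response R0 is smaller than RP0, the facilitation
    correction Fc = RP0/R0 is applied and Pr = (1 - exp(-1/tau))/Fc, otherwise
    Fc = 1.  The implied pool is RRP = RP0/Pr (from the pure-depletion
    relation E1 = Pr*N0 applied to the fitted curve).
    """
    if train.n_stim < 10:
        raise ValueError("estimate_pr_exponential needs at least 10 stimuli")
    amps = train.amplitudes_nA
    k = np.arange(2, train.n_stim + 1, dtype=float)
    y = amps[1:]

    # Initial guesses: steady state from the tail, decay constant from the
    # log-linear slope of the baseline-subtracted early amplitudes.
    p_ss0 = float(np.mean(y[-max(3, y.size // 4) :]))
    resid0 = np.clip(y - p_ss0, 1e-12, None)
    with np.errstate(divide="ignore"):
        lr = np.polyfit(k[: max(5, y.size // 2)], np.log(resid0[: max(5, y.size // 2)]), 1)
    tau0 = -1.0 / lr[0] if lr[0] < 0 else float(y.size) / 2.0
    tau0 = float(np.clip(tau0, 1e-3, 1e4))
    a0 = max(float(y[0] - p_ss0) * np.exp(1.0 / tau0), 1e-9)

    best = None
    for tau_start in (tau0, 1.0, 5.0, 20.0):
        res = least_squares(
            lambda th: _exp_model(k, th[0], th[1], th[2]) - y,
            x0=[max(p_ss0, 0.0), a0, tau_start],
            bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, 1e8]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailure("exponential fit did not converge", best=best)

    p_ss, a, tau = (float(v) for v in best.x)
    if tau <= 0:
        raise FitFailure(f"non-physical decay constant tau={tau}", best=best)

    rp0 = p_ss + a  # fitted curve at k = 1
    r0 = float(amps[0])
    # Facilitation only when R0 falls meaningfully below the fitted curve;
    # a relative guard keeps fit round-off from triggering a spurious Fc.
    fc = rp0 / r0 if (r0 > 0 and rp0 > r0 * (1.0 + 1e-9)) else 1.0
    pr = (1.0 - np.exp(-1.0 / tau)) / fc
    rrp = rp0 / pr if pr > 0 else float("nan")
    return ExpFitEstimate(
        tau_stim=tau,
        pr=float(pr),
        fc=float(fc),
        rp0_nA=float(rp0),
        rrp_nA=float(rrp),
        steady_state_nA=p_ss,
        rss=float(2.0 * best.cost),
    )


def normalize_train(train: EPSCTrain) -> np.ndarray:
    """Amplitudes normalized to the first pulse, P_k/P1 (first element 1)."""
    p1 = train.amplitudes_nA[0]
    if p1 <= 0:
        raise ValueError("cannot normalize a train whose first pulse is 0")
    return train.amplitudes_nA / p1


def treatment_ratio(mean_treated: np.ndarray, mean_control: np.ndarray) -> np.ndarray:
    """Elementwise per-stimulus ratio of treated over control mean peak amplitudes."""
    t = np.asarray(mean_treated, dtype=float)
    c = np.asarray(mean_control, dtype=float)
    if t.shape != c.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {c.shape}")
    if np.any(c <= 0):
        raise ValueError("control entries must be positive")
    return t / c


def replenishment_fold_change(
    rate_hi_pA_per_ms: float, rate_lo_pA_per_ms: float
) -> tuple[float, float]:
    """Fold change of the replenishment rate between two stimulation frequencies.

    Returns ``(raw, rounded)`` where ``rounded`` is the raw ratio rounded to
    two decimals for report output.
    """
    if rate_lo_pA_per_ms <= 0:
        raise ValueError("low-frequency rate must be positive")
    raw = float(rate_hi_pA_per_ms) / float(rate_lo_pA_per_ms)
    return raw, round(raw, 2)


def group_summary(values) -> dict:
    """Group mean +/- SEM of per-cell estimates (averaging per-cell values first)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return {"n": 0, "mean": None, "sem": None}
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {"n": int(v.size), "mean": float(np.mean(v)), "sem": sem}
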