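"""Inter-event-interval statistics.

Spontaneous release intervals at depressing central synapses are well
described by a two-component exponential (hyperexponential) mixture,
revealing fast and slow populations of spontaneous release.  This module
provides the empirical CDF, nonlinear least-squares fitting of the mixture
CDF, a manual two-sample Kolmogorov-Smirnov test (exact D over the pooled
support, asymptotic p-value), pointwise CDF differences, and iterative
two-sided Grubbs outlier screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

from .trains import FitFailure

__all__ = [
    "ECDF",
    "HyperexpFit",
    "KS2Result",
    "GrubbsResult",
    "ecdf",
    "fit_hyperexponential",
    "hyperexp_cdf",
    "ks2",
    "cdf_difference",
    "grubbs",
]


@dataclass(frozen=True)
class ECDF:
    """Right-continuous empirical CDF: value at t is (# observations <= t)/n."""

    x: np.ndarray  # sorted support
    y: np.ndarray  # step values in (0, 1]

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right")
        return idx / self.x.size


@dataclass(frozen=True)
class HyperexpFit:
    """Fitted two-component exponential mixture, identified by tau_fast < tau_slow."""

    w_fast: float
    tau_fast_ms: float
    tau_slow_ms: float
    rss: float

    @property
    def percent_fast(self) -> float:
        """Percent contribution of the fast component (reported as 100*w_fast)."""
        return 100.0 * self.w_fast

    def cdf(self, t) -> np.ndarray:
        return hyperexp_cdf(t, self.w_fast, self.tau_fast_ms, self.tau_slow_ms)


@dataclass(frozen=True)
class KS2Result:
    D: float
    p_value: float
    n1: int
    n2: int


@dataclass(frozen=True)
class GrubbsResult:
    flagged: tuple[int, ...]  # indices into the original sample, in removal order
    g_stats: tuple[float, ...]
    alpha: float


def hyperexp_cdf(t, w_fast: float, tau_fast_ms: float, tau_slow_ms: float) -> np.ndarray:
    """F(t) = 1 - [w e^(-t/tau_f) + (1-w) e^(-t/tau_s)]."""
    tt = np.asarray(t, dtype=float)
    return 1.0 - (
        w_fast * np.exp(-tt / tau_fast_ms)
        + (1.0 - w_fast) * np.exp(-tt / tau_slow_ms)
    )


def ecdf(intervals) -> ECDF:
    """Empirical CDF of a sample of positive intervals (ms)."""
    x = np.sort(np.asarray(intervals, dtype=float))
    if x.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("intervals must be positive and finite")
    y = np.arange(1, x.size + 1) / x.size
    return ECDF(x=x, y=y)


def fit_hyperexponential(intervals, n_min: int = 50) -> HyperexpFit:
    """Fit the hyperexponential CDF to the ECDF by nonlinear least squares.

    The model CDF is evaluated at the sorted observations and fitted against
    the empirical step heights, with multiple starts over log-spaced time
    constants and mixture weights {0.2, 0.5, 0.8}.  Identifiability is
    enforced by ordering tau_fast < tau_slow after the fit.  Raises
    :class:`FitFailure` (carrying the best attempt) if no start converges.
    """
    x = np.sort(np.asarray(intervals, dtype=float))
    if x.size < n_min:
        raise ValueError(f"need at least {n_min} intervals, got {x.size}")
    y = np.arange(1, x.size + 1) / x.size

    def resid(theta):
        return hyperexp_cdf(x, theta[0], theta[1], theta[2]) - y

    qs = np.quantile(x, [0.2, 0.4, 0.7, 0.9])
    tau_f_starts = np.exp(np.linspace(math.log(qs[0]), math.log(qs[1]), 2))
    tau_s_starts = np.exp(np.linspace(math.log(qs[2]), math.log(2.0 * qs[3]), 2))
    lo = [0.0, 1e-6, 1e-6]
    hi = [1.0, np.inf, np.inf]

    best = None
    for w0 in (0.2, 0.5, 0.8):
        for tf0 in tau_f_starts:
            for ts0 in tau_s_starts:
                res = least_squares(
                    resid, x0=[w0, tf0, max(ts0, 1.5 * tf0)], bounds=(lo, hi),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
                if best is None or res.cost < best.cost:
                    best = res
    if best is None or not (best.success and np.all(np.isfinite(best.x))):
        raise FitFailure("hyperexponential fit did not converge", best=best)

    w, tf, ts = (float(v) for v in best.x)
    if tf > ts:  # reorder components so the fast one comes first
        tf, ts = ts, tf
        w = 1.0 - w
    return HyperexpFit(w_fast=w, tau_fast_ms=tf, tau_slow_ms=ts,
                       rss=float(2.0 * best.cost))


def ks2(sample_a, sample_b) -> KS2Result:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact maximum vertical difference between the two empirical CDFs
    over the pooled observations; the p-value uses the asymptotic Kolmogorov
    series Q(lambda) = 2*sum_{j>=1} (-1)^(j-1) exp(-2 j^2 lambda^2) with
    lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D and effective sample size
    ne = n1*n2/(n1+n2).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(fa - fb)))

    ne = a.size * b.size / (a.size + b.size)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    p = 0.0
    for j in range(1, 101):
        term = 2.0 * (-1.0) ** (j - 1) * math.exp(-2.0 * j * j * lam * lam)
        p += term
        if abs(term) < 1e-12:
            break
    return KS2Result(D=d, p_value=float(min(max(p, 0.0), 1.0)),
                     n1=int(a.size), n2=int(b.size))


def cdf_difference(ecdf_a: ECDF, ecdf_b: ECDF, grid) -> np.ndarray:
    """Pointwise A(t) - B(t) on a grid; bounded in [-1, 1]."""
    g = np.asarray(grid, dtype=float)
    return ecdf_a(g) - ecdf_b(g)


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    tq = t_dist.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(tq * tq / (n - 2 + tq * tq))


def grubbs(values, alpha: float = 0.01) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier screen.

    G = max|x - mean|/sd is compared with the t-based critical value; one
    point is removed per pass until no rejection, with at most n-3 passes.
    A zero-variance sample flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    remaining = list(range(x.size))
    flagged: list[int] = []
    g_stats: list[float] = []
    for _ in range(x.size - 3):
        sub = x[remaining]
        sd = float(np.std(sub, ddof=1))
        if sd == 0.0:
            break
        dev = np.abs(sub - np.mean(sub))
        i_max = int(np.argmax(dev))
        g = float(dev[i_max] / sd)
        if g > _grubbs_critical(len(remaining), alpha):
            flagged.append(remaining[i_max])
            g_stats.append(g)
            remaining.pop(i_max)
        else:
            break
    return GrubbsResult(flagged=tuple(flagged), g_stats=tuple(g_stats), alpha=alpha)
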