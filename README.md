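# presyn

Quantal analysis of presynaptic neurotransmitter release, built for
voltage-clamp recordings from large depressing synapses (e.g. the calyx of
Held onto MNTB principal neurons) and the companion imaging experiments.
The package bundles four analysis stages — miniature-EPSC detection,
inter-event-interval modeling, evoked-train quantal analysis, and ROI
colocalization — together with synthetic-data generators that reproduce the
statistical structure each stage assumes, so the whole pipeline is testable
without raw recordings.

## What it computes

**Evoked trains.** During a high-frequency train, release depletes the
readily releasable pool (RRP) while replenishment refills it at a roughly
constant rate *r*:

    E_k = p_k · N_k,    N_{k+1} = min(N0, N_k − E_k + r·IPI)

Two estimators recover the release parameters from a train of peak
amplitudes P₁..Pₙ:

* *Cumulative-EPSC back-extrapolation*: an OLS line through the cumulative
  amplitude C_k over the steady-state stimuli (default window 20–30) gives
  the RRP as its y-intercept (nA), the replenishment rate as its slope
  (converted to pA/ms), and Pr₁ = P₁/RRP.
* *Exponential decay*: fitting P_k ≈ P_ss + A·e^(−(k−1)/τ) gives
  Pr = (1 − e^(−1/τ))/Fc, where the facilitation correction Fc = RP₀/R₀
  applies when the measured first response R₀ falls below the fitted curve's
  initial value RP₀.

Paired-pulse ratio (P₂/P₁), train normalization, treated/control per-stimulus
ratios and replenishment fold changes round out the train analyses.

**Spontaneous events.** A deterministic re-implementation of the classic
mini-detector (threshold 10 pA, 20 ms peak search, 5 ms baseline lead, 2 ms
baseline average, 5 ms decay search, half-decay fraction 0.5, area threshold
10 pA·ms, 3-point peak average, negative polarity) yields per-event
amplitude, 10–90% rise time, half-decay time and area. Inter-event intervals
are modeled with a hyperexponential (two-component exponential mixture) CDF

    F(t) = 1 − [w·e^(−t/τ_fast) + (1−w)·e^(−t/τ_slow)]

fitted to the empirical CDF by multi-start nonlinear least squares; a manual
two-sample Kolmogorov–Smirnov test (exact D over the pooled support,
asymptotic p) and iterative Grubbs outlier screening (α = 1%) support group
comparisons.

**Imaging.** Flat background subtraction (default 16), Pearson correlation
of two channels within an ROI mask, bilinear line-scan profiles, and ROI
mean-intensity ratios.

## Worked example

```python
import numpy as np
import presyn as ps

pool = ps.ReleasePoolParams(N0_nA=16.3, p=0.44, r_pA_per_ms=62.2, q_pA=50.0, q_cv=0.3)
protocol = ps.StimProtocol(n_stim=30, ipi_ms=10.0)  # 100 Hz

train = ps.simulate_train_deterministic(pool, protocol)
est = ps.estimate_quantal_train(train, window=(20, 30))
print(f"PPR        = {ps.paired_pulse_ratio(train):.3f}")
print(f"RRP        = {est.rrp_nA:.2f} nA")
print(f"Pr1        = {est.pr1:.3f}")
print(f"replenish  = {est.slope_pA_per_ms:.1f} pA/ms")

ex = ps.estimate_pr_exponential(train)
print(f"exp-fit Pr = {ex.pr:.3f} (tau = {ex.tau_stim:.2f} stimuli, Fc = {ex.fc:.2f})")

mix = ps.MiniIntervalParams(w_fast=0.64, tau_fast_ms=170.0, tau_slow_ms=740.0)
times = ps.simulate_mini_times(mix, duration_ms=5001 * mix.mean_interval_ms, seed=1)
fit = ps.fit_hyperexponential(np.diff(times))
print(f"mixture    = {fit.percent_fast:.0f}% fast, "
      f"tau_fast = {fit.tau_fast_ms:.0f} ms, tau_slow = {fit.tau_slow_ms:.0f} ms")

a, b = ps.simulate_image_pair(ps.ImageSimParams(r_target=0.78), seed=2)
print(f"Pearson r  = {ps.pearson(ps.subtract_background(a), ps.subtract_background(b)).r:.3f}")
```

prints

```
PPR        = 0.598
RRP        = 14.89 nA
Pr1        = 0.482
replenish  = 62.2 pA/ms
exp-fit Pr = 0.440 (tau = 1.72 stimuli, Fc = 1.00)
mixture    = 66% fast, tau_fast = 178 ms, tau_slow = 768 ms
Pearson r  = 0.780
```

The simulated 16.3 nA pool releasing 44% per stimulus with 62.2 pA/ms
replenishment depresses to its fixed-point amplitude r·IPI = 0.622 nA; the
cumulative estimator back-extrapolates an RRP of N0 − r·IPI/p = 14.89 nA and
returns the replenishment slope exactly, while the exponential method
recovers the generating Pr = 0.44. The interval fit recovers the simulated
64%/170 ms/740 ms mixture to within sampling error, and the image pair hits
its construction target r = 0.78.

## Command line

A thin CLI mirrors the library: `presyn simulate-train`, `simulate-minis`,
`simulate-images`, `detect`, `intervals`, `train-analysis`, `coloc` and
`report` (full pipeline from a JSON config; unknown config keys are rejected
with a field-level message, and every output file carries a short hash of
its generating config).

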