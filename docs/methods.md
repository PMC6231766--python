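# Methods

## Release model

Evoked trains are generated from a depletion–replenishment model of the
readily releasable pool (RRP). The pool is expressed throughout as summed
postsynaptic current: N (nA) rather than a vesicle count, so that the
analyses operate on the same scale as recorded EPSC amplitudes. Per
stimulus k,

    E_k = p_k · N_k,        N_{k+1} = min(N0, N_k − E_k + r·IPI)

with release fraction p ∈ [0, 1], replenishment rate r (pA/ms; r·IPI is
converted to nA per interval), and the pool capped at N0 — replenishment
cannot overfill a finite standing pool, which is the assumption behind
back-extrapolating the cumulative EPSC to a pool size. The recursion has
the fixed point E_ss = r·IPI, and the transient decays geometrically as
(1 − p)^k. Facilitation is off by default; when enabled, each stimulus adds
`facilitation_df` to an accumulator that decays with `tau_f_ms` and is added
to p. It exists solely to exercise the facilitation-correction branch of the
exponential estimator, not to model calcium dynamics.

The stochastic counterpart converts the pool to an integer vesicle count
M_k = round(1000·N_k/q) for quantal amplitude q (pA, default 50), releases
Binomial(M_k, p_k) vesicles per stimulus, draws per-vesicle amplitudes from
Normal(q, q·cv) truncated at zero (default cv 0.3), and replenishes with
Poisson(r·IPI/q) vesicles per interval, capped at M_0. Poisson replenishment
is one consistent reading of a constant mean refill rate; only its mean
matters to the estimators tested here. Every stochastic call takes an
explicit seed and fails without one — there is no hidden global RNG.

Defaults used throughout tests and examples are the control-condition scale
of the system this package targets: N0 = 16.3 nA, p = 0.44, r = 62.2 pA/ms,
100 Hz (IPI 10 ms) and 200 Hz (IPI 5 ms) trains of 30–800 stimuli.

## Train estimators

**Cumulative back-extrapolation.** C_k = Σ_{i≤k} P_i is regressed on the
stimulus number k over an inclusive 1-based window, default (20, 30). The
intercept is evaluated at k = 0; the abscissa convention is not universal,
and this choice makes the depletion-only oracle exact: for the noise-free
model, C_k = (N0 − r·IPI/p) + r·IPI·k − (N0 − r·IPI/p)(1−p)^k, so once the
transient has died the regression returns slope r and intercept
N0 − r·IPI/p identically. The slope per stimulus is converted to pA/ms by
×1000/IPI. Pr₁ = P₁/intercept. The window is a configuration knob: (20, 30)
follows one published convention and (15, 30) another; both are supported
and the default is the former. Note that with a (20, 30) window the
transient term is only ≈(1−p)^20, so the estimate carries a small
predictable bias at low p; the strict oracle-equivalence tests therefore
place the window at stimuli 200–230 of a 400-stimulus train, where the
transient is below double-precision resolution. A nonpositive intercept or
a Pr₁ outside [0, 1] flags the estimate rather than raising, so batch
analyses can screen cells.

**Exponential method.** P_k is fitted with P_ss + A·e^(−(k−1)/τ) by bounded
trust-region least squares (multi-start over τ). The fit uses stimuli
k ≥ 2 and the curve is extrapolated to k = 1 for RP₀: the first response is
the one subject to facilitation, and excluding it keeps the extrapolated
"expected" first response unbiased, which makes the correction
Fc = RP₀/R₀ exact on constructed facilitation cases while leaving
depletion-only recovery exact (the k ≥ 2 points of a geometric decay
determine the same curve). Fc is applied only when RP₀ exceeds R₀ by more
than a 1e-9 relative guard, so fit round-off cannot trigger a spurious
correction. Pr = (1 − e^(−1/τ))/Fc, and the implied pool RRP = RP₀/Pr
follows from the pure-depletion relation E₁ = Pr·N₀ applied to the fitted
curve — the published analyses report such pool values without stating a
formula, and this is one consistent choice, documented as such.

Group statistics average per-cell estimates first and report mean ± SEM.

## Mini detection

The detector reproduces the standard mini-analysis parameter set as a
deterministic algorithm (the interactive "visual inspection" step of GUI
tools is deliberately replaced by fixed rules). A trailing 50 ms running
median serves as the baseline for threshold crossing, because threshold
tools apply their criterion to a baseline-handled signal and a trailing
median is insensitive to the brief events themselves. Candidate peaks are
the extrema within 20 ms of each crossing; candidates closer than one
peak-search window are merged keeping the larger extremum (the parameter
set assumes isolated events). Amplitude is measured against a local
baseline — the mean over 2 ms ending 5 ms before the peak — which makes it
invariant to constant offsets and slow drift. The 10–90% rise time is
interpolated linearly between bracketing samples of the unsmoothed
baseline-subtracted signal; the decay time is the interpolated first return
to 0.5·amplitude within 5 ms of the peak (the half-decay definition of the
parameter set; a 10–90% decay is a different metric and is not what this
detector emits). Area integrates the baseline-subtracted event from the 10%
rise point to the return below 10% of the amplitude, capped at the decay
window. Events below 10 pA amplitude or 10 pA·ms area are rejected.

## Interval statistics

Inter-event intervals are summarized by the right-continuous ECDF and fitted
with the hyperexponential mixture CDF by least squares on the ECDF evaluated
at the sorted observations — matching the practice of fitting cumulative
probability data directly; interval MLE would be statistically more
efficient but answers a different question than "fit the cumulative curve".
Twelve starts (w ∈ {0.2, 0.5, 0.8} × two log-spaced τ_fast × two τ_slow
quantile-anchored values) guard against local minima; identifiability is
enforced by ordering τ_fast < τ_slow after the fit, and the fast-component
contribution is reported as 100·w. Non-convergence raises a `FitFailure`
carrying the best attempt.

The two-sample KS statistic is computed exactly as the maximum vertical
ECDF difference over the pooled observations. The p-value uses the
asymptotic Kolmogorov series Q(λ) = 2·Σ_{j≥1} (−1)^{j−1} e^(−2j²λ²) with
λ = (√n_e + 0.12 + 0.11/√n_e)·D and n_e = n₁n₂/(n₁+n₂); exact combinatorial
p-values are out of scope. Grubbs screening is two-sided at α = 0.01
(configurable), iterating one removal per pass for at most n − 3 passes;
zero-variance samples flag nothing.

## Imaging

Background subtraction is a flat clamp max(I − 16, 0), applied before
correlation by default (both raw and subtracted modes are exposed, since
reported Pearson values do not always state which was used). Pearson r is
the plain product-moment correlation over mask pixels — no Costes
thresholding, no Manders coefficients. Zero variance within the ROI raises
a dedicated error instead of propagating NaN. Line profiles sample the
image by bilinear interpolation at equally spaced points along a segment,
1 pixel wide; averaging width of GUI line tools varies and is not
replicated.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:
geometric depression to a replenishment-limited steady state, binomial
quantal release, renewal-process spontaneous events with hyperexponential
intervals, biexponential unit-peak mEPSC waveforms (τ_rise 0.3 ms, τ_decay
3 ms) on Gaussian noise at 20 kHz, and image pairs whose sample correlation
equals the target by construction (channel B = r·Â + √(1−r²)·ε̂⊥ with the
noise field orthogonalized against the standardized channel A before
rescaling to 8-bit intensities, lightly smoothed with a 1-px Gaussian to
mimic optics). They do not emulate: calcium-dependent facilitation or its
kinetics, receptor desensitization/saturation, series-resistance or filter
artifacts, correlated or 1/f recording noise, event-amplitude/interval
dependence, post-tetanic enhancement of spontaneous release (the interval
parameters are constant in time; a time-varying mechanism is not modeled),
or realistic microscope PSFs and photon noise. Passing tests therefore show
that the estimators are correct for the model class they assume, not that
the model class captures every feature of real recordings.

## Numerical choices and degenerate inputs

Least-squares fits run with tolerances at 1e-12–1e-15 so that exact-data
recovery reaches 1e-6 or better; τ is bounded positive. Empty traces,
empty samples, zero first pulses, zero-variance ROIs, non-finite or
out-of-range parameters raise `ValueError` with the offending field named;
all-rejected detections return an empty list rather than an error. Grubbs
on constant data, p = 0 trains, and durations shorter than the first
sampled interval are all defined no-op/empty cases. Acceptance and test
problem sizes (400-stimulus oracle trains, 200 stochastic replicates,
5000-interval fits × 20 seeds, 256×256 images, 100-event detector suites)
were chosen as the smallest sizes at which the asymptotic claims they test
are expected to hold with comfortable margin.

## Known limitations

The detector is not a template-matching or deconvolution detector and will
undercount overlapping events closer than the peak-search window — by
design, matching the single-event assumption of the stated parameter set.
The ECDF-based mixture fit has higher variance than MLE at equal n,
particularly for the slow component's τ. The exponential Pr estimator
assumes a single dominant depletion time constant; multi-pool kinetics bias
τ. The cumulative method's (20, 30) default window carries the (1−p)^20
transient bias noted above. The image synthesizer controls full-frame
correlation only; per-ROI correlation of a sub-region is subject to
sampling variation around the target.
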