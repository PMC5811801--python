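# Methods

## The model

The package treats the peripheral path from sudomotor-nerve (SN) firing to
measured skin conductance (SCR) as a linear time-invariant system. Two
analytic components define it:

**SN burst model.** An event-locked firing burst is modelled as a Gaussian,

    u(t) = A / (σ√(2π)) · exp(−(t−µ)² / 2σ²) + c

with area `A` (z-units·s), latency `µ` (s, ~1.7 s after the eliciting
stimulus; depends on the recording site along the nerve), dispersion `σ`
(s, ~0.25–0.31 s) and tonic baseline `c`.

**Response function (SCRF).** The impulse response is defined implicitly by
a third-order constant-coefficient linear ODE,

    x⃛ + ϑ₁ẍ + ϑ₂ẋ + ϑ₃x + g·u(t−ϑ₄) = 0,   x(0)=ẋ(0)=ẍ(0)=0.

`ϑ₁…ϑ₃` (s⁻¹, s⁻², s⁻³) set the shape; `ϑ₄` (s) delays the input (negative
values are advances and legitimately occur — they compensate
electrode-to-skin conduction distance). As printed, positive input drives
`x` negative; the gain `g` is unconstrained in sign and absorbs polarity,
so fits to positively recorded conductance return negative gains. Stability
is the Routh–Hurwitz condition `ϑ₁,ϑ₂,ϑ₃ > 0` and `ϑ₁ϑ₂ > ϑ₃`, exposed as
`ScrfParams.is_stable()`; unstable sets are simulated anyway with a logged
warning. Useful closed forms used as test oracles: a constant input `u₀`
settles at `x_ss = −g·u₀/ϑ₃`, and the unit-impulse response integrates to
`−1/ϑ₃` (the slowest pole is `≈ −ϑ₃/ϑ₂`, i.e. a ~17 s tail for the
low-rate parameter set — integral checks need a few hundred seconds of
horizon).

## Numerics

The solver is classical fixed-step RK4 on the data grid with 10× internal
substepping and linear interpolation of the (delayed) input. Because the
system is linear, one RK4 step collapses algebraically to a constant linear
recursion `y[n+1] = T·y[n] + Bₐu[n] + B_bu[n+1]`; the package converts that
recursion to a discrete transfer function (`scipy.signal.ss2tf`) and runs
it through `lfilter`, which reproduces a naive RK4 loop to ~1e-10 relative
while being vectorized. The naive loop lives in the test suite as an
independent oracle; substep halving changes solutions by <1e-4 relative.
Outside the recorded input grid the input is held at its edge values.

Impulse responses are extracted with 5 s of pre-onset padding
(`TimeSeries.start = −5 s`) so that advanced responses (negative `ϑ₄`) are
represented rather than truncated; `convolve_predict` accounts for that
offset when aligning the convolution to the input grid.

## Estimation

`GaussianBurstModel` minimizes the residual sum of squares with Nelder–Mead
from a data-driven start (µ at the epoch peak, σ = 0.3 s, c at the 5th
percentile) plus seeded jittered restarts.

`ScrfModel` minimizes Σ(prediction − observation)² over `(ϑ₁…ϑ₄)` with the
gain profiled out in closed form at every evaluation (slope-only OLS per
scoring window — equivalent to joint estimation and better conditioned).
Optimization is bounded multi-start L-BFGS-B (bounds ϑ₁,ϑ₂ ∈ (0,20],
ϑ₃ ∈ (0,5], ϑ₄ ∈ [−5,5]; deterministic starts spanning typical
electrodermal shapes plus seeded random ones) followed by a Nelder–Mead
polish — finite-difference gradients resolve the delay parameter poorly.
Optional Gaussian priors on the coefficients add a quadratic penalty (MAP);
this stands in for the original variational-Bayes machinery, whose priors
and convergence criteria were never published, and is sufficient because
everything downstream consumes point estimates, gains and explained
variance. ϑ-space is shallowly identified (different coefficient vectors
give near-identical impulse responses up to scale), so recovery is judged
on impulse-response shape (R² against truth) and on the identified area
`g/ϑ₃`, not on raw coefficients.

**Measurement forward model.** Pipeline fits compare the observation with a
prediction passed through the *known* measurement dynamics: the
preprocessing high-pass (0.0159 Hz) and, for stimulation-style data, the
recording device's rise/decay response that the cumulative-sum
reconstruction does not undo. Omitting this forces the estimator to explain
filter distortion with response-function shape; with it, the end-to-end fit
recovers the generating impulse response essentially exactly
(shape R² > 0.99 at 5% noise).

**Gains and variance.** Per-epoch gains come from OLS of observation on
prediction. The default is mean-centred scoring (equivalently, an
intercept): minimum correction of band-pass-filtered epochs leaves an
arbitrary positive offset — the filter undershoot — and forcing the
regression through the origin makes even the true model score poorly. The
origin-constrained variant remains available (`gain_intercept=False`,
and is the default of the low-level `estimate_gain`). Explained variance is
`R² = 1 − SS_res/SS_tot` on pooled sums of squares. The variance partition
across canonical / per-subject / per-epoch response functions applies a
conservative fallback: any subject (epoch) whose specific fit explains less
than the coarser fit is scored with the coarser fit's residual, so the
nested fractions are non-negative and sum to one by construction.

Epoch-level predictions convolve the *whole* preprocessed nerve record with
the fitted impulse response and then slice epochs, so that response tails
from preceding events (decay ~16 s versus ≥30 s event gaps) are carried
into each window; epoch-local convolution would drop that history.

The gain-trend analysis is a deliberate simplification of a mixed-effects
model: OLS of gain on event repetition with fixed per-subject intercepts,
reporting the slope, its SE, t and p. Stimulation-rate classes follow the
reported bands: low < 0.12 Hz, medium up to 0.6 Hz, high above, and ≥ 5 Hz
excluded outright as physiologically implausible burst rates (thresholds
configurable).

`compare_scrf_to_reference` regresses an estimated impulse response onto a
reference one after an optimal integer-sample alignment within ±5 s
(positive shift = estimate lags reference), because conduction delays shift
responses without changing shape; the applied shift is reported.

## Synthetic data

The generator emulates the two study designs with known truth.

*Recording style (exp1):* 7 subjects by default; 20 "aversive" plus 10
"oddball" events per subject, ≥30 s apart (exponentially jittered) so
response tails resolve; a 10 Hz integrated nerve channel (Gaussian bursts,
A = 0.7814, µ = 1.685 s, σ = 0.3051 s, c = 0.1567, the published aversive
estimates) and a 10 Hz conductance channel driven by the same bursts
through the low-rate response function (ϑ = 2.3051, 2.5653, 0.1517,
−0.0058).

*Stimulation style (exp2):* 4-subject-scale designs; near-periodic trains
(≤5% onset jitter) at 0.1/0.2/0.5/1.5 Hz plus an optional ~10 Hz epoch that
the pipeline must exclude; conductance synthesized at 100 Hz and recorded
through a derivative-device emulation.

Shared machinery: per-event gains are log-normal
(`g_mean·exp(N(0, 0.3²))`, keeping their sign) with an optional additive
linear repetition trend; white Gaussian noise at 5% of signal SD by
default (the residual spectrum of real recordings is unknown; noise levels
are calibration knobs, not claims); sinusoidal drift at 0.005 Hz and 10% of
signal SD — below the 0.0159 Hz high-pass, so preprocessing removes it.

**Derivative recorder.** The device is an AC-coupled amplifier: a
first-order high-pass with the 3 s decay time constant cascaded with a
first-order low-pass with the 0.3 s rise constant, applied to the
conductance itself — for signals slower than the decay constant this *is* a
scaled differentiation, which is how such hardware records a "first
derivative". An explicit first-difference variant and an extra high-pass
stage are available as parameters but off by default: differencing an
already AC-coupled signal double-differentiates, and an extra first-order
high-pass at 0.7 Hz would remove nearly all conductance-band energy
(<0.5 Hz), after which the mean-subtract/cumulative-sum reconstruction
could not recover the signal that stimulation-style analyses demonstrably
work with.

**Depletion nonlinearity.** A state `s` starts at 1, multiplies each
event's gain, drops to `s·(1−δ)` at every burst and recovers toward 1 with
τ_rec; defaults δ = 0.3, τ_rec = 20 s make the effect negligible below
0.2 Hz and strong above 1 Hz, reproducing the direction of the observed
model breakdown above ~0.6 Hz. It is a phenomenological stand-in for sweat
gland/terminal depletion, not a biophysical claim.

Everything is a pure function of (config, seed); datasets regenerate
bit-identically and serialize as CSV/YAML with a hash-carrying manifest.

## What passing tests do and do not show

The synthetic world is exactly LTI (plus the explicit depletion switch),
with white noise and stationary gains. Passing recovery tests therefore
validates the estimation machinery, not the LTI hypothesis for real skin;
non-SN sympathetic traffic, correlated noise, electrode drift and recording
artifacts beyond clipping are all absent. Two honest consequences of the
printed preprocessing are documented rather than patched: (i) piecewise 5-s
linear detrending of the integrated nerve signal removes each window's
mean — and with it much of the burst *area* that the response function's
slow pole integrates — which caps recording-style epoch-level explained
variance well below 1 even without noise (the package reaches canonical
fractions of ~0.3–0.5 on clean synthetic data, the same order as reported
for real recordings); and (ii) per-epoch gain estimates under that chain
are noisy, so repetition-trend recovery is verified at the estimator level,
not through the full recording-style chain.

## Problem sizes

Default test and validation runs use scaled designs (1–3 subjects, 3–12
events per condition, 70–140 s stimulation epochs) chosen so the full suite
and the validation script each complete in a few minutes on one core while
keeping every estimator in its asymptotic regime; the generator's
scientific defaults (7/4 subjects, 20+10 events, ≥30 s gaps, published
parameter values) are unchanged by the test configurations.

## Known limitations

- The ODE sign convention makes fitted gains negative for positive SCR;
  users comparing gains across conventions must track the sign.
- Causal single-pass filtering shifts latencies by a constant; µ and ϑ₄
  absorb this, but absolute latency values are dialect-dependent.
- `downsample` is plain decimation; the caller must low-pass filter first
  (the standard chains do).
- No artifact handling beyond clipping detection; no spike sorting; no
  alternative response-function families.
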