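# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `phasecoupling`, in the order data flows through the
package.

## Signal model and preprocessing

An input recording is a uniformly sampled multichannel time series
(`SignalRecord`); channels are assumed to superpose a cardiac mode near
1 Hz and a respiratory mode in 0.1–0.35 Hz plus broadband noise.  The
conditioning chain is:

1. **Moving-average detrend** — subtraction of a centered moving average
   (default window 30 s; the window shrinks at the record edges).  A 30-s
   window leaves content above ≈0.07 Hz essentially untouched, so both
   analysed bands pass unharmed.
2. **z-normalisation** — zero mean, unit variance; constant channels are a
   degenerate-input error.
3. **Zero-phase Butterworth bandpass** — order 2 per pass, applied
   forward–backward (`sosfiltfilt`), i.e. effective order 4 with exactly
   zero group delay.  Default bands: respiratory 0.1–0.6 Hz and cardiac
   0.6–2 Hz.  The respiratory lower edge sits at 0.1 Hz so that paced
   6 breaths/min breathing is inside the band (it is attenuated ≈50% right
   at the edge, which rescales the mode but leaves its phase intact);
   0.07 Hz can be configured when that attenuation matters.
4. **Protophase** — the unwrapped angle of the analytic (Hilbert) signal
   of the narrowband component.
5. **Protophase-to-phase transformation** — the protophase θ depends on
   the observable; the invariant phase is obtained from the empirical
   Fourier coefficients Sₙ = ⟨e^(−inθ)⟩ of the wrapped protophase
   distribution as

   φ(θ) = θ + Σ_{0<|n|≤N} Sₙ/(i n) · (e^{inθ} − 1),   N = 48 by default.

   The map satisfies φ(θ + 2π) = φ(θ) + 2π, so cycle counts are preserved,
   and the transformed wrapped phase is uniformly distributed (the tests
   verify a Kolmogorov–Smirnov distance < 0.02 at 10⁴ samples against a
   θ = φ + 0.5 sin φ distortion).
6. **Edge exclusion** — the first and last 10 s of every extracted phase
   are dropped before inference; filter and Hilbert transients concentrate
   there.

Instantaneous heart rate is 60·φ̇/2π from centered finite differences of
the cardiac phase, optionally smoothed by a short moving average.

## Wavelet analysis

For time–frequency inspection the package implements the continuous
Morlet transform

W(s, t) = (1/s) ∫ ψ((u − t)/s) g(u) du,  ψ(u) = π^(−1/4) e^(−i2πu) e^(−u²/2),

evaluated by FFT correlation on a log-spaced frequency grid (default
0.07–2 Hz, 16 voices per octave; f = 1/s since the wavelet's central
frequency is 1).  Two deliberate conventions: the **1/s normalisation**
(not the more common 1/√s) makes the ridge amplitude of a sinusoid equal
to ≈0.94 × its amplitude independent of frequency, and the coefficient
phase uses the quadrant-aware two-argument arctangent.  Users comparing
against other toolboxes should expect a √s scaling difference.  A cone of
influence marks coefficients closer than s·√2 to an edge as unreliable.
The transform is deliberately implemented directly rather than through a
generic wavelet library, because this normalisation/parameterisation pair
is not what those libraries provide; a direct numerical integration of the
defining integral serves as the test oracle.

## Dynamical Bayesian inference

The phase pair is modelled as

dφᵢ/dt = ωᵢ + qᵢ(φᵢ, φⱼ) + ξᵢ(t),  ⟨ξᵢ(t)ξⱼ(t′)⟩ = Eᵢⱼ δ(t − t′),

with the right-hand side expanded over a Fourier basis: a constant term
plus sin/cos(k₁φ₁ + k₂φ₂) for index pairs in the canonical half-plane
(k₁ > 0, or k₁ = 0 and k₂ > 0), |k₁|,|k₂| ≤ K.  K = 2 (the study's order)
gives 25 terms per oscillator.  Within a window of length 50 s (default):

* phase velocities are forward differences φ̇ₙ = (φₙ₊₁ − φₙ)/h, the basis
  is evaluated at midpoints (φₙ₊₁ + φₙ)/2;
* the noise update E = (h/N) Σₙ rₙrₙᵀ (r the residual) alternates with the
  Gaussian parameter update

  Ξ_post = Ξ_prior + h Σₙ (E⁻¹ ⊗ ΦₙΦₙᵀ),
  r_post = Ξ_prior c_prior + h Σₙ Φₙ(E⁻¹φ̇ₙ)ᵢ − (h/2) Σₙ ∂Φₙ/∂φᵢ,
  c_post = Ξ_post⁻¹ r_post,

  the last sum being the drift correction of the midpoint discretisation;
* iteration stops when the relative change of ‖c‖ drops below 1e-5
  (maximum 100 iterations; non-convergence flags the window estimate
  rather than failing silently).

Between consecutive windows the posterior mean becomes the next prior mean
and the prior covariance is the posterior covariance plus the diagonal
diffusion (p·c_post)² per coefficient, with propagation constant p = 0.2 by
default; p = 0 gives independent windows with the initial weakly
informative prior (zero mean, diagonal variance 100).  With a flat prior
and fixed E, one window reduces exactly to weighted least squares — the
test suite asserts agreement with a closed-form solution at 1e-8.

Windows are non-overlapping; 50 s spans ≥5 respiratory cycles at 0.1 Hz
and gives ≈10 velocity samples per basis term at 50 Hz (the inference
refuses windows shorter than 4 samples per term).

## Coupling measures

* σ (coupling strength) is the Euclidean norm of the coefficients of
  terms through which the partner's phase enters an oscillator's dynamics
  (k_partner ≠ 0).  The square root matters: σ is then a proper norm,
  invariant under re-enumeration of the basis half-plane and under
  rotations of the phase origin (which mix each sin/cos pair).
* D = (c₂ − c₁)/(c₁ + c₂), where cᵢ is the norm of the coupling acting ON
  oscillator i; with the convention oscillator 1 = cardiac, D < 0 means
  respiration drives the cardiac mode.  c₁ = c₂ = 0 leaves the direction
  undefined; it is reported as missing, never as 0.
* |ρ| compares two coupling functions on a uniform M×M grid over [0, 2π)²
  (default M = 100): |⟨q̃₁q̃₂⟩|/(|q̃₁||q̃₂|)×100 with q̃ the deviation from
  the grid mean.  It is scale- and sign-invariant: it measures shape
  (mechanism), not magnitude.

Per-window values aggregate to stages by the half-open interval containing
the window midtime; coupling functions average over windows within a stage
first, then across subjects (mirroring group-averaged figures).

## Surrogates

Cycle phase permutation surrogates cut the unwrapped driver phase at
upward crossings of multiples of 2π, permute the complete cycles as blocks
of phase increments, and re-accumulate.  Intra-cycle dynamics survive;
inter-oscillator timing is destroyed; the total phase gain is conserved
exactly and monotonicity is inherited.  The significance threshold for σ
is the surrogate mean + 2 SD over n = 100 surrogates by default (the
driver phase is permuted; permuting the driven or both is configurable).
The surrogate test only has power when cycle lengths vary — permuting the
near-identical cycles of a noiseless pacemaker reproduces the original
series — which is why the synthetic generator gives respiration a
realistic cycle-to-cycle variability (below).

## Stage statistics

Stage differences of a subjects × stages matrix are tested with the
Friedman chi-square (within-subject average ranks; identical columns short
-circuit to statistic 0, p = 1).  When p < α, pairwise stage differences
are located by a Tukey-style comparison of mean ranks against the
studentized-range critical difference q_{α,k,∞}/√2 · √(k(k+1)/6n)
(Nemenyi-type).  "Tukey after Friedman" is ambiguous as usually stated;
the rank-sum reading implemented here is the closest defensible procedure
for a repeated-measures rank test.  Multiple directed pairs are reported
without cross-pair multiplicity correction (each panel tests its own
hypothesis).

## Synthetic protocol generator

The generator integrates the phase model by Euler–Maruyama at the output
rate (default 50 Hz, ≥10× the fastest natural frequency is enforced) and
composes observables g(t) = A_c cos φ_c + A_r cos φ_r + ε with white
measurement noise ε.  Three channels (BP-like, SAS left/right-like with
cardiac frequencies 1.00/1.04/0.96 Hz) share one respiratory phase; each
cardiac phase is driven through q_c = γ·0.4·sin(φ_Resp + δ) rad/s.
Stage defaults (10 min each):

| stage | breathing | γ (gain) | δ (shift, rad) | (A_c, A_r) |
|-------|-----------|----------|----------------|------------|
| A     | 0.25 Hz   | 1        | 0              | (1, 2)     |
| B     | 0.10 Hz   | 2        | 1.1            | (1, 3)     |
| C     | 0.10 Hz   | 3        | 0.6            | (1, 4)     |
| D     | 0.25 Hz   | 1        | 0              | (1, 2)     |

Dynamical noise: cardiac 0.1, respiratory 0.2 rad/√s; measurement noise
sd 0.1.  Rationale for the non-obvious choices:

* **Respiratory-dominant band amplitudes.**  Order-2 Butterworth skirts
  leak the cardiac mode into the respiration band (≈12% amplitude after
  two passes).  The leak beats against the respiratory mode at φ_Card −
  φ_Resp — a term the inference basis represents exactly — and masquerades
  as cardiac→respiratory coupling.  With the respiratory mode dominating
  its band (as enhanced slow-breathing oscillations do in the signals this
  generator emulates), the artifact stays well below the genuine
  respiration→cardiac coupling and the directionality sign structure is
  recoverable.
* **Respiratory noise 0.2 rad/√s** corresponds to ≈5–10% cycle-length
  variability, typical of human breathing even when paced, and is what
  gives cycle-permutation surrogates their power.
* **Stage-dependent coupling shift δ.**  Gain changes alone rescale the
  coupling function without changing its shape, so similarity against
  baseline would be trivially ≈100% in every stage.  The shift emulates
  the altered respiratory-to-cardiac transfer during paced breathing that
  moves the coupling function along the respiratory axis; with δ_B > δ_C >
  0 the recovery stage is most similar to baseline and resistance
  partially restores the baseline shape, which is the qualitative pattern
  the analysis should detect.
* Phases are continuous across stage boundaries; gains switch stepwise.

What the generator does **not** emulate: waveform morphology (pulses are
pure cosines), amplitude dynamics within a stage, baroreflex-type
feedback (no cardiac→respiratory coupling), non-stationary noise, and
movement artifacts.  Passing tests therefore demonstrate that the
inference machinery recovers known phase-dynamical structure through the
full observation pipeline — not that every property of real recordings is
handled.

## Numerical choices and degenerate inputs

* Interior NaN gaps up to 1 s in recordings are linearly interpolated;
  longer gaps or edge NaNs are format errors.
* Stage intervals are half-open [start, end); a window midtime exactly on
  a boundary belongs to the starting stage.
* The inferred E gets a 1e-12 diagonal jitter to stay invertible on
  noiseless input.
* Surrogate construction pins the final sample to conserve total phase
  gain against floating-point reordering.
* The cycle-permutation surrogate requires ≥3 complete cycles; the
  protophase-to-phase transformation requires ≥10.

## Problem sizes used in the shipped checks

The test suite exercises the full pipeline at reduced scale chosen to keep
estimates stable: unit tests run 60–300 s signals at 20–50 Hz; the
protocol-level checks use the full 40-min default protocol for one subject
and a 20-subject cohort for the stage statistics; surrogate power and
specificity use 20 seeds × 50 surrogates on 300-s pairs.  These sizes are
the package's own verification choices; all are configurable.

## Known limitations

* Inference is pairwise only; networks of >2 oscillators are out of scope,
  as is model selection over K.
* The respiratory band edge at 0.1 Hz attenuates paced breathing by
  half; use the 0.07 Hz option if amplitude (not phase) matters.
* Spurious cross-band leakage (see above) is a property of any
  bandpass-plus-Hilbert pipeline at these band separations; directionality
  estimates from channels with weak respiratory content should be
  interpreted with the surrogate threshold in hand.
* The Friedman/Nemenyi stage comparison treats stages as exchangeable
  repeated measures and ignores serial order.
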