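# phasecoupling

Coupling functions between interacting physiological oscillators, inferred
by windowed **dynamical Bayesian inference** (DBI).

The package targets a specific question in cardiovascular/cerebrospinal
physiology: how does respiration drive the cardiac rhythm visible in blood
pressure (BP) and in the width of the subarachnoid space (SAS, a proxy for
cerebrospinal-fluid pulsatility), and how does this coupling change during
slow paced breathing (6 breaths/min, with and without inspiratory
resistance)?  It is written for researchers analysing multichannel
physiological recordings who want mechanism-level coupling estimates rather
than correlation or coherence.

## The model

Each oscillatory mode is reduced to its instantaneous phase and the pair is
modelled as coupled stochastic phase oscillators

```
dφᵢ/dt = ωᵢ + qᵢ(φᵢ, φⱼ) + ξᵢ(t),      i = 1 (cardiac), 2 (respiratory)
```

with qᵢ expanded in a Fourier basis Φₖ(φ₁, φ₂) up to order K = 2 (25 terms
per oscillator) and ξ white Gaussian noise with covariance E.  Within each
time window (default 50 s) the inference alternates a noise estimate with a
Gaussian posterior update of the stacked coefficient vector, and each
window's posterior is propagated — with diagonal diffusion — as the next
window's prior, so time-varying dynamics can be followed.  From the
inferred coefficients the package derives

* **coupling strength** σ — the Euclidean norm of the coefficients through
  which one phase enters the other's dynamics;
* **directionality index** D = (c₂ − c₁)/(c₁ + c₂) ∈ [−1, 1], negative when
  respiration predominantly drives the cardiac mode;
* **polar similarity** |ρ| ∈ [0, 100] % — the magnitude of the centered
  correlation of two coupling functions over the 2π×2π phase grid, i.e.
  whether two interactions share the same mechanism;
* cycle-phase-permutation **surrogate thresholds** (mean + 2 SD) for
  significance of σ, and Friedman/Nemenyi statistics across protocol
  stages.

Phases are extracted from raw channels by moving-average detrending,
z-normalisation, zero-phase Butterworth bandpass (respiration 0.1–0.6 Hz,
cardiac 0.6–2 Hz), the Hilbert analytic signal, and a protophase-to-phase
transformation; a 1/s-normalised Morlet wavelet transform with logarithmic
frequency resolution is included for time–frequency inspection.

Because raw recordings of this kind are not redistributable, the package
ships a ground-truthed generator (`simulate_protocol`) of the four-stage
protocol — (A) baseline, (B) paced 0.1 Hz breathing, (C) paced breathing
against resistance, (D) recovery, 10 min each — with stage-dependent
respiratory frequency, coupling gain and coupling-function shape.

## Worked example

```python
import numpy as np
from phasecoupling import PhaseCouplingModel, simulate_protocol

rec, protocol, truth = simulate_protocol(seed=1)   # 40-min, 3 channels, 50 Hz
res = PhaseCouplingModel.from_recording(rec, "BP", "BP").fit()
print(res.summary())
print(res.stage_table(protocol).round(3))
```

prints

```
Phase coupling model (dynamical Bayesian inference)
=======================================================
windows: 47 x 50 s   basis order K=2 (25 terms)   propagation=0.2
converged windows: 47/47
-------------------------------------------------------
cardiac frequency  (osc 1):  1.0001 Hz  (sd 0.0032)
respiratory freq.  (osc 2):  0.1724 Hz  (sd 0.0732)
coupling strength sigma (resp->card): median 0.4351  IQR [0.3901, 0.9034]
directionality D: median -0.394  (respiration drives cardiac)
noise intensity (rad/sqrt(s)): osc1 0.0384, osc2 0.0346

   sigma      D
A  0.398 -0.383
B  0.788 -0.366
C  1.168 -0.605
D  0.382 -0.367
```

The negative directionality says respiration drives the cardiac mode in
every stage; the per-stage medians of σ double during paced breathing (B)
and triple with added resistance (C), returning to baseline in recovery (D)
— exactly the gain structure the generator encodes (0.4, 0.8, 1.2,
0.4 rad/s).  `res.coupling_grid()` returns the reconstructed coupling
function q(φ_Card, φ_Resp), a sine along the respiratory axis, and
`res.surrogate_threshold(n_surr=100, seed=0)` gives the significance
threshold for σ.

Cohort-level stage statistics (Friedman test, similarity against baseline)
are assembled by `phasecoupling.cohort_stage_matrices`, and a shell
interface wraps the same pipeline:

```sh
phasecoupling simulate --seed 1 --out rec.csv
phasecoupling run --rec rec.csv --protocol rec.protocol.csv --out results/
phasecoupling report --rec rec.csv --protocol rec.protocol.csv --out report/
```

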