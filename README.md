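# moodquench

Simulation and Lyapunov-based verification of nonlinear treatment control for
a dynamical model of bipolar-II mood disorder.

## The problem

Bipolar-II disorder alternates between hypomanic and depressive episodes: a
*mood swing*. A clinically motivated way to model this is a van der Pol
(Liénard) oscillator for a scalar emotional mood x(t):

```
ẍ − b(a − x²)ẋ + cx = u(t)
```

with patient parameters a, b, c > 0 and treatment input u(t) (medication +
therapy intensity). In state-space form with x₁ = mood and x₂ = mood change
rate:

```
ẋ₁ = x₂
ẋ₂ = −c·x₁ + b·a·x₂ − b·x₁²·x₂ + u
```

Untreated (u ≡ 0), any nonzero initial mood is drawn onto a stable limit
cycle — a sustained, fixed-amplitude mood swing. The control goal is to
*quench* that swing: drive (x₁, x₂) to the origin, ideally without any mood
reversal along the way.

## The controllers

Both controllers use backstepping. Define the virtual control x₂d = −k₁·x₁
and the backstepping variable h = x₂ − x₂d = x₂ + k₁·x₁, so ẋ₁ = −k₁·x₁ + h.
The drift of ẋ₂ is linear in the parameters: ẋ₂ = W·θ + u with regressor
W = (−x₁, x₂, −x₁²·x₂) and θ = (c, b·a, b).

**Exact-model-knowledge (EMK) controller** — θ known:

```
u = −W·θ + k₁²·x₁ − k₁·h − x₁ − k₂·h
```

This cancels the drift exactly, leaving the linear loop ẋ₁ = −k₁·x₁ + h,
ḣ = −k₂·h − x₁. The Lyapunov function V = ½x₁² + ½h² satisfies
V̇ = −k₁x₁² − k₂h² ≤ −βV with β = 2·min(k₁, k₂), so V(t) ≤ V(0)e^(−βt):
exponential quenching.

**Adaptive controller** — θ unknown: the same law with θ replaced by a
running estimate θ̂(t), updated by the gradient rule

```
θ̂̇ = Γ·Wᵀ·h ,   Γ symmetric positive-definite.
```

With V = ½x₁² + ½h² + ½θ̃ᵀΓ⁻¹θ̃ (θ̃ = θ − θ̂), the cross terms cancel and
V̇ = −k₁x₁² − k₂h² again: the mood is quenched and θ̂ settles to a constant.
Without persistent excitation θ̂ is *not* guaranteed to reach the true θ —
the package reports the final estimate and its error rather than asserting
identification.

## Worked example

Built-in presets replicate the published scenarios (a=1, b=2, c=9,
x(0) = (0.5, 0)):

```
$ moodquench presets
figure1-untreated: none controller, model (a=1.0, b=2.0, c=9.0), duration 40.0
figure11-reestimation: adaptive controller, model (a=1.0, b=2.0, c=9.0), duration 40.0
figure2-emk: emk controller, model (a=1.0, b=2.0, c=9.0), duration 10.0
figure5-adaptive: adaptive controller, model (a=1.0, b=2.0, c=9.0), duration 10.0
```

Untreated, the mood swings indefinitely (37 reversals in 40 time units,
steady amplitude ≈ 2.0):

```
$ moodquench untreated --preset figure1-untreated --report
zero crossings of x1 : 37
peak |x1| (final window): 2.00426
mood settled         : False
```

The EMK treatment (K₁ = 1.1, K₂ = 10) quenches the swing with **zero** mood
reversals; by t = 10 the residual mood is ~6e-5 and the treatment effort has
converged to zero:

```
$ moodquench emk --preset figure2-emk --out emk.csv --report
zero crossings of x1 : 0
peak |x1| (final window): 6.34179e-05
mood settled         : True
settling time        : 5.228
```

The adaptive treatment (K₁ = 1.22, K₂ = 10, Γ = 0.1·I) achieves the same
without knowing the patient parameters. Starting the estimates at
(c, b·a, b) = (6, 2.5, 5) (i.e. guesses a=0.5, b=5, c=6):

```
$ moodquench adaptive --preset figure11-reestimation --report
zero crossings of x1 : 0
peak |x1| (final window): 8.00553e-22
mood settled         : True
settling time        : 3.964
final theta_hat      : (6.00048, 2.50254, 4.9999)
estimate drift (TV)  : 0
final theta error    : (2.99952, -0.502541, -2.9999)
```

The estimates settle to constants — close to where they started, far from the
true θ = (9, 2, 2) — yet the mood is still quenched: exactly the boundedness-
without-identification behaviour adaptive theory predicts. Custom scenarios
go in a YAML file (see `moodquench.io_cli` docs) and run via `--config`;
trajectory CSVs carry t, x1, x2, u, the estimates and the Lyapunov value, and
`moodquench report traj.csv` recomputes the diagnostics from a file.

The same functionality is available as a library:

```python
from moodquench import PRESETS, run_scenario, summarize

traj = run_scenario(PRESETS["figure2-emk"])
print(summarize(traj))   # ConvergenceReport(settled=True, zero_crossings=0, ...)
```

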