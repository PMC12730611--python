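# Methods

## Model

The mood oscillator is the van der Pol / Liénard system

    ẋ₁ = x₂
    ẋ₂ = −c·x₁ + b·a·x₂ − b·x₁²·x₂ + u

with a, b, c > 0 and all quantities dimensionless (the literature this model
comes from assigns no units to mood or to time, and neither do we). The
positivity constraint is enforced at construction: every published parameter
set is positive, and the oscillator interpretation (anti-damping inside
|x₁| < √a, damping outside) requires it. The second equation is taken in this
sign convention deliberately — it is the only form that is simultaneously
consistent with the linear-in-parameters factorisation ẋ₂ = W·θ + u,
W = (−x₁, x₂, −x₁²·x₂), θ = (c, b·a, b), and with the sustained limit cycle
the untreated model must exhibit. (The scalar second-order form with
*positive* damping +b(a−x²)ẋ, which sometimes appears in print, decays near
the origin and cannot swing.)

The unforced equilibrium is the origin and is unique: ẋ₁ = 0 forces x₂ = 0,
then ẋ₂ = −c·x₁ = 0 forces x₁ = 0.

States are assumed directly measurable; no observer is modelled.

## Controllers

Backstepping with virtual control x₂d = −k₁x₁ and h = x₂ + k₁x₁. Carefully
differentiating x₂d along ẋ₁ = −k₁x₁ + h gives

    ḣ = W·θ + u − k₁²·x₁ + k₁·h,

so the drift-cancelling law is

    u = −W·θ + k₁²·x₁ − k₁·h − x₁ − k₂·h        (EMK)
    u = −W·θ̂ + k₁²·x₁ − k₁·h − x₁ − k₂·h        (adaptive)

yielding exactly ḣ = −k₂h − x₁ (EMK) and ḣ = −k₂h − x₁ + W·θ̃ (adaptive,
θ̃ = θ − θ̂). A variant with the k₁² and k₁ terms sign-flipped is retained
behind `as_printed=True`; it does not achieve the exact cancellation but its
linear (x₁, h) loop is still Hurwitz at the default gains (checked by
eigenvalue computation in the tests), so it is kept purely for comparison
runs.

The update rule θ̂̇ = Γ·Wᵀ·h is the gradient law paired with the +W·θ̃
residual sign; with V = ½x₁² + ½h² + ½θ̃ᵀΓ⁻¹θ̃ the cross terms cancel exactly
and V̇ = −k₁x₁² − k₂h². Γ may be any symmetric positive-definite 3×3 matrix
(validated by eigenvalue check at construction); the scenario presets use
0.1·I. Important consequence, verified numerically rather than assumed:
θ̃ = 0 is *not* invariant — the update moves θ̂ whenever h ≠ 0 — so an
adaptive run seeded at the true θ coincides with the EMK run only in the
limit of negligible adaptation gain (the equivalence test uses Γ = 10⁻¹²·I;
at Γ = 0.1·I the trajectories differ by ~10⁻⁴).

## Integration

Default integrator: fixed-step classical RK4, step 10⁻³, with the feedback
law evaluated inside every derivative stage (continuous-time control, no
zero-order hold). Default horizons: 40 time units for untreated runs (several
limit-cycle periods) and 10 for controlled runs (transients die within ~5).
These are the package's defaults, all overridable per scenario. RK4 was
chosen for determinism and trivial reproducibility: identical configurations
give bit-identical trajectories, and the observed convergence order on the
untreated run is ≥ 3.5 (tested). A SciPy RK45 adaptive stepper
(`method: adaptive-stepper`, rtol 10⁻¹⁰) is available as a cross-check.

Runs abort with an `IntegrationError` naming the blow-up time if any state
component exceeds 10⁶. The closed-loop and untreated dynamics from moderate
initial states never approach this; the guard exists for pathological
configurations (e.g. fixed-step instability from extreme initial states,
where the effective damping −b·x₁² makes the system stiff).

## Diagnostics

* **Exponential envelope**: V(t) ≤ V(0)·e^(−βt)·(1+slack) with β =
  2·min(k₁, k₂). β is the sharp constant implied by
  V̇ = −k₁x₁² − k₂h² ≤ −2·min(k₁,k₂)·V; the underlying theory asserts only
  that *some* positive rate exists.
* **Monotonicity**: along controlled runs V may not increase by more than
  10⁻⁹ per step at the default step (pure floating-point/discretisation
  allowance; the continuous V̇ is strictly ≤ 0).
* **Zero crossings** (mood reversals): strict sign changes between
  consecutive samples; a sample that merely touches zero is not a reversal.
* **Steady-state window**: metrics such as peak amplitude and estimate drift
  are computed over the final 25% of the horizon by default.
* **Estimate settling**: defined by total variation of each θ̂ component over
  the final window (< 10⁻⁴ by default), since "converges to a constant" names
  no criterion by itself. Closeness of θ̂(∞) to the true θ is reported, never
  asserted — the gradient law guarantees boundedness and settling, not
  identification, absent persistent excitation (which these quenching
  trajectories, decaying to zero, do not provide; accordingly the estimates
  in the presets settle near their initial guesses).

## Scenario presets

All preset numbers are the published scenario settings: patient parameters
a=1, b=2, c=9; initial state (0.5, 0); EMK gains K₁=1.1, K₂=10; adaptive
gains K₁=1.22, K₂=10 with Γ=0.1·I; estimate initialisation (6, 2.5, 5),
i.e. parameter guesses a=0.5, b=5, c=6 packed as (c, b·a, b). The estimate
initialisation for the shorter adaptive preset is not separately published;
both adaptive presets therefore share the published re-initialisation
triple, the re-estimation preset differing only in its longer horizon (40)
for steady-state estimate reporting.

## Numerical choices and limitations

* The EMK oracle used in tests is the eigendecomposition (matrix-exponential)
  solution of the linear (x₁, h) loop — exact because the EMK cancellation is
  exact; agreement at 10⁻⁶ over the full run validates both the law and the
  integrator together.
* The harmonic-limit oracle sets b = 10⁻⁶ (or 10⁻⁹ for the energy check), for
  which the model is a conservative oscillator with ω = √c and closed-form
  solution 0.5·cos(3t) from the preset initial state.
* CSV trajectories round-trip exactly (pandas `float_precision="round_trip"`
  on read).
* This is a deterministic, noise-free model of endogenous mood dynamics: no
  stochastic perturbations, no reactive (event-driven) mood component, no
  input saturation or dosage mapping for u, no state observer, and no claim
  that the dimensionless time axis corresponds to clinical episode durations.
  Passing tests certify the mathematics and the implementation, not clinical
  validity.
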