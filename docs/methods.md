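# Methods

This note records the models implemented in `ionscale`, the numerical
choices behind them, and what the synthetic experiments do and do not
demonstrate. Units everywhere: length in ångström (Å), time in picoseconds
(ps), mass in dalton (Da); no unit-conversion layer exists.

## The coarse-grained ion model

The central object is the linear SDE system per spatial component

    dX = V dt,  dV = U dt,  dU = (−η₁V + Z) dt,
    dZ = −(η₂Z + η₃U) dt + η₄ dW,

with strictly positive parameters η₁ [ps⁻²], η₂ [ps⁻¹], η₃ [ps⁻²],
η₄ [Å ps⁻⁷ᐟ²]. The (V, U, Z) block is a stable linear system whose drift
matrix has characteristic polynomial λ³ + η₂λ² + (η₁+η₃)λ + η₁η₂; all
eigenvalue real parts lie in (−η₂, 0). Its stationary law is a centred
Gaussian with diagonal covariance
(η₄², η₁η₄², η₁η₃η₄²)/(2η₁η₂η₃), and the position integrates V, giving
long-time diffusion with D = η₄²/(2η₁²η₂²).

Parametrization and its inverse are closed-form moment maps
(`params.fit_cg_params`, `params.implied_stats`); they are exact mutual
inverses, which the test suite asserts to 10⁻¹² relative on random inputs.
The four bundled ions store the published statistics and parameters exactly
as printed (four significant figures). Because the published parameters were
computed from unrounded averages, refitting from the rounded statistics
reproduces them only to ≈0.3% relative; comparisons against printed values
therefore use 0.5% tolerance throughout.

## Integrators

* `cg.cg_step` / `cg.simulate_cg` and `fictitious.simulate_fp` use explicit
  Euler–Maruyama with all right-hand sides evaluated at the pre-step state.
  Noise is pre-generated in a single block, shape (n_steps, 3) for the CG
  model and (n_steps, N, 3) for the N-particle model, so paths are
  bit-reproducible from a seed and the N=1 fictitious model consumes the
  identical stream as the CG simulator — the basis of the path-wise
  equivalence test.
* Euler–Maruyama carries an O(λ·dt) stationary-moment bias. At the
  fine-scale timestep dt = 10⁻³ ps the stiffest bundled relaxation rate
  (|λ₁| ≈ 127–163 ps⁻¹) makes that bias ≈6–8% on second moments — a property
  of the discretization, not a bug. Convergence of simulated moments to the
  analytic stationary values is therefore asserted at dt = 10⁻⁴ ps, where
  the bias is below 1%.
* The surrogate fine-scale generator (`surrogate.generate_surrogate`)
  instead samples the model's **exact** Gaussian transition law on the
  dt-grid: A = exp(B·dt) and the step covariance from Van Loan's
  augmented-exponential identity (`linear.discretize_lti`), with a
  stationary initial draw. A surrogate trajectory thus has the prescribed
  stationary moments at any sampling interval, which is the property the
  stand-in must emulate. An `method="euler"` option exposes the plain
  discretization for comparison, and `zero_noise=True` is a validation mode
  that produces the identically zero trajectory.

## Estimators

* 〈V²〉 and 〈U²〉 are time-and-component averages with a configurable burn-in
  fraction (default 10%; the averaging interval of the source data is not
  specified more precisely, so the discard is a parameter rather than a
  constant).
* 〈Z²〉 uses the finite-difference identity
  Z ≈ (U(t+Δt) − U(t))/Δt + η₁V(t). Its infinite-data limit at Δt = 10⁻³ ps
  sits ≈5% below the model value (computable in closed form as a quadratic
  form in the exact one-step transition matrices; the consistency test does
  exactly that). The published auxiliary moments were produced by the same
  estimator at the same Δt, so the convention matches.
* D comes from the least-squares slope of the time-origin-averaged,
  component-averaged mean square displacement over a fit window, default
  [1, 5] ps — past the ≈0.1 ps velocity relaxation but early enough to keep
  sampling error moderate. The estimator is unbiased (verified by Monte
  Carlo on exact Brownian paths); its per-trajectory standard deviation is
  ≈5% for a 1 ns trajectory with the default window. Standard errors in the
  recovery report come from block averaging (10 blocks of ~100 ps, long
  against the <0.1 ps correlation times).
* The jerk map bins per-step acceleration differences (U(t+Δt) − U(t))/Δt by
  the current (V, U), default 40×40 uniform bins spanning ±4 sample standard
  deviations (bin widths are a free choice; nothing in the source constrains
  them). Unoccupied cells are NaN and excluded. J₁ is the slice through the
  u-bin containing zero; J₂ the occupancy-weighted row average. For the CG
  model the conditional mean jerk is exactly −η₁v, independent of u; the
  acceptance test asserts slope within 5%, near-zero intercept and R² > 0.99
  on a 10⁶-step simulated trajectory.

## Linear analysis

The ten second moments (X², XV, XU, XZ, V², UV, VZ, U², UZ, Z²) close under
the dynamics into a linear ODE system with constant forcing η₄² on Z².
Because the system is linear, it is propagated **exactly** through the
matrix exponential of the homogenized (augmented) system rather than with an
adaptive ODE solver — there is no integration tolerance to choose and no
stiffness concern (the rates span 10¹–10² ps⁻¹). The reduced four-moment
variant freezes 〈V²〉 at its stationary value, decoupling the position cross
moments.

The MSD time shift t\* is defined through 〈X²〉(t) → 2D(t − t\*): the package
evaluates t − 〈X²〉(t)/(2D) at t = 1 ps and asserts agreement with the value
at 0.5 ps to 10⁻⁴ ps (transients decay at ≥12 ps⁻¹, so 1 ps is converged to
machine level; the source defines the shift only graphically). The full
system started from rest gives a positive shift, the reduced system a
negative one, for all four ions.

The VACF is C(t) = e₁ᵀ exp(Bt) (〈V²〉,0,0)ᵀ, evaluated through the
eigen-expansion (vectorized over the grid) with a matrix-exponential
reference retained in tests; C(0) = 〈V²〉 and ∫₀^∞ C dt = D (Green–Kubo) are
asserted exactly and to 10⁻⁶ respectively.

## Multiscale geometry and hybrid stepping

The domain decomposition is five nested sup-norm boxes parametrized by the
inner side L, the attenuation parameter ω and shell widths h₁, h₂ (defaults
L/20, L/10; reference configuration L = 24.83 Å, ω = 10). Inner boxes are
closed — a boundary point belongs to the inner region. The fine-scale
feedback force attenuation is implemented purely as geometry: interaction
distances are inflated by ω·dist(X, Ω₁) (Euclidean distance to the closed
box) and flagged as beyond-cutoff once the inflation reaches L/2; evaluating
physical forces on water molecules is out of scope.

Hybrid stepping uses hysteresis: the CG model owns Ω₂–Ω₄ and hands over to
BD on entering Ω₅; BD owns Ω₄–Ω₅ and hands back on entering Ω₃; the overlap
keeps the current description, preventing switch chatter. Switches are
detected on the post-step position with no interpolation to the crossing
time — the BD step length √(2DΔT) ≈ 0.43 Å is small against the shell
widths. On re-entry the unobserved (V, U, Z) block is re-initialized to zero
(default) or drawn from the stationary law (`init_policy="stationary"`).
The BD clock advances by ΔT = 0.5 ps, the CG clock by dt = 10⁻³ ps; in the
fixed-horizon half-space experiment a BD step is truncated to the remaining
time when a switch has left the particle off the ΔT grid.

Two validation experiments:

* **Half-space test.** Equal halves released at (±h, 0, 0) (CG side with
  zero auxiliaries, BD side), evolved to 10³ ps, histogrammed in 2 Å bins
  against the exact two-source Gaussian. Only the first coordinate is
  simulated — the CG components are independent and the planar switching
  rule reads x₁ alone, so the x₁ marginal is exact. The analytic density is
  normalized to integrate to the particle count (n/2 per release point);
  note the reference figure's curve is counts-per-2 Å-bin, i.e. this density
  times the bin width. The acceptance test requires ≥95% of occupied bins
  inside 3σ Poisson bands at 10⁴ particles; a small excess in the single
  overlap bin is expected and tolerated by that margin.
* **Escape-time experiment.** A single ion starts at the origin with a
  stationary draw and runs through the five-region scheme until its distance
  from the origin reaches each radius of a grid (default 40 radii up to
  4L ≈ 99.3 Å); T(r) is recorded at the end of the crossing step. The mean
  over 100 realizations is compared with the Brownian first-passage law
  ⟨T⟩ = r²/(6D), sd = r²/(3√10·D), using the 95% interval for a 100-sample
  mean (the interval is reconstructed from these mean/sd expressions). The
  fine-scale stand-in shares the CG dynamics — the integrator supports only
  that surrogate configuration, since a per-step plug-in for an external
  engine would force the event loop out of compiled code; fine↔CG handovers
  keep the full state, so the scheme's switching logic is still exercised at
  every shell.

Pure-BD first passage (`bd_first_passage_times`) is kept as an independent
oracle for the analytic law.

## Fictitious-particle hierarchy

N auxiliary particles with harmonic coupling, damping and independent noise
give, after the variable change Ũⱼ = αⱼ₁(X̃ⱼ−X), Z̃ⱼ = αⱼ₁Ṽⱼ, a
(2N+1)-dimensional stable linear system per component; N=1 reproduces the CG
model exactly under η = (α₁, α₂, α₃, α₁α₄). Stationary covariances solve the
continuous Lyapunov equation; the model's 〈U²〉 is the stationary second
moment of dV/dt = ΣⱼŨⱼ, i.e. the full Ũ-block covariance sum (the natural
multi-particle generalization; the single-particle case reduces to the usual
diagonal entry). The Green–Kubo diffusion constant has the closed form
−e₁ᵀB̃⁻¹Se₁, cross-checked against quadrature of the analytic VACF.

`fit_vacf` is a constrained acceptance–rejection search: all 4N coefficients
are perturbed log-normally (σ = 0.05, halved after 50 consecutive
rejections, floor 10⁻³), each proposal is projected back onto the
(D, 〈V²〉, 〈U²〉) constraint manifold, and a proposal is accepted only if the
trapezoidal L1 distance to the target VACF (on the target's own grid)
decreases — so the error trace is non-increasing and every accepted iterate
satisfies the constraints to the projection tolerance (10⁻¹⁰ in practice).
The projection solves for three joint scale factors with smooth action on
the moments: a global time dilation (α₁, α₃ ~ τ⁻², α₂ ~ τ⁻¹, α₄ ~ τ⁻¹ᐟ², under
which D scales as τ with 〈V²〉 fixed), a joint noise amplitude (all moments
~ c²) and a joint restoring-force factor; at N=1 the log-space Jacobian is
constant with determinant −4, and for N>1 a Newton root-solve converges in a
few Lyapunov evaluations. The default initializer embeds a CG model matched
to the constraints (choosing the free auxiliary moment as z₂ = 3〈U²〉²/〈V²〉,
a stable mid-range regime) plus N−1 weakly coupled particles with spread
frequencies. The perturbation kernel, step sizes and initial guess are
design choices of this package; only the accept/reject structure and the
constraint set are prescribed.

## What the synthetic experiments show — and what they do not

The surrogate generator produces trajectories of the CG (or
fictitious-particle) model itself, with exact stationary statistics. Tests
built on it demonstrate that the estimators and the parametrization chain
are consistent — that the pipeline recovers the generating model from data
of realistic length (10⁶ steps ≈ 1 ns) within its sampling error — and that
the multiscale machinery preserves diffusive statistics through model
switches. They cannot demonstrate that the CG model describes real water:
features of genuine fine-scale data that the surrogate lacks include
non-Gaussian force statistics, state-dependent (hydration-shell) memory, and
any u-dependence of the mean jerk. Reproducing the published *measured*
statistics (the moment tables, the empirical VACF curves) requires an actual
all-atom engine and is deliberately outside this package.

## Numerical edge cases

* Degenerate drift spectra (repeated eigenvalues within 10⁻⁶ relative of the
  spectral span) are rejected with a dedicated error — the eigen-expansion
  analysis assumes distinct modes; numerically defective matrices split
  their double roots at the ~10⁻⁸ level, safely below the threshold.
* Non-finite states raise a blow-up error carrying the first bad step index.
* Trajectory files round-trip bit-exactly (17-significant-digit text,
  round-trip float parsing on read).
* Simulation problem sizes in the test suite (10⁵–10⁶ steps, 10⁴ half-space
  particles, 100 escape realizations, ≤1500 fit iterations) are chosen so
  each stochastic assertion sits at ≥3σ separation from its failure
  threshold while the whole suite stays a few minutes on one core.
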