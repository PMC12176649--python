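# Methods

## Geometry and reduction to scalar equations

The tube is an axisymmetric cylinder of radius `R(t)` with fixed length
(the channel clamps the tissue axially).  Every tensor in the model —
nematic order `q_ij`, orientation `n_ij`, shear `v_ij`, tensions — is then
diagonal in the (circumferential θ, longitudinal z) basis, and we store
mixed components: `q = q_θ^θ = -q_z^z`, `n_θ^θ = 1/2 + q`,
`n_z^z = 1/2 - q`, `v_θ^θ = Ṙ/R`, `v_z^z = 0`.  On this irrotational
geometry the co-rotational derivative of a diagonal mixed tensor is the
plain time derivative, so no covariant machinery is needed.  The price of
the fixed-length assumption is that the longitudinal residual tension obeys
`d(t_r,z)/dt = -t_r,z/τ` and stays at zero for all time; it is carried in
the state anyway so that model variants with axial kinematics can reuse the
integrator.

## Closed ODE system

The five equations (nematodynamics, fibre strain, two Maxwell components,
Laplace closure) are reduced to an explicit system by differentiating
Laplace's law `ΔP R = (ζ₀ + K_a s)(1/2 + q) + t_r,θ` in time and solving
for the expansion rate:

    (Ṙ/R) · [K_a (1/2+q)² + μ/τ − ΔP·R] = t_r,θ/τ − (ζ₀ + K_a s) q̇ + ΔṖ·R

The bracket is the short-time elastic capacity margin.  When it reaches
zero no elastic response can balance the load and the tube runs away in
finite time; the integrator detects this with a terminal event (margin
below 1% of the load) and either raises `LaplaceInstabilityError` or
returns the truncated trajectory, as requested.  States are integrated in
`ln R` for conditioning, together with the slaved cell observables `Q` and
`ln a`, giving a 7-state system solved with LSODA at relative tolerance
1e-8 (1e-6 inside fitting loops) and per-state absolute tolerances.  The
Laplace identity is verified at every output time to 1e-6 relative; a
separate test cross-checks the integrator against an independent
fixed-step scheme that re-solves the algebraic Laplace balance by root
finding at every step.

Pressure steps are linear ramps of 1/60 h by default (the reservoirs are
refilled in under a minute); a zero ramp duration instead applies the
instantaneous elastic balance, solved by bracketed root finding in
`x = ln(R₁/R)` with the nematic order frozen and the Maxwell element acting
as a spring of modulus `K = μ/τ`.  Area is reported normalized to its value
at the first output time, the reference the experimental normalization
uses.

## Default parameters

| parameter | value | units | origin |
|---|---|---|---|
| γ | 1.3 | h⁻¹ | fitted value of the nematic relaxation rate |
| q₀ | 0.25 | – | see below |
| β | 15 | (N/m)⁻¹ h⁻¹ | calibrated, see below |
| ζ₀ | closed | N/m | `ΔP₀R₀/(1/2−q₀)` = 0.0375 at 150 Pa |
| K_a | 0.22 | N/m | fitted 2-D fibre modulus |
| K = μ/τ | 0.29 | N/m | fitted short-time Maxwell modulus |
| τ | 1.0 | h | calibrated, see below |
| k_d | 0.27 | d⁻¹ | measured division rate |
| λ | 4/3 | h⁻¹ | elongation relaxation (1/λ = 45 min) |
| α | 0.7 | – | slope of the Q–q correlation |
| R₀ | 62.5 | μm | reference radius (125 μm reference diameter) |
| h | 3.6 | μm | monolayer thickness |

Two constants are not published and had to be chosen once.

**q₀ = 0.25.**  The Landau term restores the order magnitude at rate
`2γq₀²`; at γ = 1.3 h⁻¹ this is a 6 h timescale for q₀ = 0.25 but a 38 h
timescale for q₀ = 0.1.  Only with q₀ near 0.25 does the model saturate
(|q| back within [0.8, 1.05]·q₀, residual tension below 5% of ζ₀, creep
rate below 10⁻³ h⁻¹ by 56 h) inside the experimental window — and 0.25
matches the measured late-time order.  A parameter scan over (τ, β)
confirmed no combination rescues q₀ = 0.1.

**τ = 1 h, β = 15 (N/m)⁻¹h⁻¹.**  τ sets how long the residual tension
(and hence the reorientation drive β·t̃_r) persists; β sets its strength.
The pair is calibrated so that under the 650 Pa step q crosses zero around
1 h — the observed ~1 h reorientation timescale — while the peak order
stays well below the hard bound 1/2 and the 56 h state satisfies the
saturation conditions above.  In reduced form β̂ = βζ₀/γ ≈ 0.43.

With these defaults the two diagnostic model variants behave as the full
model comparison requires, with one caveat: removing the fibre elasticity
(K_a = 0) or the nematic coupling (β = 0) leaves a tube whose only
long-time resistance is viscous, so both variants reach the elastic
capacity margin and run away *before* the 56 h horizon (around 17 h and
5 h respectively).  The "no plateau" property is therefore asserted at the
last integrable time, where the expansion rate exceeds any plateau
threshold by construction.  This is the model's genuine behaviour at the
calibrated constants, not a numerical artefact.

## Order parameters and angle statistics

Orientation angles are degrees from the tube axis, folded into (−90, 90]
by the nematic symmetry θ ≡ θ + 180°.  The scalar order is
`q = −⟨cos 2θ⟩/2` (optionally weighted), so only even circular moments
matter and the fold is harmless.  Cell elongation from junction stainings
carries the calibration factor α_Q = 0.8; bright-field input overestimates
the junction-based order about twofold and is halved first; nucleus input
has no factor.  The affine-advection null model maps each angle by
`θ' = atan2(λ_θ sin θ, cos θ)` — what fibres would do if they merely
followed the tissue stretch; its order is provably non-decreasing in λ_θ,
and the gap between it and the dynamical q is the evidence for active
reorientation.  Histograms use 4° bins by default (the granularity of
typical orientation-field output; the choice only affects display and
goodness-of-fit binning).

## Gent shell stiffness

The instantaneous monolayer elasticity is modelled as an incompressible
Gent membrane inflated at fixed length: stretches (λ, 1, 1/λ), first
invariant `I₁ = λ² + 1 + λ⁻²`, hoop Cauchy stress
`σ = (E/3) J_m (λ² − λ⁻²)/(J_m − (I₁ − 3))`, membrane tension `t = σh/λ`.
Small strains give `t = (4/3)Ehε`; strains diverge as `I₁ − 3 → J_m`,
reproducing the ~20% threshold.  Forward ramps solve
`ΔP = t(λ)/(λD₀/2) + c_gel(λ−1)` on the rising branch by bracketed root
finding (the optional linear gel term is off by default — the hydrogel's
contribution is negligible at the working collagen density).  Note the
pressure–strain curve is slightly *concave* at small strain (the Laplace
denominator grows with λ) before the Gent stiffening dominates; tests
assert convexity only in the stiffening regime.  Linear inference takes
`S = d(ΔP·R)/dε` over strains below 0.2 and reports E under three
thin-shell conventions (plane-strain `3S/4h`, simple `S/h`, plate
`S(1−ν²)/h`), which span 27–36 kPa for S = 0.13 N/m — the convention
ambiguity is reported rather than resolved.  The (E, J_m) fit is nonlinear
least squares on predicted diameters in log-parameter space; a J_m estimate
at its bound flags effectively linear data.

## Synthetic data

`generate_observations` runs the forward model and emulates the
measurement process: six replicate radius series at 0.5 h sampling with
independent Gaussian relative noise (SD 0.02), mean-cell-area replicates at
{0, 7, 24, 56} h (SD 0.05), and 500-angle orientation samples per structure
and time drawn from von Mises distributions of the doubled angle whose
concentration solves `I₁(κ)/I₀(κ) = 2|q|` (axis swapped for negative
order).  Junction samples target `Q(t)/α_Q` so the calibrated estimator
recovers the model's cell elongation; order-parameter "noise" is therefore
genuine finite-sample error (~0.016 at n = 500), matching the nominal SD
0.02 used as the fitting weight.  EdU counts are binomial with labelling
probability `1 − exp(−k_d T)` over an 8 h pulse.  Every generator is a pure
function of (inputs, seed).

What the generator does **not** emulate: within-channel correlation of
replicates, spatial heterogeneity along the tube, segmentation errors, or
drift in the pressure head.  Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
structured experimental error.

## Fitting and uncertainty

`TubeModel` assembles weighted residuals (replicate-mean radius series, the
four order, elongation and area points) with per-observable σ from the
noise specification (replicate means weighted by 1/√n).  Parameters are
fitted in log space (q₀ additionally bounded below 0.5); ζ₀ is always
re-closed from q₀, never free.  Optimization is multi-start: the
configured number of log-uniform starts within ×/÷10 of the initial point
are screened by objective value and the best few are polished with a
trust-region least-squares solver; the returned objective never exceeds
that of any start.  Integration failures inside the objective (instability,
stalled solver) return a large constant residual.  Uncertainty comes from a
residual-resampling bootstrap: replicate deviations from the fitted curves
are resampled with replacement per observable (whole replicates where
replicated data exist) and the model refitted from the optimum; the SD of
bootstrap estimates is the standard error.

Identifiability at the study's observation design is uneven, as expected:
the elastic moduli K_a and K are pinned by the jump amplitude and creep
curvature of the dense radius series and recover to a few percent; k_d is
pinned by the area decay; γ, β and especially λ ride on a handful of order
parameter points and are weakly identified (λ's influence on Q at t ≥ 7 h
is below the noise floor, mirroring the ±100% uncertainties of the original
estimates).  The recovery experiment (`recovery_experiment`) quantifies
this: it generates-and-refits many datasets and tabulates bias, RMSE and
bootstrap coverage per parameter.

## Problem sizes

The shipped acceptance run uses 10 recovery trials × 32 starts (≈40 s on
one CPU); the test suite runs the same recovery once plus property suites
(~2 min).  These sizes were chosen to make the medians stable across seeds
while keeping a full from-scratch rerun comfortable on a laptop.

## Known limitations

* The cylinder reduction is exact only for the axisymmetric, fixed-length
  tube; no off-diagonal or bending terms are implemented.
* The runaway of the K_a = 0 / β = 0 variants beyond the capacity margin is
  reported as an instability rather than integrated through (the thin-shell
  model itself stops being meaningful there).
* Division-rate feedback on elongation, apoptosis, tension-dependent
  proliferation and the hydrogel's viscoplasticity are not modelled.
* The EdU conversion assumes Poissonian divisions
  (`k_d = −ln(1−f)/T`); a linear convention is available in
  `edu_to_rate` for comparison.
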