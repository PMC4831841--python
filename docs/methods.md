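# Methods

## Model

The material is a fully saturated porous hyperelastic solid with an
interstitial fluid and one dissolved neutral species, at constant temperature
310 K.  Three conservation laws are solved in the Lagrangian frame on the
reference configuration:

* **momentum** ∇·(F S) = 0, with the effective-stress split
  S = Sᵉᶠᶠ − J H pf (H = F⁻¹F⁻ᵀ = C⁻¹);
* **fluid** ∇·j̃ᶠʳ + J H : Ė − 3ϑ²ϑ̇ = 0 — incompressible constituents admit
  no pressure storage; the growth term 3ϑ²ϑ̇ is the volumetric mass source;
* **species** ∇·j̃ᶜʳ + J H : Ė c − 3ρ̄ˢϑ²ϑ̇ c + J n ċ = 0, with the Eulerian
  porosity n = 1 − J⁻¹[(1−n₀) + ρ̄ˢ(ϑ³−1)].

Fluxes follow coupled Darcy/Fick (Onsager) relations
j̃ᶠʳ = −L̃ᶠᶠ∇μ̃f − L̃ᶠᶜ∇μ̃c, j̃ᶜʳ = −L̃ᶜᶠ∇μ̃f − L̃ᶜᶜ∇μ̃c with
L̃ᶠᶠ = J H kᶠᶠ and L̃ᶠᶜ = L̃ᶜᶠ = J H kᶠᶠ bᶠᶜ c (a single stored coefficient
enforces reciprocity).  The diffusive species mobility is taken as
**L̃ᶜᶜ = J H (c dᶜᶜ/(R̄θ) + c² kᶠᶠ (bᶠᶜ)²)**, so that the diffusive part of
the species flux reduces exactly to Fick's law jᶜ = −dᶜᶜ∇c (since
∇μ̃c = R̄θ ∇c/c).  This scaling is a deliberate design choice: it makes the
Péclet-like number β = kᶠᶠbᶠᶜ/dᶜᶜ the genuine convective-to-diffusive flux
ratio, which is what separates the two diffusivity benchmarks (β differs by
100× and the convective term is O(1) vs O(10⁻²) relative to diffusion).
With the alternative scaling c·R̄θ·dᶜᶜ the species field is quasi-steady and
*independent* of dᶜᶜ — the two benchmark cases would coincide identically,
which contradicts their qualitatively different published outcomes.

Two growth cases are supported through the normalized solid growth density
ρ̄ˢ: solid-only growth (ρ̄ˢ = 1, porosity drops as mass is added) and
solid/fluid growth (ρ̄ˢ = 1−n₀, added material carries the reference
porosity).  True constituent densities never appear in the discrete
equations; only ρ̄ˢ and density-specific sources do.

## Parameters

| parameter | value | units | meaning |
|---|---|---|---|
| C₁₀, D₁ | 1e6, 5.5e-9 | Pa, 1/Pa | Neo-Hookean set; μ=2C₁₀=2 MPa, κ=2/D₁≈364 MPa (near-incompressible skeleton) |
| kᶠᶠ | 2e-14 | m⁴/(N·s) | hydraulic permeability |
| bᶠᶜ=bᶜᶠ | 6e-4 | – | convection coupling (hindrance of species drag) |
| dᶜᶜ | 4.55e-14 / 4.55e-12 | m²/s | species diffusivity (two benchmark values) |
| n₀ | 0.5 | – | reference porosity |
| γᶜ_mat, φᶜ | 0.5, 0 | – | activity and osmotic coefficients (no osmosis in the benchmarks) |
| ϑmax, ϑmin | 1.2, 0.8 | – | growth limiter bounds |
| τ±, γ± | law-specific | per driver unit | limiter relaxation scale and exponents |

Potential datums: p⁰ₒ = 0 and μ⁰c = −R̄θ ln(γᶜ c_floor) with c_floor one
tenth of the smallest boundary-equilibrium concentration.  Datums shift the
potentials uniformly and cancel in gradients and boundary relations; a test
verifies that results are datum-invariant, so the choice is immaterial.

## Discretization and solver

Linear axisymmetric triangles, single centroid Gauss point, volume weight
2π R_g A.  The annulus is meshed as a strip one quad thick in Z (height
0.025 mm; plane-strain constraints make all fields Z-independent, verified
by test).  Primary fields are nodal and continuous; pore pressure and
concentration are recovered in closed form from the interpolated potentials
at each Gauss point, so the secondary residual is identically zero by
construction (it is still monitored).

Rates (Ė, ċ, ϑ̇) use first-order backward differences over the step.  Each
time step is a Newton iteration from the previous converged state: the first
iteration is exactly the linearized incremental (forward-Euler) predictor,
subsequent iterations are backward-Euler corrections.  Every global iteration
first runs a per-element local Newton (safeguarded by bisection, |R| < 1e-12,
≤ 50 iterations) for the backward-Euler growth stretch at fixed **F**; for
the stress law the driver tr(Mᵉᶠᶠ'ᵉ) = 3λ ln Jᵉ − 3μ + μ trC/ϑ² and its
ϑ-sensitivity are evaluated analytically.  The element tangent is the
analytic consistent linearization assembled column-by-column as directional
derivatives (geometric stiffness, growth pullback, transport state
dependence, and the ∂ϑ/∂(C, c) coupling through the converged local update);
it matches finite differences of the residual to ~1e-7.

Numerical choices:

* tolerances tol_r = 1e-8 (per-field relative residual), tol_p = 1e-10
  (increment), ≤ 25 global iterations;
* direct sparse LU with symmetric diagonal equilibration (dof units differ
  by many orders of magnitude);
* the Newton increment of μ̃c is capped at two e-folds of concentration per
  iteration and the whole increment is halved until kinematically admissible
  (the exponential potential→concentration map otherwise overshoots on the
  first iteration of a freshly loaded step);
* the internal pressure acts both as a follower traction on the current
  inner radius (load stiffness omitted — displacements are small and
  convergence is unaffected) and as the fluid-potential Dirichlet value at
  the inner face; the outer face is traction-free and drained (pf = 0);
* species boundary values come from bath equilibrium through the partition
  coefficient (c_mat = c_bath/0.5 → 0.0128 and 1.28e-3 mol/m³); the interior
  starts at the outer value;
* loading is ramped in 5 equal pressure increments; the rigid benchmark uses
  10 consolidation steps before growth (consolidation there is instantaneous,
  steady state is asserted);
* clipping of ϑ at the limiter bounds uses a 1e-12 inset to avoid a zero
  derivative in kϑ; the linear time law bypasses the local Newton (its
  finite-difference update is exact);
* porosity admissibility (0 < n < 1, strict stretch bounds from the porosity
  constraint) is checked on every committed step and aborts the run with the
  offending element.

## Benchmarks and problem sizes

* **rigid-time**: 120 elements, dt = 0.5 s, 10 consolidation + 300 growth
  steps; validated against the closed-form quasi-static Poisson solution for
  pore pressure, the homogeneous effective stress [−3λ lnϑ + μ(ϑ⁻²−1)], and
  exact porosity histories, for both mass-source variants.
* **stress-he / stress-mphets**: 320 elements, dt = 50 s, 5 load + 1
  consolidation + 1000 growth steps with the Mandel-stress law.
* **conc-largeP / conc-smallP**: 160 elements, dt = 50 s, 5 load + 2000
  growth steps at the two diffusivities.

The synthetic scenarios are idealized: homogeneous isotropic properties,
plane-strain kinematics, constant transport parameters, and growth laws with
illustrative (not physiologically identified) rate constants.  Passing tests
therefore demonstrate correctness of the numerics and the published benchmark
behaviour, not predictive accuracy for real arteries.

## Known limitations

Isotropic growth only; no remodeling (density/stiffness change), no
strain-dependent permeability or diffusivity, no charged species or osmotic
swelling scenarios (the osmotic terms are implemented but the benchmarks use
φᶜ = 0), no contact, no 3D.  Low-order elements require fairly dense meshes;
the near-incompressible skeleton is unproblematic here because the benchmark
kinematics are essentially one-dimensional in radius.
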