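# porogrowth

Axisymmetric finite elements for **growing porohyperelastic soft tissue**: a
saturated porous Neo-Hookean skeleton with interstitial Darcy flow and the
transport of a dissolved neutral species (a drug, growth factor or cytokine),
extended with isotropic volumetric growth.  The package is built for
simulating growth and remodeling of soft tissues — the worked benchmarks
model a coronary artery wall under intraluminal pressure — and for comparing
mixture-model growth against classical hyperelastic (solid-only) growth.

## The model

The solid skeleton, fluid and species form a saturated mixture with primary
fields (u, μ̃f\*, μ̃c\*): displacement, fluid potential and chemical
potential.  The potentials are continuous across material interfaces even
when pore pressure and concentration jump (partition coefficient), and invert
in closed form:

    μ̃f* = pf + p⁰ₒ − R̄θ φᶜ c,     μ̃c* = μ⁰c + R̄θ ln(γᶜ c).

Growth enters through the multiplicative split **F** = **Fᵉ Fᵍ** with
**Fᵍ** = ϑ**I**.  The stretch ϑ evolves per element by one of three laws

    ϑ̇ = α                    (linear in time)
    ϑ̇ = kϑ(ϑ)·(c − c_thresh)  (concentration-driven)
    ϑ̇ = kϑ(ϑ)·tr(M^eff,e)    (stress-driven, Mandel-stress conjugate)

where kϑ is the Lubarda–Hoger limiter saturating at ϑmax/ϑmin.  Growth adds
mass: the volumetric source 3ϑ²ϑ̇ enters the fluid balance, the porosity
becomes n = 1 − J⁻¹[(1−n₀) + ρ̄ˢ(ϑ³−1)], and the admissibility constraint
0 < n < 1 bounds how far ϑ may go.  Total stress follows the effective-stress
principle with the growth pullback,

    S = Sᵉᶠᶠ − J H pf,    Sᵉᶠᶠ = Sᵉᶠᶠ'ᵉ / ϑ²,

with a compressible Neo-Hookean Sᵉᶠᶠ'ᵉ = (λ ln Jᵉ − μ) Cᵉ⁻¹ + μI.  The
discretization uses linear axisymmetric triangles with single-point
quadrature, closed-form secondary recovery at the Gauss points, and a nested
Newton–Raphson scheme: a per-element backward-Euler update of ϑ at fixed
**F** inside every global iteration.

## Worked example

Time-driven growth of a rigid, internally pressurized artery (an exact
analytic solution exists for this case):

```python
import numpy as np
from porogrowth import RigidCylinderSpec, limiting_growth_time
from porogrowth.scenarios import preset_config, run_scenario

spec = RigidCylinderSpec()            # 1 -> 1.25 mm wall, 100 mmHg, alpha=8e-4
print(f"admissibility limit: {limiting_growth_time(spec):.1f} s")

run = run_scenario(preset_config("rigid-time"))
final = run.summary.iloc[-1]
print(f"theta after 150 s growth: {final['theta_max[-]']:.4f}")
print(f"porosity: {final['n_min[-]']:.4f}")
```

prints

```
admissibility limit: 180.9 s
theta after 150 s growth: 1.1200
porosity: 0.0951
```

meaning: the simple linear law ϑ = 1 + αt would render the porous model
invalid (porosity 0) at ≈181 s, so growth is applied for 150 s, reaching
ϑ = 1.12; solid-only growth in the rigid wall has squeezed the porosity from
0.5 down to n₀ − (ϑ³−1) ≈ 0.095.  The solver's pore-pressure profile and the
homogeneous compressive effective stress match the closed forms to a fraction
of a percent (see `tests/test_acceptance.py`).

From the shell, the same scenarios run as:

```bash
porogrowth check --scenario rigid-time        # admissibility limit report
porogrowth run --scenario stress-mphets       # CSV time series to runs/
porogrowth oracle --alpha 0 --out oracle.csv  # analytic curves
```

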