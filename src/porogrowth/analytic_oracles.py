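"""Closed-form solutions for the pressurized rigid cylinder with time growth.

With every material point held fixed (F = I for all time) and the linear time
law theta(t) = 1 + alpha*t, the fluid balance reduces at each instant to an
axisymmetric Poisson problem for the pore pressure,

    (1/r) d/dr ( r dpf/dr ) = -s(t)/kff,   s(t) = 3 theta^2 theta_dot,

with pf(ri) = Pi and pf(ro) = 0; the solution is quasi-static because the
incompressible constituents admit no pressure storage term.  The effective
stress is spatially homogeneous and follows from Fe = I/theta.  These closed
forms serve as validation oracles for the finite element solver and provide
the porosity-admissibility time limit of the simple time law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MaterialParams

__all__ = [
    "RigidCylinderSpec",
    "rigid_pf_profile",
    "rigid_effective_stress",
    "rigid_porosity",
    "limiting_growth_time",
]


@dataclass(frozen=True)
class RigidCylinderSpec:
    """Geometry, load, transport and growth data of the rigid benchmark."""

    ri: float = 1e-3  # inner radius [m]
    ro: float = 1.25e-3  # outer radius [m]
    Pi: float = 100.0 * 133.322  # inner pore pressure [Pa]
    kff: float = 2e-14  # permeability [m^4/(N s)]
    alpha: float = 8e-4  # linear growth rate [1/s]
    n0: float = 0.5
    rho_bar_s: float = 1.0
    mat: MaterialParams = field(default_factory=lambda: MaterialParams(1e6, 5.5e-9))

    def __post_init__(self) -> None:
        if not (0.0 < self.ri < self.ro):
            raise ValueError("need 0 < ri < ro")
        if self.Pi < 0.0:
            raise ValueError("Pi must be non-negative")

    def theta(self, t: float) -> float:
        """Growth stretch at growth time t (t <= 0 means no growth yet)."""
        return 1.0 + self.alpha * max(t, 0.0)

    def volumetric_source(self, t: float) -> float:
        """s(t) = 3 theta^2 theta_dot = 3 (1+alpha t)^2 alpha for t > 0."""
        if t <= 0.0 or self.alpha == 0.0:
            return 0.0
        return 3.0 * self.theta(t) ** 2 * self.alpha


def rigid_pf_profile(
    spec: RigidCylinderSpec, t: float, r: np.ndarray | float
) -> np.ndarray | float:
    """Pore pressure pf(r) at growth time t.

    pf(r) = -(s/(4 kff)) r^2 + A ln r + B with A, B fixed by pf(ri) = Pi,
    pf(ro) = 0.  For s = 0 this is the classical logarithmic profile.
    """
    r = np.asarray(r, dtype=float)
    s = spec.volumetric_source(t)
    g = lambda x: -(s / (4.0 * spec.kff)) * x**2
    A = (spec.Pi - g(spec.ri) + g(spec.ro)) / np.log(spec.ri / spec.ro)
    B = -g(spec.ro) - A * np.log(spec.ro)
    out = g(r) + A * np.log(r) + B
    return out if out.shape else float(out)


def rigid_effective_stress(spec: RigidCylinderSpec, t: float) -> float:
    """Diagonal value of the homogeneous effective stress at growth time t.

    With Fe = I/theta: Seff = [-3 lam ln(theta) + mu (theta^-2 - 1)];
    compressive (negative) for theta > 1 since growth is geometrically
    constrained by rigidity.
    """
    th = spec.theta(t)
    lam, mu = spec.mat.lam, spec.mat.mu
    return -3.0 * lam * np.log(th) + mu * (th**-2 - 1.0)


def rigid_porosity(spec: RigidCylinderSpec, t: float) -> float:
    """Porosity history n(t) = n0 - rho_bar_s (theta^3 - 1) (J = 1)."""
    th = spec.theta(t)
    return spec.n0 - spec.rho_bar_s * (th**3 - 1.0)


def limiting_growth_time(spec: RigidCylinderSpec, J: float = 1.0) -> float:
    """Time at which theta = 1 + alpha*t hits the porosity admissibility bound.

    t_limit = ([1 + (J - 1 + n0)/rho_bar_s]^(1/3) - 1)/alpha; infinity when
    alpha <= 0.  Independent of time step size.
    """
    if spec.alpha <= 0.0:
        return float("inf")
    theta_upper = (1.0 + (J - 1.0 + spec.n0) / spec.rho_bar_s) ** (1.0 / 3.0)
    return (theta_upper - 1.0) / spec.alpha
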