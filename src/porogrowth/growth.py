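"""Growth-stretch evolution, mass sources, porosity and admissibility.

The growth stretch ``theta`` (one value per element, matching the single-point
quadrature) evolves by one of three laws:

* ``time_linear``   theta_dot = alpha (exact finite-difference update);
* ``concentration`` theta_dot = k_theta(theta) * (c - c_thresh);
* ``stress``        theta_dot = k_theta(theta) * tr(M^eff,e).

The Lubarda-Hoger limiter ``k_theta`` saturates growth at theta_max and
resorption at theta_min.  Nonlinear laws are integrated by backward Euler with
a safeguarded local Newton per element, run at fixed total deformation F (so
for the stress driver the elastic strain Ce = C/theta^2 varies with the trial
theta).  True constituent densities never enter the discrete equations; only
the normalized solid growth density ``rho_bar_s`` (1 for solid-only growth,
1 - n0 for solid/fluid growth) and density-specific sources appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "GrowthLawParams",
    "GrowthState",
    "SourceTerms",
    "k_theta",
    "theta_update_linear",
    "theta_update_local_newton",
    "source_terms",
    "porosity_after_growth",
    "check_admissibility",
    "AdmissibilityError",
    "LocalGrowthDivergenceError",
]

_CLIP_TOL = 1e-12  # half-open clipping inset at theta_min/theta_max


class AdmissibilityError(ValueError):
    """Growth stretch or porosity outside the admissible porous-media range."""


class LocalGrowthDivergenceError(RuntimeError):
    """Local backward-Euler Newton failed (suggests a smaller time step)."""


@dataclass(frozen=True)
class GrowthLawParams:
    """Parameters of a growth law.

    law: 'time_linear', 'concentration' or 'stress'.
    alpha: growth rate of the linear law [1/s].
    tau_plus/tau_minus: relaxation scales of the limiter (per driver unit:
        Pa for the stress law, mol/m^3 for the concentration law).
    gamma_plus/gamma_minus: limiter exponents.
    theta_max/theta_min: stretch bounds.
    c_thresh: concentration threshold [mol/m^3] (concentration law only).
    """

    law: str = "time_linear"
    alpha: float = 0.0
    tau_plus: float = 1.0
    tau_minus: float = 1.0
    gamma_plus: float = 2.0
    gamma_minus: float = 3.0
    theta_max: float = 1.2
    theta_min: float = 0.8
    c_thresh: float = 0.0

    def __post_init__(self) -> None:
        if self.law not in ("time_linear", "concentration", "stress"):
            raise ValueError(f"unknown growth law {self.law!r}")
        if not (self.theta_min < 1.0 < self.theta_max):
            raise ValueError("need theta_min < 1 < theta_max")
        if self.tau_plus <= 0.0 or self.tau_minus <= 0.0:
            raise ValueError("tau_plus and tau_minus must be positive")
        if self.gamma_plus < 1.0 or self.gamma_minus < 1.0:
            raise ValueError("gamma exponents must be >= 1")


@dataclass
class GrowthState:
    """Per-element growth variables."""

    theta: np.ndarray  # growth stretch [-]
    theta_dot: np.ndarray  # [1/s]
    rho_bar_s: float  # normalized solid growth density: 1 or 1-n0
    n0: float  # initial porosity


@dataclass
class SourceTerms:
    """Density-specific Lagrangian mass sources [1/s]."""

    R0s_over_rhoTs: np.ndarray
    R0f_over_rhoTf: np.ndarray
    volumetric_source: np.ndarray  # 3 theta^2 theta_dot, enters fluid balance


def k_theta(
    theta: np.ndarray | float,
    phi_g_sign: np.ndarray | float,
    p: GrowthLawParams,
) -> np.ndarray:
    """Lubarda-Hoger growth/resorption limiter.

    (1/tau+)*((theta_max-theta)/(theta_max-1))^gamma+ for a positive driver,
    (1/tau-)*((theta-theta_min)/(1-theta_min))^gamma- for a negative one,
    zero for a vanishing driver.
    """
    th = np.asarray(theta, dtype=float)
    sgn = np.broadcast_to(np.asarray(phi_g_sign, dtype=float), th.shape)
    if np.any(th < p.theta_min - 1e-9) or np.any(th > p.theta_max + 1e-9):
        raise AdmissibilityError(
            f"theta outside [{p.theta_min}, {p.theta_max}]"
        )
    thc = np.clip(th, p.theta_min, p.theta_max)
    up = ((p.theta_max - thc) / (p.theta_max - 1.0)) ** p.gamma_plus / p.tau_plus
    dn = ((thc - p.theta_min) / (1.0 - p.theta_min)) ** p.gamma_minus / p.tau_minus
    out = np.where(sgn > 0.0, up, np.where(sgn < 0.0, dn, 0.0))
    return out if out.shape else float(out)


def _k_theta_prime(theta: np.ndarray, sgn: np.ndarray, p: GrowthLawParams) -> np.ndarray:
    """d k_theta / d theta on the active branch (0 for zero driver)."""
    th = np.clip(np.asarray(theta, dtype=float), p.theta_min, p.theta_max)
    up = (
        -p.gamma_plus
        / p.tau_plus
        * ((p.theta_max - th) / (p.theta_max - 1.0)) ** (p.gamma_plus - 1.0)
        / (p.theta_max - 1.0)
    )
    dn = (
        p.gamma_minus
        / p.tau_minus
        * ((th - p.theta_min) / (1.0 - p.theta_min)) ** (p.gamma_minus - 1.0)
        / (1.0 - p.theta_min)
    )
    return np.where(sgn > 0.0, up, np.where(sgn < 0.0, dn, 0.0))


def theta_update_linear(
    theta_n: np.ndarray | float, alpha: float, dt: float
) -> np.ndarray | float:
    """Exact update of the linear time law: theta_{n+1} = theta_n + alpha*dt."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    return np.asarray(theta_n, dtype=float) + alpha * dt


def theta_update_local_newton(
    theta_n: float,
    driver_provider: Callable[[float], tuple[float, float]],
    p: GrowthLawParams,
    dt: float,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> float:
    """Backward-Euler root of R(theta) = theta - theta_n - k*phi*dt.

    ``driver_provider(theta)`` returns ``(phi_g, dphi_g/dtheta)`` at the trial
    stretch (total F held fixed, so a stress driver sees Ce = C/theta^2 vary).
    Newton iterations are safeguarded by bisection on the bracket delimited by
    theta_n and the active bound; the result is clipped just inside
    [theta_min, theta_max].
    """

    def residual(th: float) -> tuple[float, float]:
        phi, dphi = driver_provider(th)
        kt = float(k_theta(th, np.sign(phi), p))
        ktp = float(_k_theta_prime(np.asarray(th), np.asarray(np.sign(phi)), p))
        R = th - theta_n - kt * phi * dt
        dR = 1.0 - (ktp * phi + kt * dphi) * dt
        return R, dR

    phi0, _ = driver_provider(theta_n)
    if phi0 == 0.0:
        return theta_n
    lo, hi = (theta_n, p.theta_max) if phi0 > 0.0 else (p.theta_min, theta_n)
    th = float(np.clip(theta_n, lo, hi))
    for _ in range(max_iter):
        R, dR = residual(th)
        if abs(R) < tol:
            return float(np.clip(th, p.theta_min + _CLIP_TOL, p.theta_max - _CLIP_TOL))
        if R > 0.0:
            hi = th
        else:
            lo = th
        step_ok = dR != 0.0
        th_new = th - R / dR if step_ok else 0.5 * (lo + hi)
        if not (lo <= th_new <= hi):
            th_new = 0.5 * (lo + hi)
        th = th_new
    raise LocalGrowthDivergenceError(
        f"local growth Newton did not converge (last |R|={abs(R):.3e}); "
        "try a smaller time step"
    )


def source_terms(
    theta: np.ndarray | float,
    theta_dot: np.ndarray | float,
    rho_bar_s: float,
    growth_case: str,
) -> SourceTerms:
    """Density-specific mass sources for the two supported growth cases.

    solid_only:  R0s/rhoTs = 3 theta^2 theta_dot, fluid term zero.
    solid_fluid: R0s/rhoTs = 3 (1-n0) theta^2 theta_dot,
                 R0f/rhoTf = 3 n0 theta^2 theta_dot.
    In both cases the volumetric source entering the fluid balance is
    3 theta^2 theta_dot (the density-specific terms sum to it).
    """
    th = np.asarray(theta, dtype=float)
    td = np.asarray(theta_dot, dtype=float)
    vol = 3.0 * th**2 * td
    if growth_case == "solid_only":
        return SourceTerms(vol, np.zeros_like(vol), vol)
    if growth_case == "solid_fluid":
        # rho_bar_s = 1 - n0 here; fluid share is n0 = 1 - rho_bar_s
        return SourceTerms(rho_bar_s * vol, (1.0 - rho_bar_s) * vol, vol)
    raise ValueError(f"unknown growth case {growth_case!r}")


def porosity_after_growth(
    J: np.ndarray | float,
    theta: np.ndarray | float,
    n0: float,
    rho_bar_s: float,
) -> np.ndarray | float:
    """Eulerian porosity n = 1 - J^-1 [(1-n0) + rho_bar_s (theta^3 - 1)]."""
    J = np.asarray(J, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any(J <= 0.0) or np.any(th <= 0.0):
        raise ValueError("J and theta must be positive")
    n = 1.0 - (1.0 / J) * ((1.0 - n0) + rho_bar_s * (th**3 - 1.0))
    if np.any(n < 0.0) or np.any(n > 1.0):
        raise AdmissibilityError(
            "porosity left [0, 1]: material became purely solid or fluid"
        )
    return n if np.ndim(n) else float(n)


def check_admissibility(
    J: np.ndarray | float,
    theta: np.ndarray | float,
    n0: float,
    rho_bar_s: float,
) -> tuple[np.ndarray | bool, np.ndarray | float, np.ndarray | float]:
    """Strict stretch bounds keeping the porosity inside (0, 1).

    theta_upper = (1 + (J - 1 + n0)/rho_bar_s)^(1/3),
    theta_lower = (1 + (n0 - 1)/rho_bar_s)^(1/3);
    admissible iff theta_lower < theta < theta_upper.
    """
    J = np.asarray(J, dtype=float)
    th = np.asarray(theta, dtype=float)
    upper = (1.0 + (J - 1.0 + n0) / rho_bar_s) ** (1.0 / 3.0)
    lower_arg = 1.0 + (n0 - 1.0) / rho_bar_s
    lower = np.maximum(lower_arg, 0.0) ** (1.0 / 3.0) * np.ones_like(J)
    ok = (th > lower) & (th < upper)
    if np.ndim(ok):
        return ok, upper, lower
    return bool(ok), float(upper), float(lower)
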