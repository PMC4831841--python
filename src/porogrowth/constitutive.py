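"""Pointwise material behaviour for a growing porohyperelastic mixture.

Covers the kinematics of the multiplicative growth split F = Fe Fg with
isotropic Fg = theta*I, the compressible Neo-Hookean effective stress and its
Lagrangian tangent, the growth pullback and total (effective-stress-principle)
stress, the Onsager transport coefficients coupling Darcy and Fick fluxes, and
the mechano-chemical potentials that link the continuous nodal variables
(mu_f, mu_c) to the discontinuous secondary variables (pore pressure pf,
concentration c).

All tensor operations accept stacked arrays with leading batch dimensions,
e.g. (n_elements, 3, 3); the axisymmetric tensor axes are ordered (R, Z, hoop).
Units are strict SI; pressures in Pa, concentrations in mol/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "TransportParams",
    "Kinematics",
    "StressState",
    "lame_from_c10_d1",
    "compute_kinematics",
    "neo_hookean_stress",
    "elastic_tangent",
    "total_stress",
    "transport_coeffs",
    "fluxes",
    "potentials_forward",
    "secondary_from_potentials",
    "R_GAS",
    "BODY_TEMPERATURE",
    "MMHG_TO_PA",
    "ParameterError",
    "KinematicsError",
    "StateError",
]

R_GAS = 8.31  # universal gas constant [J/(K mol)]
BODY_TEMPERATURE = 310.0  # [K]
MMHG_TO_PA = 133.322  # unit conversion at the I/O boundary


class ParameterError(ValueError):
    """Invalid material/transport parameter."""


class KinematicsError(ValueError):
    """Inadmissible deformation state (non-SPD strain, inverted element)."""


class StateError(ValueError):
    """Inadmissible secondary state (e.g. non-positive concentration)."""


def lame_from_c10_d1(C10: float, D1: float) -> tuple[float, float, float]:
    """Lame parameters (lam, mu, kappa) from the (C10, D1) parameter set.

    mu = 2*C10, kappa = 2/D1, lam = kappa - (2/3)*mu.
    """
    if C10 <= 0.0 or D1 <= 0.0:
        raise ParameterError(f"C10 and D1 must be positive, got {C10}, {D1}")
    mu = 2.0 * C10
    kappa = 2.0 / D1
    lam = kappa - (2.0 / 3.0) * mu
    return lam, mu, kappa


@dataclass(frozen=True)
class MaterialParams:
    """Neo-Hookean solid skeleton parameters (all in Pa except D1 in 1/Pa)."""

    C10: float
    D1: float

    @property
    def mu(self) -> float:
        return 2.0 * self.C10

    @property
    def kappa(self) -> float:
        return 2.0 / self.D1

    @property
    def lam(self) -> float:
        return self.kappa - (2.0 / 3.0) * self.mu

    def __post_init__(self) -> None:
        if self.C10 <= 0.0 or self.D1 <= 0.0:
            raise ParameterError("C10 and D1 must be positive")


@dataclass(frozen=True)
class TransportParams:
    """Darcy/Fick/osmotic parameters of the interstitial fluid and species.

    kff: hydraulic permeability [m^4/(N s)]
    bfc: convection coupling coefficient (= bcf, stored once) [-]
    dcc: species diffusivity parameter [m^2/s]
    n0: initial (Lagrangian) porosity [-]
    phi_c: osmotic coefficient [-]
    gamma_mat: species activity coefficient inside the material [-]
    p0o: baseline osmotic potential datum [Pa]
    mu0c: baseline chemical potential datum [J/mol]

    The datums shift the potentials uniformly and cancel in all gradients;
    results are datum-invariant (asserted by tests).
    """

    kff: float = 2e-14
    bfc: float = 6e-4
    dcc: float = 4.55e-14
    n0: float = 0.5
    phi_c: float = 0.0
    gamma_mat: float = 0.5
    p0o: float = 0.0
    mu0c: float = 0.0
    Rbar: float = R_GAS
    theta: float = BODY_TEMPERATURE

    def __post_init__(self) -> None:
        if not (0.0 < self.n0 < 1.0):
            raise ParameterError(f"porosity n0 must lie in (0,1), got {self.n0}")
        if self.kff < 0.0 or self.dcc < 0.0:
            raise ParameterError("kff and dcc must be non-negative")
        if self.theta <= 0.0 or self.gamma_mat <= 0.0:
            raise ParameterError("theta and gamma_mat must be positive")

    @property
    def RT(self) -> float:
        return self.Rbar * self.theta


@dataclass
class Kinematics:
    """Per-point deformation measures with the isotropic growth split."""

    F: np.ndarray
    J: np.ndarray
    C: np.ndarray
    Cinv: np.ndarray  # equals Finger's tensor H = F^-1 F^-T
    E: np.ndarray
    Fe: np.ndarray
    Ce: np.ndarray
    Je: np.ndarray
    Jg: np.ndarray
    theta_g: np.ndarray

    @property
    def H(self) -> np.ndarray:
        return self.Cinv


@dataclass
class StressState:
    """Second Piola-Kirchhoff stresses, Mandel trace and Cauchy stress."""

    Seff_e: np.ndarray  # effective, elastic 2nd PK [Pa]
    Seff: np.ndarray  # effective (growth pullback applied) [Pa]
    S: np.ndarray  # total [Pa]
    trM: np.ndarray  # trace of effective, elastic Mandel stress [Pa]
    sigma: np.ndarray  # Cauchy [Pa]


def _eye_like(a: np.ndarray) -> np.ndarray:
    return np.broadcast_to(np.eye(3), a.shape).copy()


def compute_kinematics(
    grad_u: np.ndarray, hoop_stretch: np.ndarray | float, theta_g: np.ndarray | float
) -> Kinematics:
    """Axisymmetric kinematics from the in-plane displacement gradient.

    ``grad_u`` is (..., 2, 2) holding d(u_R,u_Z)/d(R,Z); ``hoop_stretch`` is
    the circumferential stretch (R + u_R)/R at the Gauss point.  The growth
    split is isotropic: Fe = F/theta_g, Jg = theta_g^3, Je = J/Jg.
    """
    grad_u = np.asarray(grad_u, dtype=float)
    batch = grad_u.shape[:-2]
    F = np.zeros(batch + (3, 3))
    F[..., :2, :2] = grad_u
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] = hoop_stretch
    return kinematics_from_F(F, theta_g)


def kinematics_from_F(F: np.ndarray, theta_g: np.ndarray | float) -> Kinematics:
    F = np.asarray(F, dtype=float)
    th = np.broadcast_to(np.asarray(theta_g, dtype=float), F.shape[:-2]).copy()
    if np.any(th <= 0.0):
        raise KinematicsError("growth stretch theta must be positive")
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise KinematicsError("inverted element: det F <= 0")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    E = 0.5 * (C - np.eye(3))
    Fe = F / th[..., None, None]
    Jg = th**3
    Je = J / Jg
    Ce = C / (th**2)[..., None, None]
    return Kinematics(F=F, J=J, C=C, Cinv=Cinv, E=E, Fe=Fe, Ce=Ce, Je=Je, Jg=Jg,
                      theta_g=th)


def neo_hookean_stress(Ce: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Effective, elastic 2nd Piola-Kirchhoff stress of the skeleton.

    Seff_e = (lam*ln(Je) - mu) * Ce^-1 + mu * I  with  Je = sqrt(det Ce).
    """
    Ce = np.asarray(Ce, dtype=float)
    detCe = np.linalg.det(Ce)
    if np.any(detCe <= 0.0) or not np.allclose(Ce, np.swapaxes(Ce, -1, -2)):
        raise KinematicsError("Ce must be symmetric positive-definite")
    lnJe = 0.5 * np.log(detCe)
    Ceinv = np.linalg.inv(Ce)
    coef = params.lam * lnJe - params.mu
    return coef[..., None, None] * Ceinv + params.mu * np.eye(3)


def elastic_tangent(Ce: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Elastic Lagrangian tangent modulus Le = 2 dSeff_e/dCe (minor+major sym).

    Le_ijkl = lam * Cinv_ij Cinv_kl
            + (mu - lam ln Je) * (Cinv_ik Cinv_lj + Cinv_il Cinv_kj)
    """
    Ce = np.asarray(Ce, dtype=float)
    detCe = np.linalg.det(Ce)
    if np.any(detCe <= 0.0):
        raise KinematicsError("Ce must be symmetric positive-definite")
    lnJe = 0.5 * np.log(detCe)
    Ci = np.linalg.inv(Ce)
    lam, mu = params.lam, params.mu
    t1 = lam * np.einsum("...ij,...kl->...ijkl", Ci, Ci)
    t2 = np.einsum("...ik,...lj->...ijkl", Ci, Ci)
    t3 = np.einsum("...il,...kj->...ijkl", Ci, Ci)
    return t1 + (mu - lam * lnJe)[..., None, None, None, None] * (t2 + t3)


def total_stress(
    Seff_e: np.ndarray,
    kin: Kinematics,
    theta_g: np.ndarray | float | None = None,
    pf: np.ndarray | float = 0.0,
) -> StressState:
    """Growth pullback and effective stress principle.

    Seff = Seff_e / theta^2;  S = Seff - J * H * pf;
    trM = tr(Ce Seff_e);  sigma = J^-1 F S F^T.
    """
    th = kin.theta_g if theta_g is None else np.broadcast_to(
        np.asarray(theta_g, dtype=float), kin.J.shape
    )
    pf = np.broadcast_to(np.asarray(pf, dtype=float), kin.J.shape)
    Seff = Seff_e / (th**2)[..., None, None]
    S = Seff - (kin.J * pf)[..., None, None] * kin.Cinv
    trM = np.einsum("...ij,...ji->...", kin.Ce, Seff_e)
    sigma = (
        np.einsum("...ip,...pq,...jq->...ij", kin.F, S, kin.F)
        / kin.J[..., None, None]
    )
    return StressState(Seff_e=Seff_e, Seff=Seff, S=S, trM=trM, sigma=sigma)


def transport_coeffs(
    kin: Kinematics, c: np.ndarray | float, tp: TransportParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lagrangian Onsager coefficient tensors (Lff, Lfc, Lcf, Lcc).

    Lff = J H kff;  Lfc = Lcf = J H kff bfc c;
    Lcc = J H (c dcc/(R theta) + c^2 kff bfc^2).

    The diffusive mobility c*dcc/(R theta) makes the diffusive part of the
    species flux reduce exactly to Fick's law jc = -dcc grad(c) (since
    grad(mu_c) = R theta grad(c)/c), so the Peclet-like number
    beta = kff*bfc/dcc is the genuine convective-to-diffusive flux ratio
    that separates the two diffusivity benchmarks.
    """
    c = np.broadcast_to(np.asarray(c, dtype=float), kin.J.shape)
    if np.any(c <= 0.0):
        raise StateError("concentration must be positive")
    JH = kin.J[..., None, None] * kin.Cinv
    Lff = tp.kff * JH
    Lfc = (tp.kff * tp.bfc * c)[..., None, None] * JH
    Lcc = (c * tp.dcc / tp.RT + c**2 * tp.kff * tp.bfc**2)[..., None, None] * JH
    return Lff, Lfc, Lfc.copy(), Lcc


def fluxes(
    grad_mu_f: np.ndarray,
    grad_mu_c: np.ndarray,
    coeffs: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Lagrangian relative fluid and species fluxes (generalized Darcy/Fick).

    jfr = -Lff grad(mu_f) - Lfc grad(mu_c);
    jcr = -Lcf grad(mu_f) - Lcc grad(mu_c).
    """
    Lff, Lfc, Lcf, Lcc = coeffs
    d = np.asarray(grad_mu_f).shape[-1]
    jfr = -np.einsum("...ij,...j->...i", Lff[..., :d, :d], grad_mu_f) - np.einsum(
        "...ij,...j->...i", Lfc[..., :d, :d], grad_mu_c
    )
    jcr = -np.einsum("...ij,...j->...i", Lcf[..., :d, :d], grad_mu_f) - np.einsum(
        "...ij,...j->...i", Lcc[..., :d, :d], grad_mu_c
    )
    return jfr, jcr


def potentials_forward(
    pf: np.ndarray | float, c: np.ndarray | float, tp: TransportParams
) -> tuple[np.ndarray, np.ndarray]:
    """Mechano-chemical potentials from the secondary variables.

    mu_f = pf + p0o - R theta phi_c c;  mu_c = mu0c + R theta ln(gamma_mat c).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0.0):
        raise StateError("concentration must be positive (log undefined)")
    mu_f = np.asarray(pf, dtype=float) + tp.p0o - tp.RT * tp.phi_c * c
    mu_c = tp.mu0c + tp.RT * np.log(tp.gamma_mat * c)
    return mu_f, mu_c


def secondary_from_potentials(
    mu_f: np.ndarray | float, mu_c: np.ndarray | float, tp: TransportParams
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form recovery of (pf, c) from the potentials; c > 0 always."""
    arg = (np.asarray(mu_c, dtype=float) - tp.mu0c) / tp.RT
    if np.any(arg > 500.0):
        raise StateError("diverged state: chemical potential overflow")
    c = np.exp(arg) / tp.gamma_mat
    pf = np.asarray(mu_f, dtype=float) - tp.p0o + tp.RT * tp.phi_c * c
    return pf, c


def partition_concentration(c_bath: float, partition_coefficient: float) -> float:
    """Material-side concentration across a bath interface.

    Equal chemical potential with activity ratio gamma_mat/gamma_bath =
    ``partition_coefficient`` gives c_mat = c_bath / partition_coefficient.
    """
    if partition_coefficient <= 0.0:
        raise ParameterError("partition coefficient must be positive")
    return c_bath / partition_coefficient
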