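"""Galerkin assembly and time stepping for the growing mixture model.

Weak forms of the three conservation laws on linear axisymmetric triangles
with single-point quadrature:

* momentum:  int grad(du) : (F S) dV - external traction work;
* fluid:     int [ grad(dmu_f) . (Lff grad mu_f + Lfc grad mu_c)
                   + dmu_f (J H : Edot - 3 theta^2 theta_dot) ] dV;
* species:   int [ grad(dmu_c) . (Lcf grad mu_f + Lcc grad mu_c)
                   + dmu_c (J H:Edot c - 3 rho_bar_s theta^2 theta_dot c
                            + J n cdot) ] dV;

with the axisymmetric measure 2*pi*gauss_R*area and rates by backward
differences over the step.  The element tangent is the analytic consistent
linearization, evaluated column-by-column as directional derivatives of the
residual (including the geometric stiffness, the growth pullback, the
transport-coefficient state dependence and, for state-driven growth laws, the
sensitivity of the converged local growth stretch to strain/concentration).

A time step runs the nested scheme of the underlying method: the first Newton
iteration from the previous converged state is the linearized incremental
(forward-Euler) predictor; subsequent iterations are backward-Euler
corrections, each preceded by the per-element local growth update at fixed F.
Secondary variables (pf, c) are recovered in closed form from the nodal
potentials at every iteration, so the secondary residual Psi_g is identically
zero; it is still monitored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import MaterialParams, TransportParams
from .growth import (
    AdmissibilityError,
    GrowthLawParams,
    LocalGrowthDivergenceError,
    _k_theta_prime,
    check_admissibility,
    k_theta,
    porosity_after_growth,
)
from .mesh_axisym import DofMap, Mesh, ModelMode, element_geometry

__all__ = [
    "DirichletBC",
    "TractionBC",
    "BoundaryConditions",
    "SolverState",
    "StepDiagnostics",
    "StepFailureError",
    "FEModel",
]

_I3 = np.eye(3)


class StepFailureError(RuntimeError):
    """Global Newton exceeded the iteration budget."""


@dataclass
class DirichletBC:
    """Prescribed dofs.

    With ``ramp`` the applied value interpolates from ``rest`` (the value of
    the unloaded state, e.g. the fluid potential at zero pore pressure) to
    ``values`` as the phase load factor goes 0 -> 1; without it ``values``
    applies directly.
    """

    dofs: np.ndarray
    values: np.ndarray
    ramp: bool = False
    rest: np.ndarray | float = 0.0

    def applied(self, load_factor: float) -> np.ndarray:
        if not self.ramp:
            return np.asarray(self.values, dtype=float)
        rest = np.broadcast_to(np.asarray(self.rest, dtype=float),
                               np.shape(self.values))
        return rest + load_factor * (np.asarray(self.values) - rest)


@dataclass
class TractionBC:
    """Follower pressure on a boundary edge of the strip (two nodes at equal R).

    The pressure acts on the current cylindrical surface 2*pi*(R+u_R)*h and is
    positive pushing in +R (internal pressurization of the inner face).
    """

    nodes: tuple[int, int]
    pressure: float  # [Pa]
    ramp: bool = True


@dataclass
class BoundaryConditions:
    dirichlet: list[DirichletBC] = field(default_factory=list)
    tractions: list[TractionBC] = field(default_factory=list)

    def fixed_dofs(self, n_dofs: int) -> np.ndarray:
        mask = np.zeros(n_dofs, dtype=bool)
        for bc in self.dirichlet:
            mask[bc.dofs] = True
        return mask


@dataclass
class SolverState:
    """Committed solver state plus the last assembled system.

    ``K_hat`` is the consistent Jacobian of the backward-Euler residual
    (stiffness plus dissipation over dt); ``Psi`` the primary residual at the
    converged state; ``Psi_g`` the monitored secondary residual, identically
    zero under closed-form secondary recovery.
    """

    p: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    C_prev: np.ndarray
    c_prev: np.ndarray
    t: float = 0.0
    K_hat: sp.spmatrix | None = None
    Psi: np.ndarray | None = None
    Psi_g: float = 0.0


@dataclass
class StepDiagnostics:
    t: float
    iterations: int
    residual_norm: float
    theta_min: float
    theta_max: float
    porosity_min: float
    porosity_max: float


class FEModel:
    """Finite element model of one scenario on a fixed reference mesh."""

    def __init__(
        self,
        mesh: Mesh,
        mode: ModelMode,
        mat: MaterialParams,
        tp: TransportParams,
        growth_params: GrowthLawParams,
        bc: BoundaryConditions,
        rho_bar_s: float = 1.0,
        growth_case: str = "solid_only",
        tol_r: float = 1e-8,
        tol_p: float = 1e-10,
        max_iter: int = 25,
    ) -> None:
        self.mesh = mesh
        self.mode = mode
        self.mat = mat
        self.tp = tp
        self.gp = growth_params
        self.bc = bc
        self.rho_bar_s = rho_bar_s
        self.growth_case = growth_case
        self.tol_r = tol_r
        self.tol_p = tol_p
        self.max_iter = max_iter

        self.dofmap = DofMap(mode, mesh.n_nodes)
        self.npn = mode.ndof_per_node
        self.nloc = 3 * self.npn

        coords = mesh.coords
        conn = mesh.connectivity
        ne = mesh.n_elements
        self.conn = conn
        B = np.empty((ne, 3, 2))
        area = np.empty(ne)
        Rg = np.empty(ne)
        for e, el in enumerate(mesh.elements):
            area[e], B[e], Rg[e] = element_geometry(el, coords)
        self.B, self.area, self.Rg = B, area, Rg
        self.w = 2.0 * np.pi * Rg * area  # axisymmetric volume weights

        # local->global dof scatter
        gd = np.empty((ne, self.nloc), dtype=int)
        for a in range(3):
            for l in range(self.npn):
                gd[:, a * self.npn + l] = conn[:, a] * self.npn + l
        self.gdofs = gd
        self._rows = np.repeat(gd, self.nloc, axis=1).ravel()
        self._cols = np.tile(gd, (1, self.nloc)).ravel()

        self._fixed = bc.fixed_dofs(self.dofmap.n_dofs)
        self._free = np.flatnonzero(~self._fixed)
        self._free_mu_c_local = (
            np.flatnonzero(self._free % self.npn == 3)
            if mode.has_species
            else np.array([], dtype=int)
        )

    # ------------------------------------------------------------------
    # state initialisation
    # ------------------------------------------------------------------

    def initial_state(self, c0: float | None = None) -> SolverState:
        """Undeformed, unloaded state; interior concentration ``c0``."""
        ne = self.mesh.n_elements
        p = np.zeros(self.dofmap.n_dofs)
        if self.mode.has_fluid:
            # unloaded state has zero pore pressure, not zero potential
            mu_f0 = self.tp.p0o - self.tp.RT * self.tp.phi_c * (
                c0 if (self.mode.has_species and c0) else 0.0
            )
            p[self.dofmap.field_dofs("mu_f")] = mu_f0
        if self.mode.has_species:
            if c0 is None or c0 <= 0.0:
                raise ValueError("species mode needs a positive initial concentration")
            mu_c0 = self.tp.mu0c + self.tp.RT * np.log(self.tp.gamma_mat * c0)
            p[self.dofmap.field_dofs("mu_c")] = mu_c0
            c_prev = np.full(ne, c0)
        else:
            c_prev = np.zeros(ne)
        C_prev = np.broadcast_to(_I3, (ne, 3, 3)).copy()
        return SolverState(
            p=p,
            theta=np.ones(ne),
            theta_dot=np.zeros(ne),
            C_prev=C_prev,
            c_prev=c_prev,
        )

    # ------------------------------------------------------------------
    # kinematic / secondary state at the Gauss points
    # ------------------------------------------------------------------

    def _gather(self, p: np.ndarray, local: int) -> np.ndarray:
        """(ne, 3) nodal values of one per-node field."""
        return p[self.conn * self.npn + local]

    def kin_state(self, p: np.ndarray) -> dict:
        uR = self._gather(p, 0)
        uZ = self._gather(p, 1)
        ne = self.mesh.n_elements
        guR = np.einsum("eaj,ea->ej", self.B, uR)
        guZ = np.einsum("eaj,ea->ej", self.B, uZ)
        F = np.zeros((ne, 3, 3))
        F[:, 0, 0] = 1.0 + guR[:, 0]
        F[:, 0, 1] = guR[:, 1]
        F[:, 1, 0] = guZ[:, 0]
        F[:, 1, 1] = 1.0 + guZ[:, 1]
        F[:, 2, 2] = 1.0 + uR.mean(axis=1) / self.Rg
        J = np.linalg.det(F)
        if np.any(J <= 0.0):
            raise AdmissibilityError("inverted element: det F <= 0")
        C = np.einsum("eki,ekj->eij", F, F)
        Cinv = np.linalg.inv(C)
        Finv = np.linalg.inv(F)
        ks = {
            "F": F, "J": J, "C": C, "Cinv": Cinv, "Finv": Finv,
            "lnJ": np.log(J), "trC": np.einsum("eii->e", C),
        }
        if self.mode.has_fluid:
            mf = self._gather(p, 2)
            ks["mu_f"] = mf.mean(axis=1)
            ks["g_mf"] = np.einsum("eaj,ea->ej", self.B, mf)
        if self.mode.has_species:
            mc = self._gather(p, 3)
            ks["mu_c"] = mc.mean(axis=1)
            ks["g_mc"] = np.einsum("eaj,ea->ej", self.B, mc)
            arg = (ks["mu_c"] - self.tp.mu0c) / self.tp.RT
            if np.any(arg > 500.0):
                raise AdmissibilityError(
                    "diverged state: chemical potential overflow"
                )
            ks["c"] = np.exp(arg) / self.tp.gamma_mat
        else:
            ks["c"] = np.zeros(ne)
        if self.mode.has_fluid:
            ks["pf"] = ks["mu_f"] - self.tp.p0o + self.tp.RT * self.tp.phi_c * ks["c"]
        else:
            ks["pf"] = np.zeros(ne)
        return ks

    # ------------------------------------------------------------------
    # local growth update (per element, at fixed F)
    # ------------------------------------------------------------------

    def update_theta(
        self, ks: dict, theta_n: np.ndarray, dt: float, growth_active: bool
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (theta, dtheta/dC (ne,3,3), dtheta/dc (ne,))."""
        ne = self.mesh.n_elements
        aC = np.zeros((ne, 3, 3))
        ac = np.zeros(ne)
        if not growth_active:
            return theta_n.copy(), aC, ac
        gp = self.gp
        if gp.law == "time_linear":
            return theta_n + gp.alpha * dt, aC, ac
        if gp.law == "concentration":
            phi = ks["c"] - gp.c_thresh
            th = self._newton_theta(theta_n, lambda t: (phi, np.zeros(ne)), dt)
            sgn = np.sign(phi)
            kt = np.asarray(k_theta(th, sgn, gp))
            ktp = _k_theta_prime(th, sgn, gp)
            D = 1.0 - ktp * phi * dt
            ac = kt * dt / D
            return th, aC, ac
        # stress-driven: driver tr(M^eff,e) at trial theta, F fixed
        lam, mu = self.mat.lam, self.mat.mu
        lnJ, trC = ks["lnJ"], ks["trC"]

        def driver(th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            phi = 3.0 * lam * (lnJ - 3.0 * np.log(th)) - 3.0 * mu + mu * trC / th**2
            dphi = -9.0 * lam / th - 2.0 * mu * trC / th**3
            return phi, dphi

        th = self._newton_theta(theta_n, driver, dt)
        phi, dphi = driver(th)
        sgn = np.sign(phi)
        kt = np.asarray(k_theta(th, sgn, gp))
        ktp = _k_theta_prime(th, sgn, gp)
        D = 1.0 - (ktp * phi + kt * dphi) * dt
        fac = kt * dt / D
        aC = fac[:, None, None] * (
            1.5 * lam * ks["Cinv"] + (mu / th**2)[:, None, None] * _I3
        )
        return th, aC, ac

    def _newton_theta(self, theta_n, driver, dt, tol=1e-12, max_iter=60):
        """Vectorized safeguarded Newton for the backward-Euler growth root."""
        gp = self.gp
        phi0, _ = driver(theta_n)
        sgn0 = np.sign(phi0)
        lo = np.where(sgn0 > 0.0, theta_n, gp.theta_min)
        hi = np.where(sgn0 > 0.0, gp.theta_max, theta_n)
        th = theta_n.astype(float).copy()
        active = sgn0 != 0.0
        for _ in range(max_iter):
            phi, dphi = driver(th)
            sgn = np.sign(phi)
            kt = np.asarray(k_theta(th, sgn, gp))
            ktp = _k_theta_prime(th, sgn, gp)
            R = th - theta_n - kt * phi * dt
            dR = 1.0 - (ktp * phi + kt * dphi) * dt
            conv = np.abs(R) < tol
            active = active & ~conv
            if not active.any():
                break
            hi = np.where(active & (R > 0.0), th, hi)
            lo = np.where(active & (R <= 0.0), th, lo)
            with np.errstate(divide="ignore", invalid="ignore"):
                newton = th - R / dR
            bad = ~np.isfinite(newton) | (newton < lo) | (newton > hi)
            cand = np.where(bad, 0.5 * (lo + hi), newton)
            th = np.where(active, cand, th)
        else:
            nbad = int(active.sum())
            raise LocalGrowthDivergenceError(
                f"local growth Newton failed on {nbad} element(s); "
                "try a smaller time step"
            )
        eps = 1e-12
        return np.clip(th, gp.theta_min + eps, gp.theta_max - eps)

    # ------------------------------------------------------------------
    # stresses, residual, tangent
    # ------------------------------------------------------------------

    def stress_state(self, ks: dict, theta: np.ndarray) -> dict:
        lam, mu = self.mat.lam, self.mat.mu
        th2 = theta**2
        Ceinv = th2[:, None, None] * ks["Cinv"]  # (C/theta^2)^-1
        lnJe = ks["lnJ"] - 3.0 * np.log(theta)
        coef = lam * lnJe - mu
        Seff_e = coef[:, None, None] * Ceinv + mu * _I3
        Seff = Seff_e / th2[:, None, None]
        S = Seff - (ks["J"] * ks["pf"])[:, None, None] * ks["Cinv"]
        P = np.einsum("eip,epj->eij", ks["F"], S)
        trM = 3.0 * coef + (mu / th2) * ks["trC"]  # tr(Ce Seff_e)
        return {
            "Ceinv": Ceinv, "lnJe": lnJe, "coef": coef,
            "Seff_e": Seff_e, "Seff": Seff, "S": S, "P": P, "trM": trM,
        }

    def element_residuals(
        self, ks: dict, ss: dict, theta: np.ndarray, state: SolverState, dt: float
    ) -> np.ndarray:
        """(ne, nloc) local residual vectors (internal part, no traction)."""
        ne = self.mesh.n_elements
        r = np.zeros((ne, self.nloc))
        w, B, Rg = self.w, self.B, self.Rg
        P = ss["P"]
        for a in range(3):
            ia = a * self.npn
            r[:, ia + 0] = w * (
                P[:, 0, 0] * B[:, a, 0]
                + P[:, 0, 1] * B[:, a, 1]
                + P[:, 2, 2] / (3.0 * Rg)
            )
            r[:, ia + 1] = w * (P[:, 1, 0] * B[:, a, 0] + P[:, 1, 1] * B[:, a, 1])
        if not self.mode.has_fluid:
            return r

        tp = self.tp
        JH = ks["J"][:, None, None] * ks["Cinv"]
        JH2 = JH[:, :2, :2]
        dC = ks["C"] - state.C_prev
        JHdotE = ks["J"] * np.einsum("eij,eij->e", ks["Cinv"], dC) / (2.0 * dt)
        src = 3.0 * theta**2 * (theta - state.theta) / dt
        qf = tp.kff * np.einsum("eij,ej->ei", JH2, ks["g_mf"])
        if self.mode.has_species:
            c = ks["c"]
            qf += (tp.kff * tp.bfc * c)[:, None] * np.einsum(
                "eij,ej->ei", JH2, ks["g_mc"]
            )
        mf = JHdotE - src
        for a in range(3):
            ia = a * self.npn
            r[:, ia + 2] = w * (
                np.einsum("ej,ej->e", B[:, a, :], qf) + mf / 3.0
            )
        if not self.mode.has_species:
            return r

        A1 = tp.kff * tp.bfc * c
        A2 = c * tp.dcc / tp.RT + c**2 * tp.kff * tp.bfc**2
        qc = A1[:, None] * np.einsum("eij,ej->ei", JH2, ks["g_mf"]) + A2[
            :, None
        ] * np.einsum("eij,ej->ei", JH2, ks["g_mc"])
        Jn = ks["J"] - (1.0 - tp.n0) - self.rho_bar_s * (theta**3 - 1.0)
        mc = JHdotE * c - self.rho_bar_s * src * c + Jn * (c - state.c_prev) / dt
        for a in range(3):
            ia = a * self.npn
            r[:, ia + 3] = w * (
                np.einsum("ej,ej->e", B[:, a, :], qc) + mc / 3.0
            )
        return r

    def element_tangents(
        self,
        ks: dict,
        ss: dict,
        theta: np.ndarray,
        aC: np.ndarray,
        ac: np.ndarray,
        state: SolverState,
        dt: float,
    ) -> np.ndarray:
        """(ne, nloc, nloc) consistent local tangents (analytic forward mode)."""
        ne = self.mesh.n_elements
        K = np.empty((ne, self.nloc, self.nloc))
        for col in range(self.nloc):
            a, l = divmod(col, self.npn)
            dF = None
            dmf = dgmf = dmc = dgmc = None
            if l == 0:
                dF = np.zeros((ne, 3, 3))
                dF[:, 0, 0] = self.B[:, a, 0]
                dF[:, 0, 1] = self.B[:, a, 1]
                dF[:, 2, 2] = 1.0 / (3.0 * self.Rg)
            elif l == 1:
                dF = np.zeros((ne, 3, 3))
                dF[:, 1, 0] = self.B[:, a, 0]
                dF[:, 1, 1] = self.B[:, a, 1]
            elif l == 2:
                dmf = np.full(ne, 1.0 / 3.0)
                dgmf = self.B[:, a, :]
            else:
                dmc = np.full(ne, 1.0 / 3.0)
                dgmc = self.B[:, a, :]
            K[:, :, col] = self._directional_residual(
                ks, ss, theta, aC, ac, state, dt, dF, dmf, dgmf, dmc, dgmc
            )
        return K

    def _directional_residual(
        self, ks, ss, theta, aC, ac, state, dt, dF, dmf, dgmf, dmc, dgmc
    ) -> np.ndarray:
        """Directional derivative of the local residual along one dof."""
        ne = self.mesh.n_elements
        tp, lam, mu = self.tp, self.mat.lam, self.mat.mu
        w, B, Rg = self.w, self.B, self.Rg
        F, J, C, Cinv, Finv = ks["F"], ks["J"], ks["C"], ks["Cinv"], ks["Finv"]
        pf, c = ks["pf"], ks["c"]
        th = theta
        th2 = th**2

        z3 = np.zeros((ne, 3, 3))
        zs = np.zeros(ne)
        if dF is not None:
            dC = np.einsum("eki,ekj->eij", dF, F) + np.einsum("eki,ekj->eij", F, dF)
            dJ = J * np.einsum("eij,eji->e", Finv, dF)
            dCinv = -np.einsum("eik,ekl,elj->eij", Cinv, dC, Cinv)
        else:
            dC, dJ, dCinv = z3, zs, z3

        dc = c / tp.RT * dmc if dmc is not None else zs
        dtheta = np.einsum("eij,eij->e", aC, dC) + ac * dc

        # stresses
        dlnJe = dJ / J - 3.0 * dtheta / th
        dCeinv = (2.0 * th * dtheta)[:, None, None] * Cinv + th2[:, None, None] * dCinv
        dSeff_e = (lam * dlnJe)[:, None, None] * ss["Ceinv"] + ss["coef"][
            :, None, None
        ] * dCeinv
        dSeff = dSeff_e / th2[:, None, None] - (2.0 * dtheta / th**3)[
            :, None, None
        ] * ss["Seff_e"]
        dpf = (dmf if dmf is not None else zs) + tp.RT * tp.phi_c * dc
        dS = (
            dSeff
            - (dJ * pf + J * dpf)[:, None, None] * Cinv
            - (J * pf)[:, None, None] * dCinv
        )
        dP = np.einsum("eip,epj->eij", F, dS)
        if dF is not None:
            dP = dP + np.einsum("eip,epj->eij", dF, ss["S"])

        dr = np.zeros((ne, self.nloc))
        for a in range(3):
            ia = a * self.npn
            dr[:, ia + 0] = w * (
                dP[:, 0, 0] * B[:, a, 0]
                + dP[:, 0, 1] * B[:, a, 1]
                + dP[:, 2, 2] / (3.0 * Rg)
            )
            dr[:, ia + 1] = w * (dP[:, 1, 0] * B[:, a, 0] + dP[:, 1, 1] * B[:, a, 1])
        if not self.mode.has_fluid:
            return dr

        JH2 = (J[:, None, None] * Cinv)[:, :2, :2]
        dJH2 = (dJ[:, None, None] * Cinv + J[:, None, None] * dCinv)[:, :2, :2]
        DC = C - state.C_prev
        CinvDC = np.einsum("eij,eij->e", Cinv, DC)
        dJHdotE = (
            dJ * CinvDC
            + J * (np.einsum("eij,eij->e", dCinv, DC) + np.einsum("eij,eij->e", Cinv, dC))
        ) / (2.0 * dt)
        thdot = (th - state.theta) / dt
        dsrc = (6.0 * th * thdot + 3.0 * th2 / dt) * dtheta
        dqf = tp.kff * np.einsum("eij,ej->ei", dJH2, ks["g_mf"])
        if dgmf is not None:
            dqf = dqf + tp.kff * np.einsum("eij,ej->ei", JH2, dgmf)
        if self.mode.has_species:
            gmc = ks["g_mc"]
            dqf = dqf + tp.kff * tp.bfc * (
                dc[:, None] * np.einsum("eij,ej->ei", JH2, gmc)
                + c[:, None] * np.einsum("eij,ej->ei", dJH2, gmc)
            )
            if dgmc is not None:
                dqf = dqf + (tp.kff * tp.bfc * c)[:, None] * np.einsum(
                    "eij,ej->ei", JH2, dgmc
                )
        dmf_bulk = dJHdotE - dsrc
        for a in range(3):
            ia = a * self.npn
            dr[:, ia + 2] = w * (
                np.einsum("ej,ej->e", B[:, a, :], dqf) + dmf_bulk / 3.0
            )
        if not self.mode.has_species:
            return dr

        gmf = ks["g_mf"]
        A1 = tp.kff * tp.bfc * c
        A2 = c * tp.dcc / tp.RT + c**2 * tp.kff * tp.bfc**2
        dA1 = tp.kff * tp.bfc * dc
        dA2 = (tp.dcc / tp.RT + 2.0 * c * tp.kff * tp.bfc**2) * dc
        dqc = (
            dA1[:, None] * np.einsum("eij,ej->ei", JH2, gmf)
            + A1[:, None] * np.einsum("eij,ej->ei", dJH2, gmf)
            + dA2[:, None] * np.einsum("eij,ej->ei", JH2, gmc)
            + A2[:, None] * np.einsum("eij,ej->ei", dJH2, gmc)
        )
        if dgmf is not None:
            dqc = dqc + A1[:, None] * np.einsum("eij,ej->ei", JH2, dgmf)
        if dgmc is not None:
            dqc = dqc + A2[:, None] * np.einsum("eij,ej->ei", JH2, dgmc)
        JHdotE = J * CinvDC / (2.0 * dt)
        src = 3.0 * th2 * thdot
        Jn = J - (1.0 - tp.n0) - self.rho_bar_s * (th**3 - 1.0)
        dJn = dJ - 3.0 * self.rho_bar_s * th2 * dtheta
        dmc_bulk = (
            dJHdotE * c
            + JHdotE * dc
            - self.rho_bar_s * (dsrc * c + src * dc)
            + dJn * (c - state.c_prev) / dt
            + Jn * dc / dt
        )
        for a in range(3):
            ia = a * self.npn
            dr[:, ia + 3] = w * (
                np.einsum("ej,ej->e", B[:, a, :], dqc) + dmc_bulk / 3.0
            )
        return dr

    # ------------------------------------------------------------------
    # external load, assembly, solve
    # ------------------------------------------------------------------

    def external_force(self, p: np.ndarray, load_factor: float) -> np.ndarray:
        """Follower-pressure nodal forces on boundary edges."""
        f = np.zeros(self.dofmap.n_dofs)
        coords = self.mesh.coords
        for tr in self.bc.tractions:
            n0, n1 = tr.nodes
            h = abs(coords[n1, 1] - coords[n0, 1])
            uR = 0.5 * (p[n0 * self.npn] + p[n1 * self.npn])
            r_cur = 0.5 * (coords[n0, 0] + coords[n1, 0]) + uR
            pres = tr.pressure * (load_factor if tr.ramp else 1.0)
            fR = pres * 2.0 * np.pi * r_cur * h / 2.0
            f[n0 * self.npn] += fR
            f[n1 * self.npn] += fR
        return f

    def residual_vector(
        self,
        p: np.ndarray,
        theta: np.ndarray,
        state: SolverState,
        dt: float,
        load_factor: float = 1.0,
        ks: dict | None = None,
    ) -> np.ndarray:
        ks = ks or self.kin_state(p)
        ss = self.stress_state(ks, theta)
        rloc = self.element_residuals(ks, ss, theta, state, dt)
        R = np.zeros(self.dofmap.n_dofs)
        np.add.at(R, self.gdofs.ravel(), rloc.ravel())
        return R - self.external_force(p, load_factor)

    def assemble(
        self,
        p: np.ndarray,
        state: SolverState,
        dt: float,
        load_factor: float = 1.0,
        growth_active: bool = False,
    ) -> SolverState:
        """Assemble K_hat and Psi at the given primary vector (Dirichlet rows
        eliminated), returning an updated SolverState snapshot."""
        ks = self.kin_state(p)
        theta, aC, ac = self.update_theta(ks, state.theta, dt, growth_active)
        ss = self.stress_state(ks, theta)
        rloc = self.element_residuals(ks, ss, theta, state, dt)
        R = np.zeros(self.dofmap.n_dofs)
        np.add.at(R, self.gdofs.ravel(), rloc.ravel())
        R -= self.external_force(p, load_factor)
        kloc = self.element_tangents(ks, ss, theta, aC, ac, state, dt)
        K = sp.coo_matrix(
            (kloc.ravel(), (self._rows, self._cols)),
            shape=(self.dofmap.n_dofs,) * 2,
        ).tocsr()
        snap = SolverState(
            p=p.copy(), theta=theta, theta_dot=(theta - state.theta) / dt,
            C_prev=state.C_prev, c_prev=state.c_prev, t=state.t,
            K_hat=K, Psi=R, Psi_g=0.0,
        )
        return snap

    def _field_slices(self) -> dict[str, np.ndarray]:
        out = {"u": self.dofmap.displacement_dofs()}
        if self.mode.has_fluid:
            out["f"] = self.dofmap.field_dofs("mu_f")
        if self.mode.has_species:
            out["c"] = self.dofmap.field_dofs("mu_c")
        return out

    def _solve_linear(self, K: sp.csr_matrix, rhs: np.ndarray) -> np.ndarray:
        free = self._free
        Kff = K[free][:, free].tocsr()
        d = np.abs(Kff.diagonal())
        d[d == 0.0] = 1.0
        s = 1.0 / np.sqrt(d)
        D = sp.diags(s)
        x = spla.spsolve((D @ Kff @ D).tocsc(), s * rhs[free])
        return s * x

    def time_step(
        self,
        state: SolverState,
        dt: float,
        load_factor: float = 1.0,
        growth_active: bool = False,
    ) -> tuple[SolverState, StepDiagnostics]:
        """Advance one step: predictor (first linearized solve from the
        previous state) plus backward-Euler Newton corrections with nested
        per-element growth updates."""
        if dt <= 0.0:
            raise ValueError("dt must be positive")
        p = state.p.copy()
        for bc in self.bc.dirichlet:
            p[bc.dofs] = bc.applied(load_factor)

        fields = self._field_slices()
        free_mask = ~self._fixed
        ref = None
        theta = state.theta.copy()
        it = 0
        res_norm = np.inf
        for it in range(1, self.max_iter + 1):
            ks = self.kin_state(p)
            theta, aC, ac = self.update_theta(ks, state.theta, dt, growth_active)
            ss = self.stress_state(ks, theta)
            rloc = self.element_residuals(ks, ss, theta, state, dt)
            R = np.zeros(self.dofmap.n_dofs)
            np.add.at(R, self.gdofs.ravel(), rloc.ravel())
            R -= self.external_force(p, load_factor)
            Rm = np.where(free_mask, R, 0.0)
            norms = {k: np.linalg.norm(Rm[v]) for k, v in fields.items()}
            if ref is None:
                ref = {k: max(v, 0.0) for k, v in norms.items()}
            res_norm = max(
                (norms[k] / ref[k] if ref[k] > 0.0 else 0.0) for k in norms
            )
            if all(
                norms[k] <= self.tol_r * ref[k] or ref[k] == 0.0 for k in norms
            ):
                break
            kloc = self.element_tangents(ks, ss, theta, aC, ac, state, dt)
            K = sp.coo_matrix(
                (kloc.ravel(), (self._rows, self._cols)),
                shape=(self.dofmap.n_dofs,) * 2,
            ).tocsr()
            dp = self._solve_linear(K, -R)
            dp = self._safeguarded_update(p, dp)
            if np.linalg.norm(dp) <= self.tol_p * (1.0 + np.linalg.norm(p)):
                ks = self.kin_state(p)
                theta, aC, ac = self.update_theta(ks, state.theta, dt, growth_active)
                break
        else:
            raise StepFailureError(
                f"no convergence in {self.max_iter} iterations "
                f"(last relative residual {res_norm:.3e}); the time step is "
                "probably too large"
            )

        ks = self.kin_state(p)
        n = self._check_admissible(ks, theta)
        new = SolverState(
            p=p,
            theta=theta,
            theta_dot=(theta - state.theta) / dt,
            C_prev=ks["C"],
            c_prev=ks["c"].copy(),
            t=state.t + dt,
            Psi_g=0.0,
        )
        diag = StepDiagnostics(
            t=new.t,
            iterations=it,
            residual_norm=res_norm,
            theta_min=float(theta.min()),
            theta_max=float(theta.max()),
            porosity_min=float(n.min()),
            porosity_max=float(n.max()),
        )
        return new, diag

    def _safeguarded_update(self, p: np.ndarray, dp: np.ndarray) -> np.ndarray:
        """Apply the Newton increment to ``p`` in place, damped if needed.

        The chemical potential is exponential in the concentration, so a raw
        Newton step can overshoot by many e-folds early in a step; the
        increment is capped at two e-folds of concentration per iteration and
        halved until the updated state is kinematically admissible.
        """
        scale = 1.0
        if self._free_mu_c_local.size:
            dmax = np.abs(dp[self._free_mu_c_local]).max()
            cap = 2.0 * self.tp.RT
            if dmax > cap:
                scale = cap / dmax
        for _ in range(12):
            trial = p.copy()
            trial[self._free] += scale * dp
            try:
                self.kin_state(trial)
            except AdmissibilityError:
                scale *= 0.5
                continue
            p[self._free] += scale * dp
            return scale * dp
        raise StepFailureError(
            "Newton increment could not be damped to an admissible state"
        )

    def _check_admissible(self, ks: dict, theta: np.ndarray) -> np.ndarray:
        ok, upper, lower = check_admissibility(
            ks["J"], theta, self.tp.n0, self.rho_bar_s
        )
        if not np.all(ok):
            e = int(np.flatnonzero(~ok)[0])
            raise AdmissibilityError(
                f"element {e}: theta={theta[e]:.6f} outside admissible "
                f"({lower if np.ndim(lower)==0 else lower[e]:.6f}, "
                f"{upper[e]:.6f}) — porosity left (0, 1)"
            )
        return np.asarray(
            porosity_after_growth(ks["J"], theta, self.tp.n0, self.rho_bar_s)
        )

    # ------------------------------------------------------------------
    # observables
    # ------------------------------------------------------------------

    def gauss_outputs(self, state: SolverState) -> dict[str, np.ndarray]:
        """Per-element secondary fields at the Gauss points."""
        ks = self.kin_state(state.p)
        ss = self.stress_state(ks, state.theta)
        n = np.asarray(
            porosity_after_growth(ks["J"], state.theta, self.tp.n0, self.rho_bar_s)
        )
        sig_eff = (
            np.einsum("eip,epq,ejq->eij", ks["F"], ss["Seff"], ks["F"])
            / ks["J"][:, None, None]
        )
        sig = (
            np.einsum("eip,epq,ejq->eij", ks["F"], ss["S"], ks["F"])
            / ks["J"][:, None, None]
        )
        return {
            "R_gp": self.Rg + np.add.reduce(
                state.p[self.conn * self.npn], axis=1
            ) / 3.0,
            "theta": state.theta.copy(),
            "J": ks["J"],
            "n": n,
            "pf": ks["pf"],
            "c": ks["c"],
            "trM": ss["trM"],
            "Seff_rr": ss["Seff"][:, 0, 0],
            "Seff_zz": ss["Seff"][:, 1, 1],
            "Seff_hoop": ss["Seff"][:, 2, 2],
            "sigma_eff_hoop": sig_eff[:, 2, 2],
            "sigma_hoop": sig[:, 2, 2],
        }

    def split_stiffness_dissipation(
        self, p: np.ndarray, state: SolverState, dt: float, growth_active: bool = False
    ) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Split the consistent Jacobian A(dt) = K_hat + C_hat/dt.

        The backward-difference rates make the Jacobian affine in 1/dt at a
        fixed state, so two assemblies at dt and 2 dt separate the stiffness
        from the dissipation contribution.
        """
        A1 = self.assemble(p, state, dt, growth_active=growth_active).K_hat
        A2 = self.assemble(p, state, 2.0 * dt, growth_active=growth_active).K_hat
        C_hat = (2.0 * dt) * (A1 - A2)
        K_hat = 2.0 * A2 - A1
        return K_hat.tocsr(), C_hat.tocsr()
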