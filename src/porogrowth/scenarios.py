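"""Scenario presets and the run driver for the artery benchmarks.

Three families of test problems on the annular artery wall (ri = 1 mm,
ro = 1.25 mm, internal pressure 100 mmHg):

* ``rigid-time``    — time-driven growth of a rigid porohyperelastic
  cylinder, run for both a solid-only and a solid/fluid mass source;
* ``stress-he`` / ``stress-mphets`` — stress-driven growth of a hyperelastic
  vs. a full mixture model on identical 320-element meshes;
* ``conc-largeP`` / ``conc-smallP`` — concentration-driven growth/resorption
  at two species diffusivities (two Peclet-like numbers beta = kff*bfc/dcc).

Every preset field can be overridden from a flat ``key = value`` text
configuration file or programmatically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly_solver import (
    BoundaryConditions,
    DirichletBC,
    FEModel,
    TractionBC,
)
from .constitutive import (
    MMHG_TO_PA,
    MaterialParams,
    TransportParams,
    partition_concentration,
    potentials_forward,
)
from .growth import GrowthLawParams
from .mesh_axisym import Mesh, ModelMode, generate_strip_mesh, nodal_average

__all__ = [
    "ScenarioConfig",
    "RunOutputs",
    "PRESETS",
    "preset_config",
    "load_config",
    "run_scenario",
    "run_preset",
]

log = logging.getLogger("porogrowth")

STRIP_HEIGHT = 2.5e-5  # [m]; results are Z-independent under plane strain


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one run (geometry, material, growth, stepping)."""

    name: str = "custom"
    model_mode: str = "MPHETS"
    n_radial: int = 60
    ri: float = 1e-3
    ro: float = 1.25e-3
    strip_height: float = STRIP_HEIGHT
    Pi_mmHg: float = 100.0

    # material / transport (defaults: porcine coronary artery data set)
    C10: float = 1e6
    D1: float = 5.5e-9
    kff: float = 2e-14
    bfc: float = 6e-4
    dcc: float = 4.55e-14
    gamma_mat: float = 0.5
    phi_c: float = 0.0
    n0: float = 0.5

    # growth
    growth_law: str = "time_linear"
    alpha: float = 8e-4
    tau_plus: float = 1.0
    tau_minus: float = 1.0
    gamma_plus: float = 2.0
    gamma_minus: float = 3.0
    theta_max: float = 1.2
    theta_min: float = 0.8
    c_thresh: float = 0.0
    growth_case: str = "solid_only"
    rho_bar_s: float = 1.0
    growth_start: str = "after_consolidation"  # or "simultaneous"

    # stepping
    n_load: int = 5
    n_consol: int = 1
    n_growth: int = 300
    dt: float = 0.5

    # constraints
    rigid: bool = False
    plane_strain: bool = True

    # bath coupling
    c_inner_bath: float = 6.40e-3
    c_outer_bath: float = 6.40e-4
    partition_coefficient: float = 0.5

    # output
    output_every: int = 10

    @property
    def mode(self) -> ModelMode:
        return ModelMode(self.model_mode)

    @property
    def Pi(self) -> float:
        return self.Pi_mmHg * MMHG_TO_PA

    @property
    def material(self) -> MaterialParams:
        return MaterialParams(self.C10, self.D1)

    @property
    def c_inner(self) -> float:
        return partition_concentration(self.c_inner_bath, self.partition_coefficient)

    @property
    def c_outer(self) -> float:
        return partition_concentration(self.c_outer_bath, self.partition_coefficient)

    @property
    def transport(self) -> TransportParams:
        # chemical-potential datum anchored below the lowest concentration in
        # the problem so the log stays well-defined; datum-invariant results.
        if self.mode.has_species:
            c_floor = 0.1 * min(self.c_inner, self.c_outer)
            mu0c = -8.31 * 310.0 * math.log(self.gamma_mat * c_floor)
        else:
            mu0c = 0.0
        return TransportParams(
            kff=self.kff,
            bfc=self.bfc,
            dcc=self.dcc,
            n0=self.n0,
            phi_c=self.phi_c,
            gamma_mat=self.gamma_mat,
            p0o=0.0,
            mu0c=mu0c,
        )

    @property
    def growth_params(self) -> GrowthLawParams:
        return GrowthLawParams(
            law=self.growth_law,
            alpha=self.alpha,
            tau_plus=self.tau_plus,
            tau_minus=self.tau_minus,
            gamma_plus=self.gamma_plus,
            gamma_minus=self.gamma_minus,
            theta_max=self.theta_max,
            theta_min=self.theta_min,
            c_thresh=self.c_thresh,
        )

    @property
    def beta(self) -> float:
        """Peclet-like number kff*bfc/dcc."""
        return self.kff * self.bfc / self.dcc


PRESETS: dict[str, ScenarioConfig] = {
    "rigid-time": ScenarioConfig(
        name="rigid-time",
        model_mode="PHE",
        n_radial=60,
        growth_law="time_linear",
        alpha=8e-4,
        growth_case="solid_only",
        rho_bar_s=1.0,
        growth_start="after_consolidation",
        n_load=0,
        n_consol=10,
        n_growth=300,
        dt=0.5,
        rigid=True,
        output_every=10,
    ),
    "stress-mphets": ScenarioConfig(
        name="stress-mphets",
        model_mode="MPHETS",
        n_radial=160,
        growth_law="stress",
        tau_plus=1e11,
        tau_minus=1e11,
        theta_max=1.2,
        theta_min=0.8,
        gamma_plus=2.0,
        gamma_minus=3.0,
        growth_case="solid_only",
        rho_bar_s=1.0,
        growth_start="simultaneous",
        n_load=5,
        n_consol=1,
        n_growth=1000,
        dt=50.0,
        rigid=False,
        output_every=50,
    ),
    "conc-largeP": ScenarioConfig(
        name="conc-largeP",
        model_mode="MPHETS",
        n_radial=80,
        growth_law="concentration",
        tau_plus=200.0,
        tau_minus=200.0,
        c_thresh=0.009185,
        theta_max=1.2,
        theta_min=0.8,
        gamma_plus=2.0,
        gamma_minus=3.0,
        growth_case="solid_only",
        rho_bar_s=1.0,
        growth_start="simultaneous",
        n_load=5,
        n_consol=0,
        n_growth=2000,
        dt=50.0,
        dcc=4.55e-14,
        output_every=100,
    ),
}
PRESETS["stress-he"] = replace(PRESETS["stress-mphets"], name="stress-he",
                              model_mode="HE")
PRESETS["conc-smallP"] = replace(PRESETS["conc-largeP"], name="conc-smallP",
                                 dcc=4.55e-12)
PRESETS["rigid-time-solidfluid"] = replace(
    PRESETS["rigid-time"], name="rigid-time-solidfluid",
    growth_case="solid_fluid", rho_bar_s=0.5,
)


def preset_config(name: str, **overrides) -> ScenarioConfig:
    if name not in PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def load_config(path: str | Path, base: str | None = None) -> ScenarioConfig:
    """Parse a flat ``key = value`` text file (optionally over a preset).

    Lines starting with ``#`` and blank lines are ignored.  A ``preset`` key
    selects the base preset; remaining keys override its fields.
    """
    text = Path(path).read_text()
    raw: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        raw[key] = val
    base = raw.pop("preset", base)
    cfg = PRESETS[base] if base else ScenarioConfig()
    valid = {f.name: f.type for f in fields(ScenarioConfig)}
    overrides = {}
    for key, val in raw.items():
        if key not in valid:
            raise KeyError(f"unknown config key {key!r}")
        cur = getattr(cfg, key)
        if isinstance(cur, bool):
            overrides[key] = val.lower() in ("1", "true", "yes", "on")
        elif isinstance(cur, int):
            overrides[key] = int(val)
        elif isinstance(cur, float):
            overrides[key] = float(val)
        else:
            overrides[key] = val
    return replace(cfg, **overrides)


@dataclass
class RunOutputs:
    """Time-series tables of one run plus the mesh and final model state."""

    config: ScenarioConfig
    mesh: Mesh
    nodal: pd.DataFrame
    gauss: pd.DataFrame
    summary: pd.DataFrame
    beta: float
    model: FEModel
    final_state: object


def _build_bcs(cfg: ScenarioConfig, mesh: Mesh, model_mode: ModelMode,
               tp: TransportParams) -> BoundaryConditions:
    npn = model_mode.ndof_per_node
    nn = mesh.n_nodes
    dir_bcs: list[DirichletBC] = []
    tractions: list[TractionBC] = []
    all_nodes = np.arange(nn)
    inner = mesh.boundary_sets["inner"]
    outer = mesh.boundary_sets["outer"]

    if cfg.rigid:
        dofs = np.r_[all_nodes * npn, all_nodes * npn + 1]
        dir_bcs.append(DirichletBC(dofs, np.zeros(dofs.size), ramp=False))
    else:
        if cfg.plane_strain:
            dofs = all_nodes * npn + 1
            dir_bcs.append(DirichletBC(dofs, np.zeros(dofs.size), ramp=False))
        tractions.append(
            TractionBC(tuple(int(n) for n in mesh.boundary_sets["inner_edge"]),
                       cfg.Pi, ramp=True)
        )

    if model_mode.has_fluid:
        # internal pressure also enters as the pore-pressure (fluid potential)
        # value at the inner face; outer face drains at pf = 0
        c_in = cfg.c_inner if model_mode.has_species else 1.0
        c_out = cfg.c_outer if model_mode.has_species else 1.0
        mu_f_in, _ = potentials_forward(cfg.Pi, c_in, tp)
        mu_f_in_rest, _ = potentials_forward(0.0, c_in, tp)
        mu_f_out, _ = potentials_forward(0.0, c_out, tp)
        dir_bcs.append(
            DirichletBC(inner * npn + 2, np.full(inner.size, float(mu_f_in)),
                        ramp=True, rest=float(mu_f_in_rest))
        )
        dir_bcs.append(
            DirichletBC(outer * npn + 2, np.full(outer.size, float(mu_f_out)),
                        ramp=False)
        )
    if model_mode.has_species:
        _, mu_c_in = potentials_forward(0.0, cfg.c_inner, tp)
        _, mu_c_out = potentials_forward(0.0, cfg.c_outer, tp)
        dir_bcs.append(
            DirichletBC(inner * npn + 3, np.full(inner.size, float(mu_c_in)),
                        ramp=False)
        )
        dir_bcs.append(
            DirichletBC(outer * npn + 3, np.full(outer.size, float(mu_c_out)),
                        ramp=False)
        )
    return BoundaryConditions(dirichlet=dir_bcs, tractions=tractions)


def build_model(cfg: ScenarioConfig, transport_override: TransportParams | None = None) -> FEModel:
    mesh = generate_strip_mesh(cfg.ri, cfg.ro, cfg.n_radial, cfg.strip_height)
    tp = transport_override if transport_override is not None else cfg.transport
    bc = _build_bcs(cfg, mesh, cfg.mode, tp)
    return FEModel(
        mesh=mesh,
        mode=cfg.mode,
        mat=cfg.material,
        tp=tp,
        growth_params=cfg.growth_params,
        bc=bc,
        rho_bar_s=cfg.rho_bar_s,
        growth_case=cfg.growth_case,
    )


def run_scenario(cfg: ScenarioConfig, progress: bool = False) -> RunOutputs:
    """Run all phases (loading, consolidation, growth) of one scenario."""
    model = build_model(cfg)
    mesh = model.mesh
    c0 = cfg.c_outer if cfg.mode.has_species else None
    state = model.initial_state(c0=c0)

    phases: list[tuple[str, int, float, bool]] = []
    for i in range(cfg.n_load):
        phases.append(("loading", i, (i + 1) / cfg.n_load, False))
    for i in range(cfg.n_consol):
        phases.append(("consolidation", i, 1.0, False))
    for i in range(cfg.n_growth):
        phases.append(("growth", i, 1.0, True))

    nodal_rows, gauss_rows, summary_rows = [], [], []
    conn = mesh.connectivity
    coords = mesh.coords
    inner_node = int(mesh.boundary_sets["inner"][0])
    outer_node = int(mesh.boundary_sets["outer"][0])
    npn = model.npn

    def record_fields(t: float) -> None:
        go = model.gauss_outputs(state)
        nodal = pd.DataFrame(
            {
                "t[s]": t,
                "node": np.arange(mesh.n_nodes),
                "R[m]": coords[:, 0],
                "Z[m]": coords[:, 1],
                "u_R[m]": state.p[np.arange(mesh.n_nodes) * npn],
                "u_Z[m]": state.p[np.arange(mesh.n_nodes) * npn + 1],
            }
        )
        if cfg.mode.has_fluid:
            nodal["mu_f[Pa]"] = state.p[np.arange(mesh.n_nodes) * npn + 2]
        if cfg.mode.has_species:
            nodal["mu_c[J/mol]"] = state.p[np.arange(mesh.n_nodes) * npn + 3]
        nodal["trM_avg[Pa]"] = nodal_average(go["trM"], mesh)
        nodal_rows.append(nodal)
        gauss = pd.DataFrame({"t[s]": t, "element": np.arange(mesh.n_elements)})
        for key, unit in (
            ("R_gp", "m"), ("theta", "-"), ("J", "-"), ("n", "-"),
            ("pf", "Pa"), ("c", "mol/m^3"), ("trM", "Pa"),
            ("Seff_rr", "Pa"), ("Seff_zz", "Pa"), ("Seff_hoop", "Pa"),
            ("sigma_eff_hoop", "Pa"), ("sigma_hoop", "Pa"),
        ):
            gauss[f"{key}[{unit}]"] = go[key]
        gauss_rows.append(gauss)

    def record_summary(t: float, phase: str, diag) -> None:
        go = model.gauss_outputs(state)
        trM_nodes = nodal_average(go["trM"], mesh)
        thickness = (
            coords[outer_node, 0] + state.p[outer_node * npn]
            - coords[inner_node, 0] - state.p[inner_node * npn]
        )
        summary_rows.append(
            {
                "t[s]": t,
                "phase": phase,
                "iterations": 0 if diag is None else diag.iterations,
                "residual": 0.0 if diag is None else diag.residual_norm,
                "thickness[m]": thickness,
                "trM_min[Pa]": float(go["trM"].min()),
                "trM_max[Pa]": float(go["trM"].max()),
                "trM_avg_min[Pa]": float(trM_nodes.min()),
                "trM_avg_max[Pa]": float(trM_nodes.max()),
                "theta_min[-]": float(state.theta.min()),
                "theta_max[-]": float(state.theta.max()),
                "n_min[-]": float(go["n"].min()),
                "n_max[-]": float(go["n"].max()),
            }
        )

    record_fields(0.0)
    record_summary(0.0, "initial", None)
    prev_phase = None
    n_steps = len(phases)
    for k, (phase, i, factor, grow) in enumerate(phases):
        if phase != prev_phase and prev_phase is not None:
            log.info("%s: entering %s phase at t=%.6g s", cfg.name, phase, state.t)
        prev_phase = phase
        state, diag = model.time_step(
            state, cfg.dt, load_factor=factor, growth_active=grow
        )
        last_of_phase = (k + 1 == n_steps) or (phases[k + 1][0] != phase)
        record_summary(state.t, phase, diag)
        if (i + 1) % cfg.output_every == 0 or last_of_phase:
            record_fields(state.t)
        if progress and (k % 100 == 0 or last_of_phase):
            log.info(
                "%s: t=%.6g s phase=%s it=%d res=%.2e theta=[%.4f, %.4f] "
                "n=[%.4f, %.4f]",
                cfg.name, state.t, phase, diag.iterations, diag.residual_norm,
                diag.theta_min, diag.theta_max, diag.porosity_min,
                diag.porosity_max,
            )

    return RunOutputs(
        config=cfg,
        mesh=mesh,
        nodal=pd.concat(nodal_rows, ignore_index=True),
        gauss=pd.concat(gauss_rows, ignore_index=True),
        summary=pd.DataFrame(summary_rows),
        beta=cfg.beta,
        model=model,
        final_state=state,
    )


def run_preset(name: str, progress: bool = False, **overrides) -> dict[str, RunOutputs]:
    """Run a named preset; ``rigid-time`` runs both mass-source variants."""
    if name == "rigid-time":
        return {
            "solid_only": run_scenario(preset_config("rigid-time", **overrides),
                                       progress=progress),
            "solid_fluid": run_scenario(
                preset_config("rigid-time-solidfluid", **overrides),
                progress=progress,
            ),
        }
    return {name: run_scenario(preset_config(name, **overrides), progress=progress)}
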