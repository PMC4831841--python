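"""CSV / legacy-VTK output of run histories.

Columns carry their units in brackets (e.g. ``u_R[m]``); CSV files are plain
RFC-4180 tables that round-trip through :func:`read_outputs`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_axisym import Mesh

__all__ = ["write_outputs", "read_outputs", "write_vtk", "write_mesh_csv"]

_TABLES = ("nodal", "gauss", "summary")


def write_outputs(run, outdir: str | Path, formats: tuple[str, ...] = ("csv",)) -> list[Path]:
    """Write the tables of a RunOutputs to ``outdir``.

    ``csv`` writes nodal.csv / gauss.csv / summary.csv; ``vtk`` additionally
    writes one legacy-VTK snapshot per stored output time.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "csv" in formats:
        for name in _TABLES:
            path = outdir / f"{name}.csv"
            getattr(run, name).to_csv(path, index=False)
            written.append(path)
    if "vtk" in formats:
        times = sorted(run.gauss["t[s]"].unique())
        for k, t in enumerate(times):
            g = run.gauss[run.gauss["t[s]"] == t]
            nd = run.nodal[run.nodal["t[s]"] == t]
            cell_data = {
                c: g[c].to_numpy()
                for c in g.columns
                if c not in ("t[s]", "element")
            }
            point_data = {
                c: nd[c].to_numpy()
                for c in nd.columns
                if c not in ("t[s]", "node", "R[m]", "Z[m]")
            }
            path = outdir / f"snapshot_{k:04d}.vtk"
            write_vtk(run.mesh, path, point_data=point_data, cell_data=cell_data,
                      title=f"t={t:g}s")
            written.append(path)
    return written


def read_outputs(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the CSV tables written by :func:`write_outputs`."""
    outdir = Path(outdir)
    return {name: pd.read_csv(outdir / f"{name}.csv") for name in _TABLES}


def write_mesh_csv(mesh: Mesh, outdir: str | Path) -> tuple[Path, Path]:
    """Write the reference mesh as node and element CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "node": [nd.id for nd in mesh.nodes],
            "R[m]": [nd.R for nd in mesh.nodes],
            "Z[m]": [nd.Z for nd in mesh.nodes],
        }
    )
    elems = pd.DataFrame(
        {
            "element": np.arange(mesh.n_elements),
            "n0": mesh.connectivity[:, 0],
            "n1": mesh.connectivity[:, 1],
            "n2": mesh.connectivity[:, 2],
            "area[m^2]": [el.area for el in mesh.elements],
            "gauss_R[m]": [el.gauss_R for el in mesh.elements],
        }
    )
    npath, epath = outdir / "mesh_nodes.csv", outdir / "mesh_elements.csv"
    nodes.to_csv(npath, index=False)
    elems.to_csv(epath, index=False)
    return npath, epath


def write_vtk(
    mesh: Mesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "porogrowth snapshot",
) -> Path:
    """Write the mesh as a legacy-VTK (ASCII) unstructured grid of triangles."""
    path = Path(path)
    coords = mesh.coords
    conn = mesh.connectivity
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for R, Z in coords:
        lines.append(f"{R:.12g} {Z:.12g} 0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for tri in conn:
        lines.append("3 " + " ".join(str(int(i)) for i in tri))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)  # VTK_TRIANGLE
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, vals in point_data.items():
            safe = name.replace(" ", "_").replace("[", "_").replace("]", "")
            lines.append(f"SCALARS {safe} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.12g}" for v in np.asarray(vals, dtype=float))
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        for name, vals in cell_data.items():
            safe = name.replace(" ", "_").replace("[", "_").replace("]", "")
            lines.append(f"SCALARS {safe} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.12g}" for v in np.asarray(vals, dtype=float))
    path.write_text("\n".join(lines) + "\n")
    return path
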