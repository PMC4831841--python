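"""Axisymmetric annular-strip triangle meshes.

The cylinder wall (an annulus in the R-Z reference plane) is meshed as a
strip one quad thick in Z: ``n_radial`` quads, each split along a consistent
diagonal into two counter-clockwise linear triangles.  Primary variables live
at the nodes; every element carries a single Gauss point at its centroid, so
the axisymmetric volume weight of an element is ``2*pi*gauss_R*area``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Node",
    "Element",
    "Mesh",
    "DofMap",
    "ModelMode",
    "generate_strip_mesh",
    "element_geometry",
    "nodal_average",
    "InvalidGeometryError",
    "DegenerateElementError",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive mesh dimensions."""


class DegenerateElementError(ValueError):
    """Raised for zero or negatively oriented triangles."""


class ModelMode(str, Enum):
    """Which primary fields are carried at the nodes.

    HE: displacement only (hyperelastic solid).
    PHE: displacement + fluid potential (porohyperelastic).
    MPHETS: displacement + fluid potential + chemical potential.
    """

    HE = "HE"
    PHE = "PHE"
    MPHETS = "MPHETS"

    @property
    def ndof_per_node(self) -> int:
        return {ModelMode.HE: 2, ModelMode.PHE: 3, ModelMode.MPHETS: 4}[self]

    @property
    def has_fluid(self) -> bool:
        return self is not ModelMode.HE

    @property
    def has_species(self) -> bool:
        return self is ModelMode.MPHETS


@dataclass(frozen=True)
class Node:
    id: int
    R: float  # radial reference coordinate [m], R > 0
    Z: float  # axial reference coordinate [m]


@dataclass(frozen=True)
class Element:
    node_ids: tuple[int, int, int]  # counter-clockwise
    area: float  # reference-plane area [m^2]
    gauss_R: float  # centroid radius of the single integration point [m]


@dataclass
class Mesh:
    nodes: list[Node]
    elements: list[Element]
    boundary_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def coords(self) -> np.ndarray:
        """(n_nodes, 2) array of (R, Z)."""
        return np.array([[nd.R, nd.Z] for nd in self.nodes])

    @property
    def connectivity(self) -> np.ndarray:
        """(n_elements, 3) array of node ids."""
        return np.array([el.node_ids for el in self.elements], dtype=int)

    def reference_volume(self) -> float:
        """Total axisymmetric reference volume 2*pi*sum(gauss_R*area)."""
        return float(
            2.0 * np.pi * sum(el.gauss_R * el.area for el in self.elements)
        )


@dataclass
class DofMap:
    """Node-major numbering of primary degrees of freedom.

    Per node the local order is (u_R, u_Z[, mu_f[, mu_c]]) depending on the
    model mode; global dof of (node, local) is ``node*ndof_per_node + local``.
    """

    mode: ModelMode
    n_nodes: int

    @property
    def ndof_per_node(self) -> int:
        return self.mode.ndof_per_node

    @property
    def n_dofs(self) -> int:
        return self.n_nodes * self.ndof_per_node

    def dof(self, node: int | np.ndarray, local: int) -> np.ndarray:
        return np.asarray(node) * self.ndof_per_node + local

    def displacement_dofs(self) -> np.ndarray:
        nodes = np.arange(self.n_nodes)
        return np.sort(np.r_[self.dof(nodes, 0), self.dof(nodes, 1)])

    def field_dofs(self, name: str) -> np.ndarray:
        """All global dofs of one field: 'u_R', 'u_Z', 'mu_f' or 'mu_c'."""
        local = {"u_R": 0, "u_Z": 1, "mu_f": 2, "mu_c": 3}[name]
        if local >= self.ndof_per_node:
            raise KeyError(f"field {name!r} not present in mode {self.mode}")
        return self.dof(np.arange(self.n_nodes), local)


def generate_strip_mesh(
    ri: float, ro: float, n_radial: int, strip_height: float
) -> Mesh:
    """Mesh the annulus [ri, ro] as a one-quad-thick strip of triangles.

    Produces ``2*n_radial`` elements and ``2*(n_radial+1)`` nodes.  Nodes are
    numbered radially then axially (bottom row Z=0 first).  Boundary sets:
    ``inner``/``outer`` node sets at R=ri / R=ro, ``bottom``/``top`` at
    Z=0 / Z=strip_height, and ``inner_edge``/``outer_edge`` as single
    (node, node) edges for traction application.
    """
    if not (0.0 < ri < ro) or strip_height <= 0.0:
        raise InvalidGeometryError(
            f"need 0 < ri < ro and strip_height > 0, got ri={ri}, ro={ro}, "
            f"strip_height={strip_height}"
        )
    if n_radial < 1:
        raise InvalidGeometryError(f"n_radial must be >= 1, got {n_radial}")

    ncol = n_radial + 1
    R = np.linspace(ri, ro, ncol)
    nodes = [Node(i, float(R[i]), 0.0) for i in range(ncol)]
    nodes += [Node(ncol + i, float(R[i]), float(strip_height)) for i in range(ncol)]

    coords = np.array([[nd.R, nd.Z] for nd in nodes])
    elements: list[Element] = []
    for i in range(n_radial):
        bl, br = i, i + 1
        tl, tr = ncol + i, ncol + i + 1
        for tri in ((bl, br, tr), (bl, tr, tl)):
            elements.append(_make_element(tri, coords))

    bottom = np.arange(ncol)
    top = ncol + np.arange(ncol)
    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        boundary_sets={
            "inner": np.array([0, ncol]),
            "outer": np.array([ncol - 1, 2 * ncol - 1]),
            "bottom": bottom,
            "top": top,
            "inner_edge": np.array([0, ncol]),
            "outer_edge": np.array([ncol - 1, 2 * ncol - 1]),
        },
    )
    return mesh


def _make_element(tri: tuple[int, int, int], coords: np.ndarray) -> Element:
    x = coords[list(tri)]
    area = 0.5 * (
        (x[1, 0] - x[0, 0]) * (x[2, 1] - x[0, 1])
        - (x[2, 0] - x[0, 0]) * (x[1, 1] - x[0, 1])
    )
    if area <= 0.0:
        raise DegenerateElementError(f"triangle {tri} has signed area {area}")
    gauss_R = float(x[:, 0].mean())
    return Element(tuple(int(t) for t in tri), float(area), gauss_R)


def element_geometry(
    elem: Element, coords: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Area, constant shape-function gradients and Gauss radius of a triangle.

    Returns ``(area, dN, gauss_R)`` where ``dN`` is (3, 2): row a holds
    (dN_a/dR, dN_a/dZ) of the linear shape function of local node a.  The
    three gradients sum to the zero vector (partition of unity).
    """
    x = coords[list(elem.node_ids)]
    area = 0.5 * (
        (x[1, 0] - x[0, 0]) * (x[2, 1] - x[0, 1])
        - (x[2, 0] - x[0, 0]) * (x[1, 1] - x[0, 1])
    )
    if area <= 0.0:
        raise DegenerateElementError(
            f"triangle {elem.node_ids} has signed area {area}"
        )
    # dN_a/dR = (Z_b - Z_c)/(2A), dN_a/dZ = (R_c - R_b)/(2A) cyclically
    dN = np.empty((3, 2))
    for a in range(3):
        b, c = (a + 1) % 3, (a + 2) % 3
        dN[a, 0] = (x[b, 1] - x[c, 1]) / (2.0 * area)
        dN[a, 1] = (x[c, 0] - x[b, 0]) / (2.0 * area)
    return float(area), dN, float(x[:, 0].mean())


def nodal_average(element_values: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Average per-element scalars to nodes (mean over adjacent elements)."""
    vals = np.asarray(element_values, dtype=float)
    if vals.shape != (mesh.n_elements,):
        raise ValueError(
            f"expected one value per element ({mesh.n_elements}), got shape "
            f"{vals.shape}"
        )
    acc = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    conn = mesh.connectivity
    for a in range(3):
        np.add.at(acc, conn[:, a], vals)
        np.add.at(cnt, conn[:, a], 1.0)
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    return out
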