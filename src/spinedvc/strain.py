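"""Hexahedral mesh extraction and small-strain differentiation.

The registration grid becomes an 8-node hexahedral mesh restricted to
cells having at least one node inside the evaluation VOI ("voxel
detection"); nodal displacements are differentiated through the
trilinear shape functions into the six small-strain components
(εxx, εyy, εzz, γxy, γyz, γxz, engineering shear), reported in
microstrain.  Because the basis is trilinear, any affine displacement
field is reproduced exactly and yields spatially constant strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registration import DisplacementField, NodalGrid
from .volumes import BinaryMask

STRAIN_COMPONENTS = ("exx", "eyy", "ezz", "gxy", "gyz", "gxz")

# local corner order (dx, dy, dz), dx slowest — matches NodalGrid.cell_nodes
_CORNERS = np.array([(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)])


@dataclass
class HexMesh:
    """Retained part of the registration grid as an FE-style hex mesh."""

    nodes: np.ndarray        # (n_mesh_nodes, 3) voxel coords
    elements: np.ndarray     # (n_elements, 8) mesh-node indices
    node_map: dict           # grid-node flat index -> mesh-node index
    grid_node_index: np.ndarray  # (n_mesh_nodes,) flat grid-node indices
    ns: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


@dataclass
class StrainField:
    """Six small-strain components per retained mesh node, in με."""

    nodes: np.ndarray  # (n, 3) voxel coords
    eps: np.ndarray    # (n, 6) με, order STRAIN_COMPONENTS

    def __post_init__(self) -> None:
        if self.eps.shape != (len(self.nodes), 6):
            raise ValueError("eps must be (n_nodes, 6)")
        if not np.all(np.isfinite(self.eps)):
            raise ValueError("strain field contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def extract_mesh(grid: NodalGrid, voi: BinaryMask) -> HexMesh:
    """Keep exactly the cells with ≥ 1 node inside the VOI.

    A node counts as inside when its voxel position lies in the lattice
    and the VOI is true there.  Retained mesh nodes are the union of the
    kept cells' corners.
    """
    if not np.any(voi.data):
        raise ValueError("VOI is empty")
    if voi.shape != grid.shape:
        raise ValueError("VOI must share the grid's volume shape")

    coords = grid.node_coordinates().astype(int)
    in_lattice = np.all(coords < np.asarray(grid.shape), axis=1)
    node_in_voi = np.zeros(grid.n_nodes, dtype=bool)
    ok = coords[in_lattice]
    node_in_voi[in_lattice] = voi.data[ok[:, 0], ok[:, 1], ok[:, 2]]

    cells = grid.cell_nodes()
    keep = node_in_voi[cells].any(axis=1)
    if not np.any(keep):
        raise ValueError("no grid cell has a node inside the VOI")
    kept_cells = cells[keep]

    used = np.unique(kept_cells)
    node_map = {int(g): i for i, g in enumerate(used)}
    elements = np.vectorize(node_map.__getitem__)(kept_cells)
    return HexMesh(
        nodes=coords[used].astype(float),
        elements=elements.astype(np.int64),
        node_map=node_map,
        grid_node_index=used,
        ns=grid.ns,
    )


def compute_nodal_strains(mesh: HexMesh, field: DisplacementField) -> StrainField:
    """Differentiate nodal displacements into small strains, in με.

    Within each element the displacement is the trilinear interpolant of
    its 8 corner values; the gradient at a corner reduces to the three
    edge differences from that corner divided by the cell side.  Per-node
    strain is the average over the node's incident retained elements —
    the standard FE nodal averaging.
    """
    if field.grid.ns != mesh.ns:
        raise ValueError("mesh and displacement field use different nodal spacings")
    u_all = field.u_flat()  # voxels, grid-node-major
    try:
        u = u_all[mesh.grid_node_index]
    except IndexError as exc:
        raise ValueError("displacement field does not cover all mesh nodes") from exc

    h = float(mesh.ns)
    elem_u = u[mesh.elements]  # (ne, 8, 3)

    # corner-local gradients: du/dx at corner (a,b,c) = (u(1,b,c)-u(0,b,c))/h
    idx = {tuple(c): i for i, c in enumerate(_CORNERS)}
    grads = np.empty((mesh.n_elements, 8, 3, 3))  # (elem, corner, du_i, d/dx_j)
    for ci, (a, b, c) in enumerate(_CORNERS):
        dx = (elem_u[:, idx[(1, b, c)]] - elem_u[:, idx[(0, b, c)]]) / h
        dy = (elem_u[:, idx[(a, 1, c)]] - elem_u[:, idx[(a, 0, c)]]) / h
        dz = (elem_u[:, idx[(a, b, 1)]] - elem_u[:, idx[(a, b, 0)]]) / h
        grads[:, ci, :, 0] = dx
        grads[:, ci, :, 1] = dy
        grads[:, ci, :, 2] = dz

    eps_corner = np.empty((mesh.n_elements, 8, 6))
    eps_corner[..., 0] = grads[..., 0, 0]
    eps_corner[..., 1] = grads[..., 1, 1]
    eps_corner[..., 2] = grads[..., 2, 2]
    eps_corner[..., 3] = grads[..., 0, 1] + grads[..., 1, 0]  # γxy
    eps_corner[..., 4] = grads[..., 1, 2] + grads[..., 2, 1]  # γyz
    eps_corner[..., 5] = grads[..., 0, 2] + grads[..., 2, 0]  # γxz

    sums = np.zeros((mesh.n_nodes, 6))
    counts = np.zeros(mesh.n_nodes)
    flat_nodes = mesh.elements.ravel()
    np.add.at(sums, flat_nodes, eps_corner.reshape(-1, 6))
    np.add.at(counts, flat_nodes, 1.0)
    eps = sums / counts[:, None] * 1e6  # με

    return StrainField(nodes=mesh.nodes, eps=eps)
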