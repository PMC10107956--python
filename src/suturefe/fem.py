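"""Small-strain linear-elastic FE solver on labelled tetrahedral meshes.

The element is the 4-node constant-strain tetrahedron (TET4):
K_e = V * B^T D B with the isotropic elasticity matrix D built from the
Lame parameters of the element's tissue.  Constraints are imposed by
elimination (row/column reduction); the reduced symmetric system is
solved by sparse LU factorization.  Reactions are recovered at every
constrained DOF as (K u - f) and global equilibrium (sum of applied
forces plus reactions = 0 per axis) is verified on every solve.

Everything is deterministic and seedless.  Strain recovery is exact for
globally linear displacement fields, which is the basis of the patch
tests in the verification suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialTable, lame_parameters
from .phantom import TetMesh, tet_volumes

logger = logging.getLogger(__name__)

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class LoadCase:
    """Nodal point loads plus homogeneous displacement constraints.

    ``fixed`` holds (node, axis, prescribed value) triples; the pipeline
    only ever prescribes 0 (the loading experiments constrain, never
    displace), but the solver supports arbitrary values for verification
    studies.  A DOF may not be both loaded and constrained.
    """

    name: str = "custom"
    loads: list = field(default_factory=list)  # (node, (3,) force N)
    fixed: list = field(default_factory=list)  # (node, axis int, value)

    def add_load(self, node: int, force) -> None:
        f = np.asarray(force, dtype=float)
        if f.shape != (3,) or not np.all(np.isfinite(f)):
            raise ValueError("load must be a finite 3-vector")
        self.loads.append((int(node), f))

    def fix(self, node: int, axis, value: float = 0.0) -> None:
        ax = AXES[axis] if isinstance(axis, str) else int(axis)
        if ax not in (0, 1, 2):
            raise ValueError(f"invalid axis {axis!r}")
        self.fixed.append((int(node), ax, float(value)))

    def fix_all(self, node: int, value: float = 0.0) -> None:
        for ax in range(3):
            self.fix(node, ax, value)

    def fixed_dofs(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted unique DOF indices, prescribed values); conflicting
        prescriptions for one DOF raise."""
        dofs = {}
        for node, ax, val in self.fixed:
            dof = 3 * node + ax
            if dof in dofs and dofs[dof] != val:
                raise ValueError(f"conflicting prescribed values at DOF {dof}")
            dofs[dof] = val
        idx = np.array(sorted(dofs), dtype=np.int64)
        vals = np.array([dofs[d] for d in idx], dtype=float)
        return idx, vals

    def validate(self, n_nodes: int) -> None:
        fixed = {(n, a) for n, a, _ in self.fixed}
        for node, f in self.loads:
            if not (0 <= node < n_nodes):
                raise ValueError(f"load references invalid node {node}")
            for ax in range(3):
                if f[ax] != 0.0 and (node, ax) in fixed:
                    raise ValueError(
                        f"node {node} axis {ax} is both loaded and constrained"
                    )
        for node, ax, _ in self.fixed:
            if not (0 <= node < n_nodes):
                raise ValueError(f"constraint references invalid node {node}")


@dataclass
class DisplacementField:
    """Per-node displacement vectors in mm."""

    u: np.ndarray  # (n, 3)


@dataclass
class StrainField:
    """Per-element constant strain tensors (dimensionless) and volumes."""

    tensors: np.ndarray  # (m, 3, 3), symmetric
    volumes: np.ndarray  # (m,) mm^3

    def microstrain_tensors(self) -> np.ndarray:
        return self.tensors * 1.0e6


def isotropic_elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 Voigt elasticity matrix (order xx, yy, zz, xy, yz, zx)."""
    lam, mu = lame_parameters(E, nu)
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2.0 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Shape-function gradients (m, 4, 3) and volumes (m,) of TET4s."""
    m = elements.shape[0]
    M = np.ones((m, 4, 4))
    M[:, :, 1:] = nodes[elements]
    det = np.linalg.det(M)
    vols = det / 6.0
    if np.any(vols <= 0):
        bad = int(np.argmax(vols <= 0))
        raise ValueError(f"degenerate tetrahedron {bad}: volume {vols[bad]:.3e}")
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:, :].transpose(0, 2, 1)  # (m, node a, d/dx_i)
    return grads, vols


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrices B (m, 6, 12)."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def element_stiffness_tet4(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 TET4 stiffness K_e = V * B^T D B for one element.

    Symmetric positive semi-definite with exactly 6 zero eigenvalues
    (the rigid-body modes).
    """
    coords = np.asarray(coords, dtype=float).reshape(1, 4, 3)
    grads, vols = _shape_gradients(coords[0], np.arange(4).reshape(1, 4))
    B = _b_matrices(grads)[0]
    D = isotropic_elasticity_matrix(E, nu)
    return vols[0] * B.T @ D @ B


def assemble(mesh: TetMesh, materials: MaterialTable) -> sp.csr_matrix:
    """Global sparse stiffness matrix, 3 n_nodes square.

    Elements are processed grouped by tissue label but summed in a fixed
    global ordering, so assembly is independent of label grouping and
    bit-reproducible for equal per-element material values.
    """
    for label in np.unique(mesh.tissue):
        if label not in materials.entries:
            raise ValueError(f"no material for tissue label {label!r}")
    grads, vols = _shape_gradients(mesh.nodes, mesh.elements)
    B = _b_matrices(grads)
    m = mesh.n_elements
    Ke = np.empty((m, 12, 12))
    for label in np.unique(mesh.tissue):
        sel = mesh.tissue == label
        D = isotropic_elasticity_matrix(*materials[label])
        DB = np.einsum("ij,ejk->eik", D, B[sel])
        Ke[sel] = np.einsum("eji,ejk->eik", B[sel], DB) * vols[sel, None, None]

    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


@dataclass
class SolveResult:
    displacement: DisplacementField
    reactions: dict  # (node, axis) -> reaction force N
    residual: float  # relative residual on free DOFs


def solve(
    mesh: TetMesh,
    materials: MaterialTable,
    loadcase: LoadCase,
    K: sp.csr_matrix | None = None,
) -> SolveResult:
    """Solve K u = f with constrained DOFs eliminated.

    Pass a pre-assembled ``K`` to amortize assembly over several load
    cases on the same mesh/materials.  Raises if the reduced system is
    singular (under-constrained model) or the relative residual on the
    free DOFs exceeds 1e-8, and verifies global force balance.
    """
    loadcase.validate(mesh.n_nodes)
    if K is None:
        K = assemble(mesh, materials)
    n = 3 * mesh.n_nodes
    f = np.zeros(n)
    for node, force in loadcase.loads:
        f[3 * node : 3 * node + 3] += force

    fixed_idx, fixed_vals = loadcase.fixed_dofs()
    if fixed_idx.size == 0:
        raise ValueError("load case has no constraints; rigid modes present")
    free = np.ones(n, dtype=bool)
    free[fixed_idx] = False
    free_idx = np.flatnonzero(free)

    Kff = K[free_idx][:, free_idx].tocsc()
    rhs = f[free_idx]
    if np.any(fixed_vals != 0.0):
        rhs = rhs - K[free_idx][:, fixed_idx] @ fixed_vals

    u = np.zeros(n)
    u[fixed_idx] = fixed_vals
    if np.linalg.norm(rhs) > 0.0:
        try:
            lu = spla.splu(Kff)
        except RuntimeError as exc:
            raise ValueError(
                "singular reduced stiffness matrix — the constraint set "
                "probably leaves rigid-body modes; add constraints"
            ) from exc
        uf = lu.solve(rhs)
        if not np.all(np.isfinite(uf)):
            raise ValueError(
                "non-finite solution — singular or ill-posed reduced system"
            )
        res = np.linalg.norm(Kff @ uf - rhs) / np.linalg.norm(rhs)
        if res > 1e-8:
            raise ValueError(f"solver residual {res:.3e} exceeds 1e-8")
        u[free_idx] = uf
    else:
        res = 0.0

    r = K @ u - f
    reactions = {
        (int(d // 3), int(d % 3)): float(r[d]) for d in fixed_idx
    }
    # global equilibrium: applied + reactions balance per axis; the floor
    # keeps the relative check meaningful when loads and reactions are
    # numerically zero (e.g. prescribed rigid motion)
    kscale = np.abs(K.data).max() if K.nnz else 1.0
    floor = 1e-6 * kscale * (1.0 + np.abs(u).max())
    scale = max(np.abs(f).sum(), sum(abs(v) for v in reactions.values()), floor)
    total = f.reshape(-1, 3).sum(axis=0) + np.array(
        [sum(v for (nd, ax), v in reactions.items() if ax == i) for i in range(3)]
    )
    if np.abs(total).max() > 1e-8 * scale:
        raise ValueError(
            f"global equilibrium violated: residual {np.abs(total).max():.3e}"
        )
    logger.debug(
        "solve %s: %d free DOFs, residual %.2e", loadcase.name, free_idx.size, res
    )
    return SolveResult(DisplacementField(u.reshape(-1, 3)), reactions, res)


def recover_strains(mesh: TetMesh, displacement: DisplacementField) -> StrainField:
    """Constant strain per element: eps = sym(grad u)."""
    grads, vols = _shape_gradients(mesh.nodes, mesh.elements)
    ue = displacement.u[mesh.elements]  # (m, 4, 3)
    ue = ue - ue.mean(axis=1, keepdims=True)  # exact cancellation for rigid translation
    g = np.einsum("eai,eaj->eij", ue, grads)  # grad u, (m, 3, 3)
    eps = 0.5 * (g + g.transpose(0, 2, 1))
    return StrainField(tensors=eps, volumes=vols)


def reaction_sum(reactions: dict, nodes, axis: int) -> float:
    """Sum reaction components at given nodes along one axis."""
    nodes = {int(n) for n in np.atleast_1d(nodes)}
    return sum(v for (nd, ax), v in reactions.items() if ax == axis and nd in nodes)
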