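"""Solution-verification studies for the TET4 solver.

Standard solid-mechanics benchmarks with closed-form references: affine
patch tests on distorted meshes, rigid-body null-space checks, the
end-loaded axial bar (u = PL/EA) and a cantilever bending convergence
study against Timoshenko beam theory (Euler-Bernoulli tip deflection
plus the first-order shear correction).  These back the verification
analysis scripts, the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import LoadCase, recover_strains, solve
from .materials import default_material_table
from .phantom import PhantomSpec, TetMesh, build_hex_grid, hex_to_tets
from .strain import principal_strains


def _uniform_block(
    L: float, W: float, t: float, n: tuple[int, int, int],
    jitter: float = 0.0, seed: int = 0,
) -> TetMesh:
    """Homogeneous cortical-bone block mesh (no sutures, pegs or cores)."""
    spec = PhantomSpec(
        length=L, width=W, thickness=t, nx=n[0], ny=n[1], nz=n[2],
        jitter=jitter, seed=seed,
    )
    return hex_to_tets(build_hex_grid(spec))


def _face_nodes(mesh: TetMesh, axis: int, value: float, tol: float = 1e-9) -> np.ndarray:
    return np.flatnonzero(np.abs(mesh.nodes[:, axis] - value) < tol)


def _face_tractions(
    mesh: TetMesh, axis: int, value: float, traction: np.ndarray
) -> list[tuple[int, np.ndarray]]:
    """Consistent nodal loads of a uniform traction on one boundary plane."""
    faces = mesh.boundary_faces()
    on = np.all(np.abs(mesh.nodes[faces][:, :, axis] - value) < 1e-9, axis=1)
    loads: dict[int, np.ndarray] = {}
    for tri in faces[on]:
        p = mesh.nodes[tri]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        for node in tri:
            loads[int(node)] = loads.get(int(node), np.zeros(3)) + traction * area / 3.0
    return sorted(loads.items())


@dataclass
class PatchTestResult:
    max_strain_error: float  # max relative deviation from the imposed strain
    max_displacement_error: float  # interior nodes vs the affine field


def run_patch_test(
    n: tuple[int, int, int] = (5, 5, 5),
    jitter: float = 0.35,
    seed: int = 0,
    gradient: np.ndarray | None = None,
) -> PatchTestResult:
    """Affine displacement patch test on a jitter-distorted block.

    u = G x is prescribed on every boundary node of a distorted unit-ish
    block; a conforming linear element must reproduce the affine field
    (and its uniform strain sym(G)) exactly in the interior.
    """
    mesh = _uniform_block(1.0, 1.0, 1.0, n, jitter=jitter, seed=seed)
    if gradient is None:
        gradient = np.array(
            [
                [3.0e-4, 1.2e-4, -0.7e-4],
                [0.5e-4, -2.1e-4, 0.9e-4],
                [-1.1e-4, 0.4e-4, 1.8e-4],
            ]
        )
    exact = mesh.nodes @ gradient.T
    surf = mesh.surface_nodes()
    lc = LoadCase(name="patch")
    for node in surf:
        for ax in range(3):
            lc.fix(int(node), ax, float(exact[node, ax]))
    table = default_material_table()
    res = solve(mesh, table, lc)
    strain = recover_strains(mesh, res.displacement)
    eps_exact = 0.5 * (gradient + gradient.T)
    scale = np.abs(eps_exact).max()
    strain_err = np.abs(strain.tensors - eps_exact).max() / scale
    disp_err = np.abs(res.displacement.u - exact).max() / np.abs(exact).max()
    return PatchTestResult(float(strain_err), float(disp_err))


def run_rigid_mode_test(
    n: tuple[int, int, int] = (4, 4, 4), jitter: float = 0.3, seed: int = 0
) -> float:
    """Max |strain| (microstrain per unit displacement) under prescribed
    rigid translation + infinitesimal rotation of the whole boundary."""
    mesh = _uniform_block(1.0, 1.0, 1.0, n, jitter=jitter, seed=seed)
    # rigid motion: translation t0 + W x with skew W (infinitesimal rotation)
    t0 = np.array([0.3, -0.2, 0.5])
    omega = np.array([0.2, -0.4, 0.1]) * 1e-3
    W = np.array(
        [
            [0.0, -omega[2], omega[1]],
            [omega[2], 0.0, -omega[0]],
            [-omega[1], omega[0], 0.0],
        ]
    )
    exact = t0 + mesh.nodes @ W.T
    lc = LoadCase(name="rigid")
    for node in mesh.surface_nodes():
        for ax in range(3):
            lc.fix(int(node), ax, float(exact[node, ax]))
    res = solve(mesh, default_material_table(), lc)
    strain = recover_strains(mesh, res.displacement)
    unit = max(np.abs(exact).max(), 1e-30)
    return float(np.abs(strain.microstrain_tensors()).max() / unit)


@dataclass
class BarResult:
    tip_displacement: float  # mm, mean axial displacement of the loaded face
    exact: float  # PL / (E A)
    rel_error: float


def run_axial_bar(
    n: tuple[int, int, int] = (20, 2, 2),
    L: float = 100.0,
    side: float = 10.0,
    P: float = 10.0,
    E: float = 19920.0,
) -> BarResult:
    """End-loaded prismatic bar: uniform axial stress, u_tip = PL/(EA).

    nu = 0 so the uniaxial solution is exactly linear and a conforming
    linear element reproduces it to solver tolerance.
    """
    mesh = _uniform_block(L, side, side, n)
    table = default_material_table({"cortical": (E, 0.0)})
    A = side * side
    lc = LoadCase(name="bar")
    for node in _face_nodes(mesh, 0, 0.0):
        lc.fix_all(int(node))
    for node, f in _face_tractions(mesh, 0, L, np.array([P / A, 0.0, 0.0])):
        lc.add_load(node, f)
    res = solve(mesh, table, lc)
    tip = float(res.displacement.u[_face_nodes(mesh, 0, L), 0].mean())
    exact = P * L / (E * A)
    return BarResult(tip, exact, abs(tip - exact) / exact)


@dataclass
class CantileverResult:
    grid: tuple[int, int, int]
    tip_deflection: float  # mm, mean transverse displacement of the tip face
    reference: float  # Timoshenko tip deflection
    rel_error: float


def timoshenko_tip_deflection(
    P: float, L: float, W: float, t: float, E: float, nu: float
) -> float:
    """Euler-Bernoulli PL^3/(3EI) plus first-order shear correction
    PL/(kappa G A), kappa = 5/6 for a rectangular section."""
    I = W * t**3 / 12.0
    A = W * t
    G = E / (2.0 * (1.0 + nu))
    kappa = 5.0 / 6.0
    return P * L**3 / (3.0 * E * I) + P * L / (kappa * G * A)


def run_cantilever(
    n: tuple[int, int, int],
    L: float = 100.0,
    W: float = 10.0,
    t: float = 10.0,
    P: float = 10.0,
    E: float = 19920.0,
    nu: float = 0.3,
) -> CantileverResult:
    """Tip-loaded cantilever bending benchmark on one grid."""
    mesh = _uniform_block(L, W, t, n)
    table = default_material_table({"cortical": (E, nu)})
    lc = LoadCase(name="cantilever")
    for node in _face_nodes(mesh, 0, 0.0):
        lc.fix_all(int(node))
    for node, f in _face_tractions(mesh, 0, L, np.array([0.0, 0.0, P / (W * t)])):
        lc.add_load(node, f)
    res = solve(mesh, table, lc)
    tip = float(res.displacement.u[_face_nodes(mesh, 0, L), 2].mean())
    ref = timoshenko_tip_deflection(P, L, W, t, E, nu)
    return CantileverResult(tuple(n), tip, ref, abs(tip - ref) / ref)


def run_cantilever_study(
    grids: tuple = ((20, 2, 2), (40, 4, 4), (80, 8, 8))
) -> list[CantileverResult]:
    """Refinement study; errors must decrease monotonically (TET4 is
    stiff in bending and converges from below)."""
    return [run_cantilever(n) for n in grids]


def run_linearity_check(scale: float = 3.5) -> float:
    """Scaling all loads by c must scale u, strains and reactions by c
    exactly; returns the max relative deviation."""
    mesh = _uniform_block(10.0, 5.0, 5.0, (4, 2, 2), jitter=0.2, seed=3)
    table = default_material_table()
    lc1 = LoadCase(name="unit")
    for node in _face_nodes(mesh, 0, 0.0):
        lc1.fix_all(int(node))
    loads = _face_tractions(mesh, 0, 10.0, np.array([1.0, 0.5, -0.8]))
    for node, f in loads:
        lc1.add_load(node, f)
    lc2 = LoadCase(name="scaled")
    for node in _face_nodes(mesh, 0, 0.0):
        lc2.fix_all(int(node))
    for node, f in loads:
        lc2.add_load(node, scale * f)
    r1 = solve(mesh, table, lc1)
    r2 = solve(mesh, table, lc2)
    du = np.abs(r2.displacement.u - scale * r1.displacement.u).max()
    return float(du / max(np.abs(r2.displacement.u).max(), 1e-30))
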