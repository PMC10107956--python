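"""TET4 solver: element stiffness, assembly, solution, strain recovery."""

import numpy as np
import pytest
import scipy.sparse as sp

from suturefe.fem import (
    DisplacementField,
    LoadCase,
    assemble,
    element_stiffness_tet4,
    recover_strains,
    solve,
)
from suturefe.materials import default_material_table
from suturefe.phantom import TetMesh
from suturefe.verification import (
    run_axial_bar,
    run_linearity_check,
    run_patch_test,
    run_rigid_mode_test,
)

REF_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def two_tet_mesh(offset=5.0):
    """Two disconnected reference tets."""
    nodes = np.vstack([REF_TET, REF_TET + [offset, 0.0, 0.0]])
    elements = np.array([[0, 1, 2, 3], [4, 5, 6, 7]])
    return TetMesh(nodes=nodes, elements=elements,
                   tissue=np.array(["cortical", "cortical"]))


def test_element_stiffness_is_symmetric_psd_with_six_rigid_modes():
    rng = np.random.default_rng(2)
    coords = REF_TET + 0.2 * rng.standard_normal((4, 3))
    K = element_stiffness_tet4(coords, 19920.0, 0.3)
    assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()
    w = np.linalg.eigvalsh(K)
    assert np.sum(np.abs(w) < 1e-8 * w.max()) == 6
    assert w.min() > -1e-8 * w.max()


def test_element_stiffness_annihilates_rigid_modes():
    K = element_stiffness_tet4(REF_TET, 1000.0, 0.25)
    translation = np.tile([1.0, -2.0, 0.5], 4)
    assert np.abs(K @ translation).max() < 1e-9 * np.abs(K).max()
    omega = np.array([0.3, -0.1, 0.2])
    rotation = np.concatenate([np.cross(omega, x) for x in REF_TET])
    assert np.abs(K @ rotation).max() < 1e-9 * np.abs(K).max()


def test_element_stiffness_matches_symbolic_oracle():
    """Independent symbolic K = V B^T D B on the reference tet."""
    import sympy as sym

    E, nu = 1.0, 0.0
    lam, mu = 0, sym.Rational(1, 2)  # E/(2(1+nu)) with nu = 0
    # shape-function gradients of the reference tet, exact rationals
    grads = {0: (-1, -1, -1), 1: (1, 0, 0), 2: (0, 1, 0), 3: (0, 0, 1)}
    B = sym.zeros(6, 12)
    for a, (gx, gy, gz) in grads.items():
        c = 3 * a
        B[0, c], B[1, c + 1], B[2, c + 2] = gx, gy, gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    D = sym.diag(2 * mu, 2 * mu, 2 * mu, mu, mu, mu)
    for i in range(3):
        for j in range(3):
            D[i, j] += lam
    K_exact = sym.Rational(1, 6) * B.T * D * B
    K = element_stiffness_tet4(REF_TET, E, nu)
    assert np.abs(K - np.array(K_exact, dtype=float)).max() < 1e-14


def test_degenerate_tet_rejected():
    flat = REF_TET.copy()
    flat[3] = flat[0]  # zero volume
    with pytest.raises(ValueError, match="degenerate"):
        element_stiffness_tet4(flat, 100.0, 0.3)


def test_assembly_of_disconnected_tets_is_block_diagonal():
    mesh = two_tet_mesh()
    K = assemble(mesh, default_material_table()).toarray()
    assert np.abs(K[:12, 12:]).max() == 0.0
    assert np.abs(K[12:, :12]).max() == 0.0
    assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()


def test_missing_material_raises_with_label():
    mesh = two_tet_mesh()
    table = default_material_table()
    object.__setattr__(table, "entries",
                       {k: v for k, v in table.entries.items() if k != "cortical"})
    with pytest.raises(ValueError, match="cortical"):
        assemble(mesh, table)


def test_fused_variant_equals_relabelled_mesh_bit_for_bit(small_mesh):
    from suturefe.materials import apply_variant

    base = default_material_table()
    fused = apply_variant(base, "fused")
    K_fused = assemble(small_mesh, fused)

    relabelled = TetMesh(
        nodes=small_mesh.nodes,
        elements=small_mesh.elements,
        tissue=np.where(small_mesh.tissue == "suture", "cortical",
                        small_mesh.tissue),
        node_sets=small_mesh.node_sets,
        flat_nodes=small_mesh.flat_nodes,
    )
    K_rel = assemble(relabelled, base)
    assert (K_fused != K_rel).nnz == 0
    assert np.array_equal(K_fused.data, K_rel.data)


def test_zero_loads_give_zero_displacement_and_reactions():
    mesh = two_tet_mesh()
    lc = LoadCase(name="null")
    for n in range(8):
        lc.fix_all(n)
    res = solve(mesh, default_material_table(), lc)
    assert np.all(res.displacement.u == 0.0)
    assert all(v == 0.0 for v in res.reactions.values())


def test_global_equilibrium_of_applied_and_reaction_forces():
    mesh = two_tet_mesh(offset=2.0)
    lc = LoadCase(name="eq")
    for n in (0, 1, 2, 4, 5, 6):
        lc.fix_all(n)
    lc.add_load(3, [1.0, 2.0, -3.0])
    lc.add_load(7, [-0.5, 1.5, 2.0])
    res = solve(mesh, default_material_table(), lc)
    f_sum = np.array([0.5, 3.5, -1.0])
    r_sum = np.zeros(3)
    for (node, ax), v in res.reactions.items():
        r_sum[ax] += v
    assert np.abs(f_sum + r_sum).max() < 1e-8 * np.abs(f_sum).sum()


def test_unconstrained_model_raises():
    mesh = two_tet_mesh()
    lc = LoadCase(name="floating")
    lc.add_load(3, [1.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        solve(mesh, default_material_table(), lc)


def test_loaded_and_constrained_dof_rejected():
    mesh = two_tet_mesh()
    lc = LoadCase(name="conflict")
    lc.fix_all(3)
    lc.add_load(3, [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="both loaded and constrained"):
        solve(mesh, default_material_table(), lc)


# --------------------------------------------------------------------------
# strain recovery


def test_rigid_translation_recovers_exactly_zero_strain():
    mesh = two_tet_mesh()
    u = np.tile([0.3, -0.7, 0.2], (8, 1))
    strain = recover_strains(mesh, DisplacementField(u))
    assert np.abs(strain.tensors).max() == 0.0


def test_uniaxial_patch_field_gives_1000_microstrain():
    mesh = two_tet_mesh()
    u = np.zeros((8, 3))
    u[:, 0] = 0.001 * mesh.nodes[:, 0]
    strain = recover_strains(mesh, DisplacementField(u)).microstrain_tensors()
    expected = np.diag([1000.0, 0.0, 0.0])
    assert np.abs(strain - expected).max() < 1e-9


def test_pure_shear_patch_field_gives_500_microstrain_offdiagonal():
    mesh = two_tet_mesh()
    u = np.zeros((8, 3))
    u[:, 0] = 0.0005 * mesh.nodes[:, 1]
    u[:, 1] = 0.0005 * mesh.nodes[:, 0]
    strain = recover_strains(mesh, DisplacementField(u)).microstrain_tensors()
    expected = np.zeros((3, 3))
    expected[0, 1] = expected[1, 0] = 500.0
    assert np.abs(strain - expected).max() < 1e-9


# --------------------------------------------------------------------------
# verification benchmarks (shared with the acceptance suite)


def test_affine_patch_test_on_distorted_block():
    result = run_patch_test(seed=4)
    assert result.max_strain_error < 1e-9
    assert result.max_displacement_error < 1e-9


def test_rigid_boundary_motion_produces_no_strain():
    assert run_rigid_mode_test(seed=4) < 1e-4  # microstrain per unit disp


def test_axial_bar_matches_closed_form():
    assert run_axial_bar().rel_error < 1e-6


def test_solution_scales_linearly_with_load():
    assert run_linearity_check() < 1e-12
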