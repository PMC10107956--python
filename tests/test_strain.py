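"""Principal strains, dominance ratio, difference fields, gauges,
bone summaries and VTK round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from suturefe.fem import StrainField
from suturefe.phantom import build_phantom
from suturefe.strain import (
    PrincipalField,
    bone_surface_summary,
    difference_fields,
    dominance_ratio,
    nodal_average,
    principal_field,
    principal_strains,
    virtual_gauge,
)
from tests.conftest import small_spec


def test_diagonal_tensor_principals_are_sorted_eigenvalues():
    assert principal_strains(np.diag([5.0, -2.0, -10.0])) == pytest.approx(
        [5.0, -2.0, -10.0]
    )


def test_pure_shear_principals():
    e = 7.5
    t = np.zeros((3, 3))
    t[0, 1] = t[1, 0] = e
    assert principal_strains(t) == pytest.approx([e, 0.0, -e], abs=1e-12)


def test_isotropic_tensor_principals_are_equal():
    assert principal_strains(np.eye(3) * 3.3) == pytest.approx([3.3] * 3)


def test_asymmetric_tensor_rejected():
    t = np.zeros((3, 3))
    t[0, 1] = 1.0
    with pytest.raises(ValueError, match="symmetric"):
        principal_strains(t)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_principal_decomposition_preserves_trace_and_rebuilds(seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((3, 3)) * 1e-3
    t = 0.5 * (a + a.T)
    p = principal_strains(t)
    assert p[0] >= p[1] >= p[2]
    assert p.sum() == pytest.approx(np.trace(t), abs=1e-12)
    # rebuild from the eigen-decomposition (independent route via eigh)
    w, v = np.linalg.eigh(t)
    rebuilt = v @ np.diag(w) @ v.T
    assert np.abs(rebuilt - t).max() < 1e-9 * max(np.abs(t).max(), 1e-12)
    assert np.sort(w)[::-1] == pytest.approx(p, abs=1e-15)


@pytest.mark.parametrize(
    "e1, e3, expected", [(4.0, -4.0, 1.0), (10.0, -5.0, 2.0), (3.0, -6.0, 0.5)]
)
def test_dominance_ratio_values(e1, e3, expected):
    ratio, undef = dominance_ratio(e1, e3)
    assert not undef[0]
    assert ratio[0] == pytest.approx(expected)


def test_dominance_ratio_sentinel_for_degenerate_compression():
    ratio, undef = dominance_ratio(5.0, 0.0)
    assert undef[0]
    assert np.isnan(ratio[0])


def _pf(e1, e3):
    m = len(e1)
    princ = np.column_stack([e1, np.zeros(m), e3])
    return PrincipalField(
        element_principals=princ,
        dominance=np.zeros(m),
        dominance_undefined=np.zeros(m, bool),
        nodal_eps1=np.zeros(0),
        nodal_eps3=np.zeros(0),
    )


def test_difference_fields_identical_inputs_are_zero():
    f = _pf([10.0, -3.0], [-5.0, -8.0])
    d = difference_fields(f, f)
    for arr in d.values():
        assert np.all(arr == 0.0)


def test_difference_fields_doubled_magnitude_gives_relative_one():
    sut = _pf([10.0], [-5.0])
    fus = _pf([20.0], [-10.0])
    d = difference_fields(fus, sut)
    assert d["rel_diff_eps1"][0] == pytest.approx(1.0)
    assert d["abs_diff_eps1"][0] == pytest.approx(10.0)
    assert d["abs_diff_eps3"][0] == pytest.approx(5.0)


def test_difference_fields_sign_flips_when_arguments_swap():
    a = _pf([10.0, 2.0], [-5.0, -1.0])
    b = _pf([4.0, 6.0], [-9.0, -0.5])
    d_ab = difference_fields(a, b)
    d_ba = difference_fields(b, a)
    for k in d_ab:
        assert np.all(np.sign(d_ab[k]) == -np.sign(d_ba[k]))


def test_difference_fields_mismatched_meshes_rejected():
    with pytest.raises(ValueError, match="identical"):
        difference_fields(_pf([1.0], [-1.0]), _pf([1.0, 2.0], [-1.0, -2.0]))


def test_nodal_average_is_convex_combination(small_mesh):
    rng = np.random.default_rng(0)
    vals = rng.uniform(-10, 10, small_mesh.n_elements)
    nodal = nodal_average(small_mesh, vals)
    # adjacency bound: every nodal value within global element range
    assert nodal.min() >= vals.min() - 1e-12
    assert nodal.max() <= vals.max() + 1e-12
    const = nodal_average(small_mesh, np.full(small_mesh.n_elements, 4.2))
    assert const == pytest.approx(np.full(small_mesh.n_nodes, 4.2))


def _uniform_field(mesh, value):
    m = mesh.n_elements
    return PrincipalField(
        element_principals=np.tile([value, 0.0, -value], (m, 1)),
        dominance=np.ones(m),
        dominance_undefined=np.zeros(m, bool),
        nodal_eps1=np.full(mesh.n_nodes, value),
        nodal_eps3=np.full(mesh.n_nodes, -value),
    )


def test_virtual_gauge_uniform_field_has_zero_sd(small_mesh):
    g = virtual_gauge(small_mesh, _uniform_field(small_mesh, 123.0), "gauge_pb")
    assert g.mean_eps1 == pytest.approx(123.0)
    assert g.sd_eps1 == pytest.approx(0.0, abs=1e-9)
    assert g.patch_area == pytest.approx(1.0)
    assert g.n_nodes >= 3


def test_virtual_gauge_missing_site_rejected(small_mesh):
    with pytest.raises(ValueError, match="missing"):
        virtual_gauge(small_mesh, _uniform_field(small_mesh, 1.0), "nope")


def test_suture_crossing_gauge_has_larger_sd_than_bone_gauge(small_run):
    """Patches straddling a suture band mix band and bone values, so
    their spread dwarfs a patch on homogeneous bone."""
    art = small_run.artifacts["cases"]["incisor_bilateral"]
    gauges = {
        g["site"]: g
        for g in small_run.data["cases"]["incisor_bilateral"]["variants"][
            "sutured"
        ]["gauges"]
    }
    assert gauges["gauge_sgs"]["sd_eps1"] > 10 * gauges["gauge_pb"]["sd_eps1"]
    assert art is not None


def test_bone_summary_constant_field(small_mesh):
    s = bone_surface_summary(
        small_mesh, _uniform_field(small_mesh, 7.0), "parietal_left"
    )
    assert s.mean_eps1 == pytest.approx(7.0)
    assert s.sd_eps1 == pytest.approx(0.0, abs=1e-12)
    assert s.n_nodes == small_mesh.node_sets["surface_parietal_left"].size
    with pytest.raises(ValueError, match="no surface node set"):
        bone_surface_summary(small_mesh, _uniform_field(small_mesh, 1.0), "hyoid")


def test_principal_field_orders_elementwise(small_run):
    pf = small_run.artifacts["cases"]["incisor_bilateral"]["variants"][
        "sutured"
    ]["principal"]
    p = pf.element_principals
    assert np.all(p[:, 0] >= p[:, 1] - 1e-12)
    assert np.all(p[:, 1] >= p[:, 2] - 1e-12)


# --------------------------------------------------------------------------
# VTK round trip


def test_vtk_round_trip_preserves_mesh_and_fields(tmp_path):
    from suturefe.vtk_io import export_vtk, mesh_from_vtk, read_vtk

    mesh = build_phantom(small_spec())
    rng = np.random.default_rng(1)
    cell = rng.standard_normal(mesh.n_elements) * 1e3
    point = rng.standard_normal(mesh.n_nodes)
    disp = rng.standard_normal((mesh.n_nodes, 3)) * 1e-2
    path = tmp_path / "mesh.vtk"
    export_vtk(mesh, path, cell_fields={"eps1": cell},
               point_fields={"nodal_eps1": point}, displacement=disp)

    data = read_vtk(path)
    assert np.array_equal(data.cells, mesh.elements)
    assert np.allclose(data.points, mesh.nodes, rtol=1e-6, atol=1e-12)
    # tissue + eps1 cell arrays; displacement + nodal + node-set masks
    assert set(data.cell_data) == {"tissue", "eps1"}
    assert np.allclose(data.cell_data["eps1"], cell, rtol=1e-6)
    assert np.allclose(data.point_data["nodal_eps1"], point, rtol=1e-6)
    assert np.allclose(data.point_data["displacement"], disp, rtol=1e-6)

    rebuilt = mesh_from_vtk(data)
    assert np.array_equal(rebuilt.tissue, mesh.tissue)
    for name, nodes in mesh.node_sets.items():
        assert np.array_equal(rebuilt.node_sets[name], np.sort(nodes))


def test_vtk_header_structure(tmp_path):
    from suturefe.vtk_io import export_vtk

    mesh = build_phantom(small_spec())
    path = tmp_path / "hdr.vtk"
    export_vtk(mesh, path, include_node_sets=False)
    lines = path.read_text().splitlines()
    assert lines[0] == "# vtk DataFile Version 3.0"
    assert lines[2] == "ASCII"
    assert lines[3] == "DATASET UNSTRUCTURED_GRID"
    assert lines[4] == f"POINTS {mesh.n_nodes} double"
    assert f"CELLS {mesh.n_elements} {5 * mesh.n_elements}" in lines
    assert f"CELL_TYPES {mesh.n_elements}" in lines
    assert f"CELL_DATA {mesh.n_elements}" in lines


def test_vtk_mis_sized_field_rejected(tmp_path):
    from suturefe.vtk_io import export_vtk

    mesh = build_phantom(small_spec())
    with pytest.raises(ValueError, match="not sized"):
        export_vtk(mesh, tmp_path / "x.vtk", cell_fields={"bad": np.zeros(3)})
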