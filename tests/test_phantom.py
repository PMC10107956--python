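"""Phantom generator: lattice counts, tet split, labelling, node sets."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from suturefe.phantom import (
    PhantomSpec,
    SutureBand,
    ToothPeg,
    analytic_volume,
    build_hex_grid,
    build_phantom,
    hex_to_tets,
    label_regions,
    tet_volumes,
)
from tests.conftest import small_spec


def block(nx, ny, nz, **kw):
    return PhantomSpec(length=kw.pop("L", 1.0), width=kw.pop("W", 1.0),
                       thickness=kw.pop("t", 1.0), nx=nx, ny=ny, nz=nz, **kw)


# --------------------------------------------------------------------------
# lattice and hex -> tet split


@pytest.mark.parametrize(
    "n, n_nodes, n_hex",
    [((1, 1, 1), 8, 1), ((2, 1, 1), 12, 2), ((3, 2, 2), 36, 12)],
)
def test_lattice_counts(n, n_nodes, n_hex):
    grid = build_hex_grid(block(*n))
    assert grid.nodes.shape == (n_nodes, 3)
    assert grid.hexes.shape == (n_hex, 8)


def test_flat_lattice_has_parallel_z_levels():
    grid = build_hex_grid(block(3, 3, 3, t=2.0))
    zs = np.unique(np.round(grid.nodes[:, 2], 12))
    assert zs.size == 4  # nz + 1 distinct planes
    for z in zs:
        layer = grid.nodes[np.abs(grid.nodes[:, 2] - z) < 1e-12]
        assert layer.shape[0] == 16


def test_invalid_dimensions_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(length=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(nx=0)


def test_unit_hex_splits_into_six_tets_conserving_volume():
    mesh = hex_to_tets(build_hex_grid(block(1, 1, 1)))
    vols = mesh.volumes()
    assert mesh.n_elements == 6
    assert np.all(vols > 0)
    assert vols.sum() == pytest.approx(1.0, abs=1e-14)


def test_two_hex_grid_gives_twelve_unique_tets():
    mesh = hex_to_tets(build_hex_grid(block(2, 1, 1, L=2.0)))
    assert mesh.n_elements == 12
    canon = {tuple(sorted(e)) for e in mesh.elements}
    assert len(canon) == 12


def _divergence_volume(pts: np.ndarray) -> float:
    """Volume of one hex cell by the divergence theorem over the twelve
    boundary triangles of the fixed diagonal pattern (independent of the
    tetrahedral decomposition)."""
    quads = [  # outward-oriented faces, first corner on the split diagonal
        (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
        (1, 2, 6, 5), (3, 7, 6, 2), (0, 4, 7, 3),
    ]
    vol = 0.0
    for quad in quads:
        # triangulate on the diagonal the conforming mesher uses
        a, b, c, d = quad
        for tri in ((a, b, c), (a, c, d)):
            p0, p1, p2 = pts[list(tri)]
            vol += np.dot(p0, np.cross(p1, p2)) / 6.0
    return vol


def test_arched_jittered_cells_conserve_volume_against_divergence_oracle():
    spec = block(4, 3, 2, L=8.0, W=6.0, t=2.0, arch_curvature=1.1,
                 jitter=0.3, seed=7)
    grid = build_hex_grid(spec)
    mesh = hex_to_tets(grid)
    vols = mesh.volumes().reshape(-1, 6).sum(axis=1)
    for ci, hexa in enumerate(grid.hexes):
        oracle = _divergence_volume(grid.nodes[hexa])
        assert vols[ci] == pytest.approx(oracle, rel=1e-12)


def test_total_volume_matches_analytic_flat_and_arched():
    for kw in ({}, {"arch_curvature": 1.2}, {"arch_curvature": 0.9, "jitter": 0.3}):
        spec = block(6, 5, 4, L=12.0, W=8.0, t=3.0, **kw)
        mesh = hex_to_tets(build_hex_grid(spec))
        assert mesh.volumes().sum() == pytest.approx(
            analytic_volume(spec), rel=1e-10
        )


def test_interior_faces_shared_by_exactly_two_tets():
    mesh = hex_to_tets(build_hex_grid(block(3, 3, 2, jitter=0.25, seed=1)))
    faces = mesh.elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
    key = np.sort(faces.reshape(-1, 3), axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    assert set(counts) <= {1, 2}
    boundary = np.sum(counts == 1)
    # each boundary quad contributes 2 triangles
    assert boundary == 2 * 2 * (3 * 3 + 3 * 2 + 3 * 2)


def test_inverted_cell_raises_with_cell_index():
    grid = build_hex_grid(block(2, 1, 1, L=2.0))
    # collapse one corner of the second hex through the cell
    grid.nodes[grid.hexes[1, 6]] = grid.nodes[grid.hexes[1, 0]] - 0.1
    with pytest.raises(ValueError, match="cell 1"):
        hex_to_tets(grid)


# --------------------------------------------------------------------------
# labelling


def band_spec(width=0.4, amplitude=0.0, wavelength=4.0, patent=True,
              n=(40, 20, 4)):
    return PhantomSpec(
        length=8.0, width=4.0, thickness=0.8, nx=n[0], ny=n[1], nz=n[2],
        sutures=(SutureBand("longitudinal", offset=2.0, width=width,
                            amplitude=amplitude, wavelength=wavelength,
                            patent=patent),),
    )


def test_straight_band_is_exactly_two_cells_wide():
    # cell size 0.2 mm, band width 0.4 mm centred on a lattice line
    spec = band_spec(width=0.4)
    mesh = label_regions(hex_to_tets(build_hex_grid(spec)), spec)
    cy = mesh.flat_centroids()[:, 1]
    sut = mesh.tissue == "suture"
    assert np.unique(np.round(cy[sut], 6)).size > 0
    assert np.abs(cy[sut] - 2.0).max() < 0.2
    assert not np.any((np.abs(cy - 2.0) <= 0.2) & ~sut)
    rows = np.unique(np.floor(cy[sut] / 0.2).astype(int))
    assert rows.size == 2


def test_non_patent_band_labels_no_suture_elements():
    spec = band_spec(patent=False)
    mesh = label_regions(hex_to_tets(build_hex_grid(spec)), spec)
    assert np.sum(mesh.tissue == "suture") == 0


def test_interdigitated_band_claims_strictly_more_elements():
    straight = band_spec(width=0.4)
    wavy = band_spec(width=0.4, amplitude=1.5, wavelength=4.0)
    n_straight = np.sum(
        label_regions(hex_to_tets(build_hex_grid(straight)), straight).tissue
        == "suture"
    )
    n_wavy = np.sum(
        label_regions(hex_to_tets(build_hex_grid(wavy)), wavy).tissue == "suture"
    )
    assert n_wavy > n_straight


@pytest.mark.parametrize("param", ["width", "amplitude"])
def test_suture_count_monotone_in_band_parameters(param):
    values = {"width": (0.4, 0.8, 1.2), "amplitude": (0.0, 0.5, 1.0)}[param]
    counts = []
    for v in values:
        kw = {param: v}
        if param == "amplitude":
            kw["width"] = 0.4
        spec = band_spec(**kw)
        mesh = label_regions(hex_to_tets(build_hex_grid(spec)), spec)
        counts.append(int(np.sum(mesh.tissue == "suture")))
    assert counts == sorted(counts)


def test_labels_deterministic_and_complete(small_mesh):
    again = build_phantom(small_spec())
    assert np.array_equal(small_mesh.nodes, again.nodes)
    assert np.array_equal(small_mesh.elements, again.elements)
    assert np.array_equal(small_mesh.tissue, again.tissue)
    for name, nodes in small_mesh.node_sets.items():
        assert np.array_equal(nodes, again.node_sets[name])
    assert set(np.unique(small_mesh.tissue)) <= {
        "cortical", "trabecular", "suture", "tooth", "pulp", "pdl"
    }


def test_band_outside_plate_rejected():
    with pytest.raises(ValueError, match="bounds"):
        band_spec(width=0.4, amplitude=3.0, wavelength=4.0)


def test_pdl_thinner_than_cell_rejected():
    with pytest.raises(ValueError, match="PDL"):
        small_spec(pegs=(ToothPeg("incisor_left", x=2.5, y=12.5, radius=1.2,
                                  length=0.75, pdl_thickness=0.2),))


# --------------------------------------------------------------------------
# node sets


def test_bite_sets_are_single_peg_tip_nodes(small_mesh):
    for name in ("incisor_left_bite", "incisor_right_bite",
                 "molar_left_bite", "molar_right_bite"):
        assert small_mesh.node_sets[name].size == 1


def test_pb_gauge_site_is_at_least_3mm_from_sutures(small_mesh):
    from scipy.spatial import cKDTree

    sut = small_mesh.flat_centroids()[small_mesh.tissue == "suture"]
    flat = small_mesh.flat_nodes
    node = int(small_mesh.node_sets["gauge_pb"][0])
    d, _ = cKDTree(sut[:, :2]).query(flat[node, :2])
    assert d >= 3.0


def test_bone_surface_sets_partition_non_suture_surface(small_mesh):
    suture_nodes = np.unique(
        small_mesh.elements[small_mesh.tissue == "suture"]
    )
    bone_sets = [v for k, v in small_mesh.node_sets.items()
                 if k.startswith("surface_")]
    assert len(bone_sets) == 6
    union = np.concatenate(bone_sets)
    assert union.size == np.unique(union).size  # disjoint
    assert not np.isin(union, suture_nodes).any()
    surf = small_mesh.surface_nodes()
    expected = np.setdiff1d(surf, suture_nodes)
    assert np.array_equal(np.sort(union), expected)


def test_gauge_seed_nodes_sit_on_their_bands(small_mesh):
    flat = small_mesh.flat_nodes
    ifs = flat[int(small_mesh.node_sets["gauge_ifs"][0])]
    sgs = flat[int(small_mesh.node_sets["gauge_sgs"][0])]
    spec = small_spec()
    coronal = [b for b in spec.sutures if b.name == "coronal"][0]
    sagittal = [b for b in spec.sutures if b.name == "sagittal"][0]
    assert abs(ifs[0] - coronal.offset_at(ifs[1], spec.width)) < 1.5
    assert abs(sgs[1] - sagittal.offset_at(sgs[0], spec.length)) < 1.5


def test_pb_site_impossible_when_sutures_cover_plate():
    spec = small_spec()
    # band leaves the lateral walls as bone but no dorsal node is
    # more than 3 mm from a suture element
    covering = (SutureBand("longitudinal", offset=10.0, width=15.0),)
    with pytest.raises(ValueError, match="PB"):
        build_phantom(replace(spec, sutures=covering, pegs=()))
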