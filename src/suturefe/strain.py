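"""Principal-strain post-processing: dominance ratios, difference fields,
virtual strain gauges, per-bone surface summaries.

Conventions follow the craniofacial FE literature: eps1 is the most
tensile and eps3 the most compressive principal strain, both reported in
microstrain (1e6 x strain); the dominance ratio |eps1 / eps3| classifies
each element as tension- or compression-dominated.  Nodal fields are
volume-weighted averages of the adjacent element values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fem import StrainField
from .phantom import TetMesh

#: |eps3| below this (microstrain) makes the dominance ratio undefined.
DOMINANCE_FLOOR = 1.0e-3
#: denominator floor (microstrain) of the relative difference field
RELATIVE_DIFF_FLOOR = 1.0


def principal_strains(tensors: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric strain tensors, sorted descending.

    Accepts one (3, 3) tensor or a stack (m, 3, 3); returns (..., 3) as
    (eps1 >= eps2 >= eps3) in the units of the input.  Inputs with
    asymmetry above 1e-9 (relative) are rejected.
    """
    t = np.asarray(tensors, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    if t.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    asym = np.abs(t - t.transpose(0, 2, 1)).max()
    scale = max(np.abs(t).max(), 1.0e-30)
    if asym > 1e-9 * max(scale, 1.0):
        raise ValueError(f"non-symmetric strain tensor (asymmetry {asym:.3e})")
    vals = np.linalg.eigvalsh(0.5 * (t + t.transpose(0, 2, 1)))[:, ::-1]
    return vals[0] if single else vals


def dominance_ratio(
    eps1: np.ndarray, eps3: np.ndarray, floor: float = DOMINANCE_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """|eps1| / |eps3| per element, with a sentinel for |eps3| below floor.

    Returns ``(ratio, undefined)``: where ``undefined`` is True the
    element is tension-dominated with an undefined ratio and ``ratio``
    holds NaN.  Inputs in microstrain (the floor is 1e-3 microstrain).
    """
    e1 = np.atleast_1d(np.asarray(eps1, dtype=float))
    e3 = np.atleast_1d(np.asarray(eps3, dtype=float))
    undefined = np.abs(e3) < floor
    ratio = np.full(e1.shape, np.nan)
    np.divide(np.abs(e1), np.abs(e3), out=ratio, where=~undefined)
    return ratio, undefined


@dataclass
class PrincipalField:
    """Element principal strains (microstrain) with nodal companions."""

    element_principals: np.ndarray  # (m, 3): eps1 >= eps2 >= eps3
    dominance: np.ndarray  # (m,) |eps1/eps3|, NaN where undefined
    dominance_undefined: np.ndarray  # (m,) bool
    nodal_eps1: np.ndarray  # (n,)
    nodal_eps3: np.ndarray  # (n,)


def nodal_average(mesh: TetMesh, element_values: np.ndarray) -> np.ndarray:
    """Volume-weighted average of element values onto nodes.

    Every nodal value lies within [min, max] of the adjacent element
    values (convex combination).
    """
    vals = np.asarray(element_values, dtype=float)
    vols = mesh.volumes()
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(num, mesh.elements[:, a], vals * vols)
        np.add.at(den, mesh.elements[:, a], vols)
    out = np.zeros(mesh.n_nodes)
    np.divide(num, den, out=out, where=den > 0)
    return out


def principal_field(mesh: TetMesh, strain: StrainField) -> PrincipalField:
    """Full principal post-processing of one FE strain field."""
    princ = principal_strains(strain.microstrain_tensors())
    ratio, undef = dominance_ratio(princ[:, 0], princ[:, 2])
    return PrincipalField(
        element_principals=princ,
        dominance=ratio,
        dominance_undefined=undef,
        nodal_eps1=nodal_average(mesh, princ[:, 0]),
        nodal_eps3=nodal_average(mesh, princ[:, 2]),
    )


def difference_fields(
    field_fused: PrincipalField, field_sutured: PrincipalField
) -> dict[str, np.ndarray]:
    """Per-element strain-magnitude differences between variants.

    Sign convention: positive = higher strain when sutures are fused
    (absent), negative = higher when sutures are present.  The relative
    difference divides by max(|sutured|, 1 microstrain).
    """
    a = field_fused.element_principals
    b = field_sutured.element_principals
    if a.shape != b.shape:
        raise ValueError("difference fields require identically meshed variants")
    out = {}
    for comp, col in (("eps1", 0), ("eps3", 2)):
        mag_f = np.abs(a[:, col])
        mag_s = np.abs(b[:, col])
        out[f"abs_diff_{comp}"] = mag_f - mag_s
        out[f"rel_diff_{comp}"] = (mag_f - mag_s) / np.maximum(
            mag_s, RELATIVE_DIFF_FLOOR
        )
    return out


@dataclass
class GaugeReading:
    """Mean +/- SD of nodal eps1/eps3 over a ~1 mm^2 surface patch."""

    site: str
    mean_eps1: float
    sd_eps1: float
    mean_eps3: float
    sd_eps3: float
    n_nodes: int
    patch_area: float  # mm^2


def _node_tributary_areas(mesh: TetMesh) -> np.ndarray:
    """Surface area attributed to each node (1/3 of adjacent face areas)."""
    faces = mesh.boundary_faces()
    p = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    out = np.zeros(mesh.n_nodes)
    for a in range(3):
        np.add.at(out, faces[:, a], areas / 3.0)
    return out


def virtual_gauge(
    mesh: TetMesh,
    field: PrincipalField,
    site: str,
    target_area: float = 1.0,
) -> GaugeReading:
    """Average nodal principal strains over a rosette-gauge-sized patch.

    Surface nodes join the patch in order of distance from the site's
    seed node, each contributing its tributary surface area; the last
    node enters with the fractional weight that makes the patch area
    equal ``target_area`` exactly (default 1 mm^2, the footprint of the
    in vivo rosette gauges), so the reading is the area-weighted mean a
    physical gauge integrates.  Patches under 3 contributing nodes are
    rejected.
    """
    if site not in mesh.node_sets or mesh.node_sets[site].size == 0:
        raise ValueError(f"site node set {site!r} missing or empty")
    seed = mesh.nodes[mesh.node_sets[site]].mean(axis=0)
    surf = mesh.surface_nodes()
    areas = _node_tributary_areas(mesh)
    d = np.linalg.norm(mesh.nodes[surf] - seed, axis=1)
    order = np.argsort(d, kind="stable")
    cand = surf[order]
    cum = np.cumsum(areas[cand])
    if cum[-1] < target_area:
        raise ValueError(f"site {site}: surface smaller than the gauge footprint")
    k = int(np.searchsorted(cum, target_area))
    patch = cand[: k + 1]
    if patch.size < 3:
        raise ValueError(
            f"site {site}: gauge patch has {patch.size} nodes (< 3); refine mesh"
        )
    w = areas[patch].copy()
    w[-1] = target_area - (cum[k - 1] if k > 0 else 0.0)
    w /= w.sum()
    e1 = field.nodal_eps1[patch]
    e3 = field.nodal_eps3[patch]
    m1 = float(np.sum(w * e1))
    m3 = float(np.sum(w * e3))
    return GaugeReading(
        site=site,
        mean_eps1=m1,
        sd_eps1=float(np.sqrt(np.sum(w * (e1 - m1) ** 2))),
        mean_eps3=m3,
        sd_eps3=float(np.sqrt(np.sum(w * (e3 - m3) ** 2))),
        n_nodes=int(patch.size),
        patch_area=float(target_area),
    )


@dataclass
class BoneSummary:
    """Mean +/- SD of eps1/eps3 over one bone's surface node set."""

    bone: str
    mean_eps1: float
    sd_eps1: float
    mean_eps3: float
    sd_eps3: float
    n_nodes: int


def bone_surface_summary(
    mesh: TetMesh, field: PrincipalField, bone: str
) -> BoneSummary:
    """Surface-averaged principal strains of one bone.

    Tensile (eps1) and compressive (eps3) magnitudes are reported
    separately, as signed values.
    """
    key = f"surface_{bone}" if not bone.startswith("surface_") else bone
    if key not in mesh.node_sets:
        raise ValueError(f"no surface node set for bone {bone!r}")
    nodes = mesh.node_sets[key]
    if nodes.size == 0:
        raise ValueError(f"empty surface node set for bone {bone!r}")
    e1 = field.nodal_eps1[nodes]
    e3 = field.nodal_eps3[nodes]
    return BoneSummary(
        bone=bone.removeprefix("surface_"),
        mean_eps1=float(e1.mean()),
        sd_eps1=float(e1.std(ddof=0)),
        mean_eps3=float(e3.mean()),
        sd_eps3=float(e3.std(ddof=0)),
        n_nodes=int(nodes.size),
    )


def near_suture_bone_mask(mesh: TetMesh, distance: float = 1.0) -> np.ndarray:
    """Bone (cortical/trabecular) elements within ``distance`` mm of a
    suture element centroid."""
    cent = mesh.centroids()
    sut = cent[mesh.tissue == "suture"]
    if sut.shape[0] == 0:
        return np.zeros(mesh.n_elements, dtype=bool)
    d, _ = cKDTree(sut).query(cent, workers=1)
    bone = np.isin(mesh.tissue, ("cortical", "trabecular"))
    return bone & (d <= distance)
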