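"""Parametric labelled "skull phantom" meshes.

The phantom is a rectangular plate (optionally bent into a cylindrical
arch) of cortical bone carrying the topological features the cranial
loading experiment needs:

* one longitudinal "sagittal" suture band and two transverse
  "coronal"/"lambdoid" bands, straight or interdigitated (sinusoidal
  centreline), splitting the plate into six "bones";
* four tooth pegs (two anterior incisor-analogs, two posterior
  molar-analogs), each a cylindrical tooth with a pulp core and a
  compliant periodontal-ligament (PDL) sleeve;
* a trabecular core layer nested inside the cortical shell of each bone;
* named node sets for bite points, jaw-joint (TMJ) constraints, muscle
  attachment patches, virtual strain-gauge sites and per-bone surfaces.

Geometry is generated on a structured hexahedral lattice, each hexahedron
split into six tetrahedra with a fixed diagonal pattern that keeps shared
faces conforming.  Region labels are decided at element centroids in the
flat parametric frame, so the same spec labels the flat and the arched
phantom identically.  Everything is deterministic given the spec (the
seed only drives the optional interior-node jitter).

Axes: x runs longitudinally (anterior -> posterior), y transversely
(right -> left), z dorsoventrally ("vertical"); units are mm; node and
element indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

TISSUE_CODES = {
    "cortical": 0,
    "trabecular": 1,
    "suture": 2,
    "tooth": 3,
    "pulp": 4,
    "pdl": 5,
}
CODE_TISSUES = {v: k for k, v in TISSUE_CODES.items()}

_BONE_REGIONS = ("frontal", "parietal", "occipital")

# Six tetrahedra around the main diagonal v0-v6 of a hexahedron whose
# corners follow the usual bottom-then-top counter-clockwise ordering.
# Shared-face diagonals all point the same lattice direction, so
# neighbouring cells triangulate their common face identically.
_HEX_TO_TET = np.array(
    [
        (0, 1, 2, 6),
        (0, 2, 3, 6),
        (0, 3, 7, 6),
        (0, 7, 4, 6),
        (0, 4, 5, 6),
        (0, 5, 1, 6),
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class SutureBand:
    """A suture band with a straight or sinusoidal centreline.

    A *longitudinal* band runs along x with centreline
    ``y_c(x) = offset + amplitude * sin(2 pi x / wavelength)``; a
    *transverse* band swaps the roles of x and y.  An element belongs to
    the band when its centroid lies within ``width / 2`` (in-plane
    Euclidean distance) of the centreline curve.  Non-patent bands are
    geometric dividers only and are never labelled ``suture``.
    """

    axis: str  # "longitudinal" | "transverse"
    offset: float  # mm, centreline offset along the perpendicular axis
    width: float  # mm
    amplitude: float = 0.0  # mm, interdigitation amplitude
    wavelength: float = 0.0  # mm, interdigitation wavelength
    patent: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ("longitudinal", "transverse"):
            raise ValueError(f"unknown suture axis {self.axis!r}")
        if not self.width > 0:
            raise ValueError("suture width must be > 0")
        if self.width < 0.2:
            raise ValueError("suture width must be >= 0.2 mm")
        if self.amplitude > 0 and not self.wavelength > 0:
            raise ValueError("wavelength must be > 0 when amplitude > 0")

    def centreline(self, extent: float, n: int = 2048) -> np.ndarray:
        """Sampled centreline points (n, 2) in the (x, y) plane.

        Longitudinal bands oscillate as a sine from the anterior end;
        transverse bands use a cosine centred on the transverse midline
        so that interdigitation preserves the phantom's left-right
        (sagittal) mirror symmetry.
        """
        s = np.linspace(0.0, extent, n)
        if self.amplitude > 0:
            if self.axis == "longitudinal":
                wave = np.sin(2.0 * np.pi * s / self.wavelength)
            else:
                wave = np.cos(2.0 * np.pi * (s - extent / 2.0) / self.wavelength)
            off = self.offset + self.amplitude * wave
        else:
            off = np.full_like(s, self.offset)
        if self.axis == "longitudinal":
            return np.column_stack([s, off])
        return np.column_stack([off, s])

    def offset_at(self, s, extent: float):
        """Centreline offset at arclength coordinate ``s`` along the band."""
        if self.amplitude == 0:
            return self.offset + np.zeros_like(np.asarray(s, dtype=float))
        if self.axis == "longitudinal":
            wave = np.sin(2.0 * np.pi * np.asarray(s) / self.wavelength)
        else:
            wave = np.cos(2.0 * np.pi * (np.asarray(s) - extent / 2.0) / self.wavelength)
        return self.offset + self.amplitude * wave


@dataclass(frozen=True)
class ToothPeg:
    """A cylindrical tooth embedded in the plate, axis along z.

    The peg occupies ``0 <= z <= length`` from the ventral surface.
    Radially: pulp for ``r <= pulp_radius``, tooth for
    ``pulp_radius < r <= radius``, PDL sleeve for
    ``radius < r <= radius + pdl_thickness``.  The 0.2 mm default PDL is
    the anatomical minimum; specs on coarse grids must widen it to at
    least one cell so that the sleeve captures element centroids.
    """

    name: str
    x: float
    y: float
    radius: float
    length: float
    pdl_thickness: float = 0.2
    pulp_radius: float = 0.0

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.length > 0):
            raise ValueError("peg radius and length must be > 0")
        if self.pdl_thickness < 0 or self.pulp_radius < 0:
            raise ValueError("pdl_thickness and pulp_radius must be >= 0")
        if self.pulp_radius >= self.radius:
            raise ValueError("pulp_radius must be < radius")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of a phantom mesh."""

    length: float = 40.0  # mm, x
    width: float = 20.0  # mm, y
    thickness: float = 4.0  # mm, z
    nx: int = 64
    ny: int = 32
    nz: int = 6
    sutures: tuple[SutureBand, ...] = ()
    pegs: tuple[ToothPeg, ...] = ()
    trabecular_fraction: float = 0.0  # fraction of thickness in the core layer
    arch_curvature: float = 0.0  # rad subtended by the transverse section
    jitter: float = 0.0  # interior-node perturbation, fraction of cell size
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0 and self.thickness > 0):
            raise ValueError("plate dimensions must be > 0")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid resolutions must be >= 1")
        if not (0.0 <= self.trabecular_fraction < 1.0):
            raise ValueError("trabecular_fraction must lie in [0, 1)")
        if not (0.0 <= self.jitter <= 0.45):
            raise ValueError("jitter must lie in [0, 0.45] to keep cells valid")
        if self.arch_curvature < 0 or self.arch_curvature > np.pi:
            raise ValueError("arch_curvature must lie in [0, pi]")
        cell = min(self.length / self.nx, self.width / self.ny)
        if self.pegs:
            for peg in self.pegs:
                if peg.pdl_thickness > 0 and peg.pdl_thickness < cell:
                    raise ValueError(
                        f"peg {peg.name!r}: PDL thickness {peg.pdl_thickness} mm is "
                        f"below one cell size ({cell:.3g} mm); widen the sleeve or "
                        "refine the grid"
                    )
        for band in self.sutures:
            extent = self.length if band.axis == "transverse" else self.width
            reach = band.width / 2.0 + band.amplitude
            if band.offset - reach < 0 or band.offset + reach > extent:
                raise ValueError(
                    f"suture band {band.name!r} leaves the plate bounds"
                )

    @property
    def cell_sizes(self) -> tuple[float, float, float]:
        return (self.length / self.nx, self.width / self.ny, self.thickness / self.nz)


@dataclass
class HexGrid:
    """Structured lattice: arched node coordinates plus the flat frame."""

    nodes: np.ndarray  # (n, 3) arched coordinates
    flat_nodes: np.ndarray  # (n, 3) parametric (flat) coordinates
    hexes: np.ndarray  # (m, 8) node indices
    spec: PhantomSpec


@dataclass
class TetMesh:
    """Labelled tetrahedral mesh with named node sets."""

    nodes: np.ndarray  # (n, 3) mm
    elements: np.ndarray  # (m, 4) node indices, positive orientation
    tissue: np.ndarray  # (m,) tissue label strings
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    flat_nodes: np.ndarray | None = None  # parametric frame, if generated
    _boundary_faces: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.elements)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def flat_centroids(self) -> np.ndarray:
        pts = self.flat_nodes if self.flat_nodes is not None else self.nodes
        return pts[self.elements].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces on the mesh boundary, (k, 3) node indices."""
        if self._boundary_faces is None:
            faces = self.elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
            faces = faces.reshape(-1, 3)
            key = np.sort(faces, axis=1)
            _, inverse, counts = np.unique(
                key, axis=0, return_inverse=True, return_counts=True
            )
            self._boundary_faces = faces[counts[inverse] == 1]
        return self._boundary_faces

    def surface_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    def tissue_codes(self) -> np.ndarray:
        return np.array([TISSUE_CODES[t] for t in self.tissue], dtype=np.int32)


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedral elements."""
    x = nodes[elements]
    return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0


def _arch_map(flat: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Bend the flat plate about the x axis into a cylindrical arch.

    y is arclength along the mid-surface and z a radial offset, so the
    mapping preserves the analytic (faceted) volume cell by cell.
    """
    if spec.arch_curvature == 0.0:
        return flat.copy()
    r0 = spec.width / spec.arch_curvature
    theta = (flat[:, 1] - spec.width / 2.0) / r0
    r = r0 + (flat[:, 2] - spec.thickness / 2.0)
    out = flat.copy()
    out[:, 1] = spec.width / 2.0 + r * np.sin(theta)
    out[:, 2] = spec.thickness / 2.0 + r * np.cos(theta) - r0
    return out


def analytic_volume(spec: PhantomSpec) -> float:
    """Exact volume of the faceted phantom solid.

    Flat plate: L * W * t.  Arched: the cross-section is a faceted annulus
    sector whose area is ny * R0 * t * sin(curvature / ny); interior-node
    jitter never changes the total (the boundary is jitter-free).
    """
    if spec.arch_curvature == 0.0:
        return spec.length * spec.width * spec.thickness
    r0 = spec.width / spec.arch_curvature
    dtheta = spec.arch_curvature / spec.ny
    return spec.length * spec.ny * r0 * spec.thickness * np.sin(dtheta)


def build_hex_grid(spec: PhantomSpec) -> HexGrid:
    """Structured (nx+1)(ny+1)(nz+1)-node lattice of nx*ny*nz hexahedra.

    Interior nodes are jittered (seeded, in the flat frame) when
    ``spec.jitter > 0``; the lattice is then optionally bent into an arch.
    """
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    xs = np.linspace(0.0, spec.length, nx + 1)
    ys = np.linspace(0.0, spec.width, ny + 1)
    zs = np.linspace(0.0, spec.thickness, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    flat = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        delta = rng.uniform(-0.5, 0.5, size=flat.shape)
        delta *= spec.jitter * np.array(spec.cell_sizes)
        interior = (
            (X.ravel() > xs[0]) & (X.ravel() < xs[-1])
            & (Y.ravel() > ys[0]) & (Y.ravel() < ys[-1])
            & (Z.ravel() > zs[0]) & (Z.ravel() < zs[-1])
        )
        flat[interior] += delta[interior]

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    hexes = np.column_stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ]
    ).astype(np.int64)

    return HexGrid(nodes=_arch_map(flat, spec), flat_nodes=flat, hexes=hexes, spec=spec)


def hex_to_tets(grid: HexGrid) -> TetMesh:
    """Split every hexahedron into 6 conforming tetrahedra.

    Raises if any resulting tetrahedron has non-positive volume, naming
    the offending hexahedral cell.
    """
    elements = grid.hexes[:, _HEX_TO_TET].reshape(-1, 4)
    vols = tet_volumes(grid.nodes, elements)
    if np.any(vols <= 0):
        bad = int(np.argmax(vols <= 0) // len(_HEX_TO_TET))
        raise ValueError(f"inverted hexahedral cell {bad}: non-positive tet volume")
    tissue = np.full(elements.shape[0], "cortical", dtype="<U10")
    return TetMesh(
        nodes=grid.nodes,
        elements=elements,
        tissue=tissue,
        flat_nodes=grid.flat_nodes,
    )


def _suture_distance(points_xy: np.ndarray, band: SutureBand, spec: PhantomSpec) -> np.ndarray:
    """In-plane Euclidean distance from points to the band centreline."""
    extent = spec.width if band.axis == "transverse" else spec.length
    curve = band.centreline(extent)
    d, _ = cKDTree(curve).query(points_xy, workers=1)
    return d


def label_regions(mesh: TetMesh, spec: PhantomSpec) -> TetMesh:
    """Assign one tissue label per element from the spec's region rules.

    Decided at element centroids in the flat frame.  Precedence when
    regions overlap: tooth/pulp/pdl (peg interior is radially disjoint)
    > suture > trabecular > cortical.
    """
    c = mesh.flat_centroids()
    cx, cy, cz = c[:, 0], c[:, 1], c[:, 2]
    tissue = np.full(mesh.n_elements, "cortical", dtype="<U10")
    dx, dy, _dz = spec.cell_sizes
    cell = max(dx, dy)

    if spec.trabecular_fraction > 0:
        t = spec.thickness
        z_lo = t * (1.0 - spec.trabecular_fraction) / 2.0
        z_hi = t * (1.0 + spec.trabecular_fraction) / 2.0
        core = (cz >= z_lo) & (cz <= z_hi)
        # nested within cortical bone: inset from the plate's lateral walls
        core &= (cx >= dx) & (cx <= spec.length - dx)
        core &= (cy >= dy) & (cy <= spec.width - dy)
        # keep the core clear of suture bands (one-cell clearance)
        for band in spec.sutures:
            d = _suture_distance(c[:, :2], band, spec)
            core &= d > band.width / 2.0 + cell
        for peg in spec.pegs:
            r = np.hypot(cx - peg.x, cy - peg.y)
            core &= r > peg.radius + peg.pdl_thickness + cell
        tissue[core] = "trabecular"

    n_overlap = 0
    for band in spec.sutures:
        if not band.patent:
            continue
        d = _suture_distance(c[:, :2], band, spec)
        sel = d <= band.width / 2.0
        tissue[sel] = "suture"

    for peg in spec.pegs:
        r = np.hypot(cx - peg.x, cy - peg.y)
        inz = cz <= peg.length
        pdl = inz & (r > peg.radius) & (r <= peg.radius + peg.pdl_thickness)
        tooth = inz & (r > peg.pulp_radius) & (r <= peg.radius)
        pulp = inz & (r <= peg.pulp_radius)
        n_overlap += int(np.sum((pdl | tooth | pulp) & (tissue == "suture")))
        tissue[pdl] = "pdl"
        tissue[tooth] = "tooth"
        tissue[pulp] = "pulp"
    if n_overlap:
        logger.info(
            "label_regions: %d elements claimed by both a peg and a suture band; "
            "peg labels take precedence", n_overlap,
        )

    return replace(mesh, tissue=tissue)


def _nearest_node(points: np.ndarray, target: np.ndarray, candidates: np.ndarray) -> int:
    d = np.linalg.norm(points[candidates] - target, axis=1)
    return int(candidates[np.argmin(d)])


def _bone_name(x: float, y: float, spec: PhantomSpec) -> str:
    """Bone region of a flat-frame point, from the band dividers."""
    longi = [b for b in spec.sutures if b.axis == "longitudinal"]
    trans = [b for b in spec.sutures if b.axis == "transverse"]
    if longi:
        side = "left" if y >= longi[0].offset_at(x, spec.length) else "right"
    else:
        side = "left" if y >= spec.width / 2.0 else "right"
    xcs = [b.offset_at(y, spec.width) for b in trans]
    idx = int(np.sum(np.array(xcs) < x)) if xcs else 0
    if len(trans) == 2:
        region = _BONE_REGIONS[idx]
    else:
        region = f"region{idx}"
    return f"{region}_{side}"


def make_node_sets(mesh: TetMesh, spec: PhantomSpec) -> TetMesh:
    """Attach the named node sets the loading experiment uses.

    Bite sets are single nodes at peg tips (ventral surface); TMJ sets are
    single nodes at the posterior ventral corners (working = left, +y;
    balancing = right); muscle attachment sets are lateral surface
    patches; gauge seeds are single dorsal nodes (IFS-analog on the
    anterior transverse band, SGS-analog on the longitudinal band,
    PB-analog on bone >= 3 mm from every suture element); per-bone sets
    hold each bone's boundary-surface nodes, excluding any node touching
    a suture element.
    """
    flat = mesh.flat_nodes if mesh.flat_nodes is not None else mesh.nodes
    surf = mesh.surface_nodes()
    fx, fy, fz = flat[:, 0], flat[:, 1], flat[:, 2]
    sets: dict[str, np.ndarray] = {}

    # --- bite points: one node at each peg tip --------------------------
    for peg in spec.pegs:
        target = np.array([peg.x, peg.y, 0.0])
        ventral = surf[fz[surf] < spec.cell_sizes[2] / 4.0]
        if ventral.size == 0:
            raise ValueError("no ventral surface nodes for bite sets")
        node = _nearest_node(flat, target, ventral)
        sets[f"{peg.name}_bite"] = np.array([node], dtype=np.int64)

    # --- TMJ points: posterior ventral corners --------------------------
    for name, ytarget in (("tmj_working", spec.width), ("tmj_balancing", 0.0)):
        node = _nearest_node(flat, np.array([spec.length, ytarget, 0.0]), surf)
        sets[name] = np.array([node], dtype=np.int64)

    # --- muscle attachment patches ---------------------------------------
    # lateral walls, spanning the zygomatic-arch range (anterior of the
    # coronal band through the parietal region); the pure-lattice selection
    # keeps the left and right patches exact mirror images, which the
    # bilateral load case relies on
    x_lo, x_hi = 0.25 * spec.length, 0.78 * spec.length
    tol = 1e-9 * max(spec.length, spec.width, spec.thickness)
    for name, wall in (("muscle_attach_left", spec.width), ("muscle_attach_right", 0.0)):
        sel = surf[
            (np.abs(fy[surf] - wall) < tol)
            & (fx[surf] >= x_lo)
            & (fx[surf] <= x_hi)
        ]
        if sel.size == 0:
            raise ValueError(f"empty node set {name}")
        sets[name] = np.sort(sel)

    # --- gauge seed nodes ----------------------------------------------
    dorsal = surf[np.abs(fz[surf] - spec.thickness) < tol]
    if dorsal.size == 0:
        raise ValueError("no dorsal surface nodes for gauge sites")
    trans = [b for b in spec.sutures if b.axis == "transverse" and b.patent]
    longi = [b for b in spec.sutures if b.axis == "longitudinal" and b.patent]
    if trans:
        b = min(trans, key=lambda s: s.offset)  # anterior transverse band
        yg = 0.30 * spec.width
        xg = float(b.offset_at(yg, spec.width))
        sets["gauge_ifs"] = np.array(
            [_nearest_node(flat, np.array([xg, yg, spec.thickness]), dorsal)]
        )
    if longi:
        b = longi[0]
        xg = 0.60 * spec.length
        yg = float(b.offset_at(xg, spec.length))
        sets["gauge_sgs"] = np.array(
            [_nearest_node(flat, np.array([xg, yg, spec.thickness]), dorsal)]
        )

    suture_centroids = mesh.flat_centroids()[mesh.tissue == "suture"]
    if suture_centroids.shape[0] and dorsal.size:
        d, _ = cKDTree(suture_centroids[:, :2]).query(flat[dorsal][:, :2], workers=1)
        far = dorsal[d >= 3.0]
        if far.size == 0:
            raise ValueError(
                "no dorsal bone node lies >= 3 mm from the sutures; "
                "PB-analog gauge site impossible on this phantom"
            )
        # deterministic: the farthest-from-suture node, ties by index
        dfar = d[d >= 3.0]
        order = np.lexsort((far, -dfar))
        sets["gauge_pb"] = np.array([far[order[0]]], dtype=np.int64)

    # --- per-bone surface sets ------------------------------------------
    # nodes adjacent to any suture element are excluded ("suture-interior"
    # plus suture-interface nodes): at phantom resolution their averaged
    # values are dominated by the band, not the bone.
    touches_suture = np.zeros(mesh.n_nodes, dtype=bool)
    sut_el = mesh.elements[mesh.tissue == "suture"]
    touches_suture[np.unique(sut_el)] = True
    bone_nodes = surf[~touches_suture[surf]]
    names = np.array([_bone_name(fx[n], fy[n], spec) for n in bone_nodes])
    for bone in np.unique(names):
        sets[f"surface_{bone}"] = np.sort(bone_nodes[names == bone])

    for name, nodes in sets.items():
        if nodes.size == 0:
            raise ValueError(f"empty node set {name}")
        if nodes.min() < 0 or nodes.max() >= mesh.n_nodes:
            raise ValueError(f"node set {name} references invalid node indices")

    mesh.node_sets = sets
    return mesh


def default_spec(seed: int = 0, arch_curvature: float = 0.7) -> PhantomSpec:
    """The standard phantom used by the sutured-vs-fused experiment.

    A 40 x 20 x 1 mm arched shell at 100 x 50 x 3 cells (90k tetrahedra)
    — calvaria-like slenderness (t/L = 0.025), so suture-induced strain
    perturbations (which decay over about one thickness) stay local to
    the bands.  Carries an interdigitated sagittal band, an
    interdigitated coronal and a straight lambdoid transverse band (all
    0.8 mm = 2 cells wide), two incisor and two molar pegs, and a
    trabecular core over the middle third of the thickness.
    """
    w = 0.8  # two cells at the default grid
    sutures = (
        SutureBand("longitudinal", offset=10.0, width=w, amplitude=0.75,
                   wavelength=8.0, name="sagittal"),
        SutureBand("transverse", offset=18.0, width=w, amplitude=0.75,
                   wavelength=5.0, name="coronal"),
        SutureBand("transverse", offset=30.0, width=w, amplitude=0.0,
                   wavelength=0.0, name="lambdoid"),
    )
    pegs = (
        ToothPeg("incisor_left", x=2.5, y=12.5, radius=1.0, length=0.75,
                 pdl_thickness=0.45, pulp_radius=0.45),
        ToothPeg("incisor_right", x=2.5, y=7.5, radius=1.0, length=0.75,
                 pdl_thickness=0.45, pulp_radius=0.45),
        ToothPeg("molar_left", x=13.75, y=13.75, radius=1.0, length=0.75,
                 pdl_thickness=0.45, pulp_radius=0.45),
        ToothPeg("molar_right", x=13.75, y=6.25, radius=1.0, length=0.75,
                 pdl_thickness=0.45, pulp_radius=0.45),
    )
    return PhantomSpec(
        thickness=1.0,
        nx=100,
        ny=50,
        nz=3,
        sutures=sutures,
        pegs=pegs,
        trabecular_fraction=1.0 / 3.0,
        arch_curvature=arch_curvature,
        jitter=0.0,
        seed=seed,
    )


def build_phantom(spec: PhantomSpec) -> TetMesh:
    """Full pipeline: lattice -> tetrahedra -> labels -> node sets."""
    grid = build_hex_grid(spec)
    mesh = hex_to_tets(grid)
    mesh = label_regions(mesh, spec)
    mesh = make_node_sets(mesh, spec)
    return mesh
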