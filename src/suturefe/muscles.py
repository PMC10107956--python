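"""Muscle architecture, PCSA forces, strand discretization, wrapped paths.

Maximal isometric force follows the standard physiological
cross-sectional-area route:

    PCSA [cm^2] = mass [g] * cos(pennation) / (fibre length [cm] * rho)
    F_max [N]   = PCSA * sigma_m

with fibre density rho = 1.06 g cm^-3 and an intrinsic muscle stress
sigma_m = 25 N cm^-2.  Parallel-fibred muscles record pennation 0, so the
cos(0) = 1 path is exact.

Each muscle is discretized into strands that carry F_max / n_strands from
an origin node on the cranial surface toward an insertion point on the
(virtual) mandible.  Muscles that wrap over the vault are modelled as a
frictionless inextensible string under uniform tension: every via point
receives the contact force T * (t_out - t_in) of the two adjacent unit
tangents, the proximal anchor receives +T along its outgoing segment and
the most distal node -T along its incoming segment, so the emitted force
system is closed (zero net force and moment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIBRE_DENSITY = 1.06  # g cm^-3
MUSCLE_STRESS = 25.0  # N cm^-2


@dataclass(frozen=True)
class MuscleSpec:
    """Architecture plus geometric attachment of one muscle (one side)."""

    name: str
    mass: float  # g
    pennation: float  # deg; 0 for parallel-fibred muscles
    fibre_length: float  # cm
    fibre_density: float = FIBRE_DENSITY  # g cm^-3
    muscle_stress: float = MUSCLE_STRESS  # N cm^-2
    n_strands: int = 1
    origin_nodes: tuple[int, ...] = ()  # node indices of the origin patch
    insertion_points: tuple[tuple[float, float, float], ...] = ()  # mm
    wrap_polyline: tuple[tuple[float, float, float], ...] = ()  # via points, mm

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.fibre_length > 0):
            raise ValueError(f"{self.name}: mass and fibre length must be > 0")
        if not (0.0 <= self.pennation < 90.0):
            raise ValueError(f"{self.name}: pennation must lie in [0, 90) deg")
        if self.fibre_density <= 0:
            raise ValueError(f"{self.name}: fibre density must be > 0")
        if self.n_strands < 1:
            raise ValueError(f"{self.name}: n_strands must be >= 1")
        if self.wrap_polyline and len(self.wrap_polyline) < 2:
            raise ValueError(f"{self.name}: wrap polyline needs >= 2 points")


@dataclass(frozen=True)
class StrandLoad:
    """A nodal point force, in N, applied at a mesh node."""

    node: int
    force: np.ndarray  # (3,)
    muscle: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float)
        if f.shape != (3,) or not np.all(np.isfinite(f)):
            raise ValueError("strand force must be a finite 3-vector")
        object.__setattr__(self, "force", f)


def compute_pcsa(spec: MuscleSpec) -> float:
    """Physiological cross-sectional area in cm^2."""
    alpha = np.deg2rad(spec.pennation)
    return spec.mass * np.cos(alpha) / (spec.fibre_length * spec.fibre_density)


def max_isometric_force(pcsa: float, muscle_stress: float = MUSCLE_STRESS) -> float:
    """F_max = PCSA * sigma_m, in N."""
    if pcsa < 0:
        raise ValueError("PCSA must be >= 0")
    return pcsa * muscle_stress


def discretize_strands(
    spec: MuscleSpec, f_max: float, node_coords: np.ndarray
) -> list[StrandLoad]:
    """Split F_max evenly over n_strands origin->insertion strands.

    Origins are picked deterministically, evenly spaced by index over the
    muscle's origin node set; each strand is paired with an insertion
    point (a single insertion serves all strands) and pulls its origin
    node toward it with magnitude F_max / n_strands.
    """
    if not spec.origin_nodes:
        raise ValueError(f"{spec.name}: empty origin node set")
    if len(spec.origin_nodes) < spec.n_strands:
        raise ValueError(
            f"{spec.name}: origin set has {len(spec.origin_nodes)} nodes "
            f"< n_strands = {spec.n_strands}"
        )
    if not spec.insertion_points:
        raise ValueError(f"{spec.name}: no insertion points")
    idx = np.round(
        np.linspace(0, len(spec.origin_nodes) - 1, spec.n_strands)
    ).astype(int)
    origins = [spec.origin_nodes[i] for i in idx]
    insertions = list(spec.insertion_points)
    if len(insertions) == 1:
        insertions = insertions * spec.n_strands
    if len(insertions) != spec.n_strands:
        raise ValueError(
            f"{spec.name}: need 1 or n_strands insertion points, "
            f"got {len(spec.insertion_points)}"
        )
    per_strand = f_max / spec.n_strands
    loads = []
    for node, target in zip(origins, insertions):
        vec = np.asarray(target, dtype=float) - node_coords[node]
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            raise ValueError(f"{spec.name}: strand origin coincides with insertion")
        loads.append(StrandLoad(node=int(node), force=per_strand * vec / norm,
                                muscle=spec.name))
    return loads


def wrapped_path_nodal_forces(
    polyline: np.ndarray, tension: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Nodal forces of a frictionless string under uniform tension.

    ``polyline`` is (m, 3), proximal anchor first, most distal point last.
    Returns ``[(point, force), ...]`` for every polyline point.  Negative
    tension is clamped to 0 (tension-only element).  The emitted system
    is closed: forces sum to zero and carry zero net moment.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be (m >= 2, 3)")
    T = max(float(tension), 0.0)
    seg = np.diff(pts, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths == 0.0):
        raise ValueError(f"zero-length segment at index {int(np.argmin(lengths))}")
    tangents = seg / lengths[:, None]
    forces = np.zeros_like(pts)
    forces[0] = T * tangents[0]  # proximal anchor: pulled along the path
    forces[-1] = -T * tangents[-1]  # distal end: full tension, pulling back
    for i in range(1, pts.shape[0] - 1):
        forces[i] = T * (tangents[i] - tangents[i - 1])  # wrap contact force
    return [(pts[i], forces[i]) for i in range(pts.shape[0])]


@dataclass(frozen=True)
class MuscleTableRow:
    """One row of the user-facing muscle architecture table."""

    name: str
    mass_g: float
    pennation_deg: float
    fibre_length_cm: float
    n_strands: int = 1
    wrap: bool = False


def load_muscle_csv(path) -> list[MuscleTableRow]:
    """Read a muscle architecture table (CSV) into table rows.

    Columns: name, mass_g, pennation_deg, fibre_length_cm, n_strands, wrap.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "mass_g", "pennation_deg", "fibre_length_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"muscle CSV missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            MuscleTableRow(
                name=str(r["name"]),
                mass_g=float(r["mass_g"]),
                pennation_deg=float(r["pennation_deg"]),
                fibre_length_cm=float(r["fibre_length_cm"]),
                n_strands=int(r.get("n_strands", 1)),
                wrap=bool(r.get("wrap", False)),
            )
        )
    return rows
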