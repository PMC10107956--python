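"""Run configuration: YAML parsing, defaults, validation.

An empty config is valid and yields the full default experiment (default
phantom, default tissue table, placeholder muscle architecture, both
bite load cases).  Unknown keys and out-of-range values are rejected
with messages naming the field.

The default muscle architecture values (mass, pennation, fibre length)
are plausible placeholders for an adult rat, not measurements; studies
with their own dissection data should override them via the ``muscles``
section or a CSV table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .materials import TISSUES
from .muscles import MuscleTableRow, load_muscle_csv
from .phantom import PhantomSpec, SutureBand, ToothPeg, default_spec

LOAD_CASE_NAMES = ("incisor_bilateral", "molar_unilateral")

DEFAULT_MUSCLES = (
    MuscleTableRow("temporalis", mass_g=1.1, pennation_deg=20.0,
                   fibre_length_cm=1.1, n_strands=1, wrap=True),
    MuscleTableRow("masseter", mass_g=1.5, pennation_deg=25.0,
                   fibre_length_cm=0.9, n_strands=4, wrap=False),
)

_PHANTOM_KEYS = {
    "length", "width", "thickness", "nx", "ny", "nz", "arch_curvature",
    "trabecular_fraction", "jitter", "seed", "sutures", "pegs",
}
_TOP_KEYS = {
    "phantom", "materials", "muscles", "load_cases", "element_order",
    "outdir", "seed", "log_level", "write_vtk",
}


@dataclass
class RunConfig:
    """Validated configuration of one sutured-vs-fused experiment."""

    phantom: PhantomSpec
    material_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    muscles: tuple[MuscleTableRow, ...] = DEFAULT_MUSCLES
    load_cases: tuple[str, ...] = LOAD_CASE_NAMES
    element_order: str = "tet4"
    outdir: Path = Path("suturefe_out")
    seed: int = 0
    log_level: str = "INFO"
    write_vtk: bool = True


def _build_phantom_spec(raw: dict, seed: int) -> PhantomSpec:
    unknown = set(raw) - _PHANTOM_KEYS
    if unknown:
        raise ValueError(f"phantom: unknown keys {sorted(unknown)}")
    base = default_spec(seed=raw.get("seed", seed))
    kwargs = {k: v for k, v in raw.items() if k not in ("sutures", "pegs")}
    if "sutures" in raw:
        kwargs["sutures"] = tuple(SutureBand(**b) for b in raw["sutures"])
    if "pegs" in raw:
        kwargs["pegs"] = tuple(ToothPeg(**p) for p in raw["pegs"])
    from dataclasses import replace

    return replace(base, **kwargs)


def validate_config(raw, base_dir: Path | None = None) -> RunConfig:
    """Build a RunConfig from a YAML string / mapping, filling defaults.

    ``base_dir`` resolves relative paths (muscle CSV, output directory).
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    base_dir = Path(base_dir) if base_dir else Path.cwd()

    seed = int(raw.get("seed", 0))
    phantom = _build_phantom_spec(raw.get("phantom") or {}, seed)

    overrides = {}
    for tissue, pair in (raw.get("materials") or {}).items():
        if tissue not in TISSUES:
            raise ValueError(f"materials: unknown tissue {tissue!r}")
        E, nu = float(pair[0]), float(pair[1])
        if not E > 0:
            raise ValueError(f"materials.{tissue}: E must be > 0")
        if not (0.0 <= nu < 0.5):
            raise ValueError(
                f"materials.{tissue}: Poisson's ratio {nu} must lie in [0, 0.5)"
            )
        overrides[tissue] = (E, nu)

    muscles_raw = raw.get("muscles")
    if muscles_raw is None:
        muscles = DEFAULT_MUSCLES
    elif isinstance(muscles_raw, dict) and "csv" in muscles_raw:
        path = base_dir / muscles_raw["csv"]
        if not path.exists():
            raise ValueError(f"muscles.csv: file not found: {path}")
        muscles = tuple(load_muscle_csv(path))
    elif isinstance(muscles_raw, list):
        muscles = tuple(
            MuscleTableRow(
                name=str(m["name"]),
                mass_g=float(m["mass_g"]),
                pennation_deg=float(m["pennation_deg"]),
                fibre_length_cm=float(m["fibre_length_cm"]),
                n_strands=int(m.get("n_strands", 1)),
                wrap=bool(m.get("wrap", False)),
            )
            for m in muscles_raw
        )
    else:
        raise ValueError("muscles: expected a list of rows or {csv: path}")
    if not muscles:
        raise ValueError("muscles: at least one muscle is required")

    cases = tuple(raw.get("load_cases") or LOAD_CASE_NAMES)
    if not cases:
        raise ValueError("load_cases: at least one load case is required")
    for c in cases:
        if c not in LOAD_CASE_NAMES:
            raise ValueError(
                f"load_cases: unknown case {c!r}; expected {LOAD_CASE_NAMES} "
                "(custom cases are built through the library API)"
            )

    order = str(raw.get("element_order", "tet4"))
    if order == "tet10":
        raise NotImplementedError(
            "element_order: tet10 is not implemented in this build; use tet4"
        )
    if order != "tet4":
        raise ValueError(f"element_order: unknown order {order!r}")

    return RunConfig(
        phantom=phantom,
        material_overrides=overrides,
        muscles=muscles,
        load_cases=cases,
        element_order=order,
        outdir=base_dir / str(raw.get("outdir", "suturefe_out")),
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        write_vtk=bool(raw.get("write_vtk", True)),
    )
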