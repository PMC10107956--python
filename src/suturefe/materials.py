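"""Tissue material model for the cranial loading experiments.

All tissues are homogeneous, linear elastic and isotropic.  Moduli are
stored in MPa and lengths everywhere in the package are mm, so forces come
out in N and stresses in MPa (consistent mm-N-MPa unit system).

The experiment compares two material variants on the *same* mesh:

``sutured``
    every tissue keeps its own properties (patent sutures are three orders
    of magnitude more compliant than cortical bone);
``fused``
    the suture entry is overwritten with the cortical-bone properties,
    which is the standard in-silico model of complete suture fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TISSUES = ("cortical", "trabecular", "suture", "tooth", "pulp", "pdl")

#: Nano-indentation-derived defaults: tissue -> (Young's modulus E [MPa],
#: Poisson's ratio nu).  Teeth use enamel properties for the combined
#: enamel+dentine structure.
_DEFAULTS = {
    "cortical": (19920.0, 0.3),
    "trabecular": (56.0, 0.3),
    "suture": (20.0, 0.49),
    "tooth": (62370.0, 0.33),
    "pulp": (2.0, 0.45),
    "pdl": (50.0, 0.49),
}

VARIANTS = ("sutured", "fused")


@dataclass(frozen=True)
class MaterialTable:
    """Mapping tissue label -> (E [MPa], nu), tagged with the variant."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    variant: str = "sutured"

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES if t not in self.entries]
        if missing:
            raise ValueError(f"material table missing tissues: {missing}")
        for tissue, (E, nu) in self.entries.items():
            if not E > 0:
                raise ValueError(f"{tissue}: Young's modulus must be > 0, got {E}")
            if not (0.0 <= nu < 0.5):
                raise ValueError(
                    f"{tissue}: Poisson's ratio must lie in [0, 0.5), got {nu}"
                )
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {VARIANTS}")

    def __getitem__(self, tissue: str) -> tuple[float, float]:
        return self.entries[tissue]

    def bulk_modulus(self, tissue: str) -> float:
        """K = E / (3(1 - 2 nu)); finite for every admissible entry."""
        E, nu = self.entries[tissue]
        return E / (3.0 * (1.0 - 2.0 * nu))


def default_material_table(
    overrides: dict[str, tuple[float, float]] | None = None,
) -> MaterialTable:
    """Default tissue table, optionally with per-tissue ``(E, nu)`` overrides."""
    entries = dict(_DEFAULTS)
    for tissue, pair in (overrides or {}).items():
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        E, nu = float(pair[0]), float(pair[1])
        entries[tissue] = (E, nu)
    return MaterialTable(entries=entries, variant="sutured")


def apply_variant(table: MaterialTable, variant: str) -> MaterialTable:
    """Return the table for an experimental variant.

    ``sutured`` is the identity; ``fused`` re-assigns the cortical-bone
    properties to the sutures and leaves every other tissue untouched.
    Idempotent for both variants.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
    entries = dict(table.entries)
    if variant == "fused":
        entries["suture"] = entries["cortical"]
    return MaterialTable(entries=entries, variant=variant)


def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """Convert (E, nu) to the Lame pair (lambda, mu).

    mu = E / (2(1+nu)), lambda = E nu / ((1+nu)(1-2nu)).  The
    incompressible limit nu = 0.5 is rejected (lambda diverges).
    """
    if not E > 0:
        raise ValueError(f"Young's modulus must be > 0, got {E}")
    if not (-1.0 < nu < 0.5):
        raise ValueError(f"Poisson's ratio must lie in (-1, 0.5), got {nu}")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu
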