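"""End-to-end sutured-vs-fused experiment on a phantom.

One call runs the whole protocol: build the labelled phantom, derive
muscle forces from architecture (PCSA), transfer them onto the mesh as
strand and wrapped-path nodal loads, cross-check each load case against
the determinate rigid-body bite prediction, run the finite-element
solve twice per load case (patent sutures vs. fused), post-process
principal strains, virtual gauges, per-bone surface summaries and
difference fields, and write VTK/CSV/JSON artifacts.

The sutured/fused pair is always run together — the comparison *is* the
experiment — and the report is byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .fem import LoadCase, assemble, reaction_sum, recover_strains, solve
from .materials import apply_variant, default_material_table
from .muscles import (
    MuscleSpec,
    MuscleTableRow,
    compute_pcsa,
    discretize_strands,
    max_isometric_force,
    wrapped_path_nodal_forces,
)
from .phantom import TetMesh, _arch_map, build_phantom
from .statics import BiteScenario, solve_bilateral_bite, solve_unilateral_bite
from .strain import (
    bone_surface_summary,
    difference_fields,
    principal_field,
    virtual_gauge,
)
from .vtk_io import export_vtk

logger = logging.getLogger(__name__)

VARIANTS = ("sutured", "fused")
GAUGE_SITES = ("gauge_ifs", "gauge_sgs", "gauge_pb")


def _map_point(flat_point, spec) -> np.ndarray:
    return _arch_map(np.asarray(flat_point, dtype=float)[None, :], spec)[0]


def _snap_to_set(mesh: TetMesh, flat_target, candidates: np.ndarray) -> int:
    flat = mesh.flat_nodes if mesh.flat_nodes is not None else mesh.nodes
    d = np.linalg.norm(flat[candidates] - np.asarray(flat_target), axis=1)
    return int(candidates[np.argmin(d)])


def build_muscle_loads(
    mesh: TetMesh, spec, muscles: tuple[MuscleTableRow, ...]
) -> list[tuple[int, np.ndarray]]:
    """Nodal muscle loads on the cranium phantom, both sides.

    Direct (non-wrapping, "masseter-analog") muscles become strand loads
    from the lateral attachment patches toward an insertion point on the
    virtual mandible below the plate.  Wrapping ("temporalis-analog")
    muscles run as a frictionless-string polyline over the vault and down
    the lateral wall; every polyline force except the distal (insertion,
    off-mesh) one is applied to the cranium, so the cranium receives the
    wrap contact forces plus the anchor pull and, in total, the tension
    directed along the final segment toward the mandible.

    Returns per-node aggregated ``(node, force)`` loads; the identical
    list feeds both the FE load cases and the rigid-statics scenarios.
    """
    L, W, t = spec.length, spec.width, spec.thickness
    acc: dict[int, np.ndarray] = {}

    def add(node: int, force: np.ndarray) -> None:
        acc[node] = acc.get(node, np.zeros(3)) + force

    surf = mesh.surface_nodes()
    for row in muscles:
        mspec = MuscleSpec(
            name=row.name,
            mass=row.mass_g,
            pennation=row.pennation_deg,
            fibre_length=row.fibre_length_cm,
            n_strands=row.n_strands,
        )
        f_max = max_isometric_force(compute_pcsa(mspec))
        for side, sgn in (("left", 1.0), ("right", -1.0)):
            ymirror = (lambda y: y) if side == "left" else (lambda y: W - y)
            wall_y = W if side == "left" else 0.0
            if row.wrap:
                # via points over the vault at one x station, ending at the
                # lateral dorsal edge; insertion on the mandible beyond it
                xw = 0.609 * L
                ys = [0.5625 * W, 0.6875 * W, 0.8125 * W, 0.9375 * W, W]
                nodes = []
                for y in ys:
                    n = _snap_to_set(mesh, (xw, ymirror(y), t), surf)
                    if not nodes or n != nodes[-1]:
                        nodes.append(n)
                insertion = _map_point((xw, wall_y, 0.0), spec) + np.array(
                    [0.0, sgn * 2.0, -7.0]
                )
                polyline = np.vstack([mesh.nodes[nodes], insertion])
                emitted = wrapped_path_nodal_forces(polyline, f_max)
                for n, (_, force) in zip(nodes, emitted[:-1]):
                    add(n, force)
                logger.info(
                    "%s %s: wrapped path, tension %.2f N over %d via nodes",
                    row.name, side, f_max, len(nodes),
                )
            else:
                origin_nodes = tuple(
                    int(n) for n in mesh.node_sets[f"muscle_attach_{side}"]
                )
                insertion = _map_point((0.656 * L, wall_y, 0.0), spec) + np.array(
                    [0.0, sgn * 1.0, -7.0]
                )
                strands = discretize_strands(
                    MuscleSpec(
                        name=f"{row.name}_{side}",
                        mass=row.mass_g,
                        pennation=row.pennation_deg,
                        fibre_length=row.fibre_length_cm,
                        n_strands=row.n_strands,
                        origin_nodes=origin_nodes,
                        insertion_points=(tuple(insertion),),
                    ),
                    f_max,
                    mesh.nodes,
                )
                for s in strands:
                    add(s.node, s.force)
                logger.info(
                    "%s %s: %d strands, total %.2f N",
                    row.name, side, row.n_strands, f_max,
                )
    return [(n, acc[n]) for n in sorted(acc)]


def build_load_case(
    mesh: TetMesh, name: str, muscle_loads: list[tuple[int, np.ndarray]]
) -> LoadCase:
    """FE load case mirroring the bite constraint scheme.

    Bilateral incisor biting: one node on each incisor constrained
    vertically.  Unilateral posterior biting: one node on the left first
    molar constrained vertically.  Both: the balancing-side TMJ node
    fixed in all three directions, the working-side TMJ node in the
    anterior-posterior (x) and dorsoventral (z) directions only.
    """
    lc = LoadCase(name=name)
    for node, force in muscle_loads:
        lc.add_load(node, force)
    if name == "incisor_bilateral":
        for s in ("incisor_left_bite", "incisor_right_bite"):
            lc.fix(int(mesh.node_sets[s][0]), "z")
    elif name == "molar_unilateral":
        lc.fix(int(mesh.node_sets["molar_left_bite"][0]), "z")
    else:
        raise ValueError(f"unknown load case {name!r}")
    lc.fix_all(int(mesh.node_sets["tmj_balancing"][0]))
    lc.fix(int(mesh.node_sets["tmj_working"][0]), "x")
    lc.fix(int(mesh.node_sets["tmj_working"][0]), "z")
    return lc


def bite_nodes(mesh: TetMesh, name: str) -> np.ndarray:
    if name == "incisor_bilateral":
        return np.concatenate(
            [mesh.node_sets["incisor_left_bite"], mesh.node_sets["incisor_right_bite"]]
        )
    if name == "molar_unilateral":
        return mesh.node_sets["molar_left_bite"]
    raise ValueError(f"unknown load case {name!r}")


def build_bite_scenario(
    mesh: TetMesh, name: str, muscle_loads: list[tuple[int, np.ndarray]]
) -> BiteScenario:
    """Rigid-statics analog of a load case, from the same nodal loads."""
    forces = tuple((mesh.nodes[n].copy(), f.copy()) for n, f in muscle_loads)
    bp = mesh.nodes[bite_nodes(mesh, name)].mean(axis=0)
    return BiteScenario(
        bite_point=bp,
        tmj_working=mesh.nodes[int(mesh.node_sets["tmj_working"][0])].copy(),
        tmj_balancing=mesh.nodes[int(mesh.node_sets["tmj_balancing"][0])].copy(),
        muscle_forces=forces,
        laterality="bilateral" if name == "incisor_bilateral" else "unilateral",
    )


def solve_statics(scenario: BiteScenario):
    if scenario.laterality == "bilateral":
        return solve_bilateral_bite(scenario)
    return solve_unilateral_bite(scenario)


@dataclass
class RunReport:
    """Serializable results plus in-memory artifacts for further analysis."""

    data: dict
    artifacts: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2)


def _gauge_rows(mesh, pf, case, variant):
    rows = []
    for site in GAUGE_SITES:
        if site not in mesh.node_sets:
            continue
        g = virtual_gauge(mesh, pf, site)
        rows.append(
            dict(load_case=case, variant=variant, site=site,
                 mean_eps1=g.mean_eps1, sd_eps1=g.sd_eps1,
                 mean_eps3=g.mean_eps3, sd_eps3=g.sd_eps3,
                 n_nodes=g.n_nodes, patch_area=g.patch_area)
        )
    return rows


def _bone_rows(mesh, pf, case, variant):
    rows = []
    for key in sorted(mesh.node_sets):
        if not key.startswith("surface_"):
            continue
        s = bone_surface_summary(mesh, pf, key)
        rows.append(
            dict(load_case=case, variant=variant, bone=s.bone,
                 mean_eps1=s.mean_eps1, sd_eps1=s.sd_eps1,
                 mean_eps3=s.mean_eps3, sd_eps3=s.sd_eps3, n_nodes=s.n_nodes)
        )
    return rows


def run_experiment(config: RunConfig) -> RunReport:
    """Run the full experiment described by ``config``.

    For every requested load case both material variants are solved on
    the identical mesh; a lone-variant run is not expressible.  Outputs
    (report.json, summary.csv, gauges.csv and per-case VTK files) land in
    ``config.outdir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage phantom: building %dx%dx%d grid",
                config.phantom.nx, config.phantom.ny, config.phantom.nz)
    mesh = build_phantom(config.phantom)
    logger.info("phantom: %d nodes, %d elements", mesh.n_nodes, mesh.n_elements)

    base = default_material_table(config.material_overrides)
    tables = {v: apply_variant(base, v) for v in VARIANTS}
    muscle_loads = build_muscle_loads(mesh, config.phantom, config.muscles)
    total_f = np.sum([f for _, f in muscle_loads], axis=0)
    logger.info("muscle loads: %d loaded nodes, net force %s N",
                len(muscle_loads), np.round(total_f, 3))

    stiffness = {}
    for v in VARIANTS:
        logger.info("stage assemble (%s): %d DOF", v, 3 * mesh.n_nodes)
        stiffness[v] = assemble(mesh, tables[v])

    report: dict = {
        "software": {"name": "suturefe", "version": __version__},
        "config": {
            "phantom": asdict(config.phantom),
            "material_overrides": {
                k: list(v) for k, v in config.material_overrides.items()
            },
            "muscles": [asdict(m) for m in config.muscles],
            "load_cases": list(config.load_cases),
            "element_order": config.element_order,
            "seed": config.seed,
        },
        "mesh": {
            "n_nodes": int(mesh.n_nodes),
            "n_elements": int(mesh.n_elements),
            "tissue_counts": {
                t: int(np.sum(mesh.tissue == t)) for t in np.unique(mesh.tissue)
            },
        },
        "cases": {},
        "files": [],
    }
    artifacts = {"mesh": mesh, "muscle_loads": muscle_loads, "cases": {}}
    gauge_rows: list[dict] = []
    bone_rows: list[dict] = []

    for case in config.load_cases:
        logger.info("stage load case %s", case)
        lc = build_load_case(mesh, case, muscle_loads)
        scenario = build_bite_scenario(mesh, case, muscle_loads)
        stat = solve_statics(scenario)
        case_data: dict = {
            "statics": {
                "bite_force": stat.bite_force,
                "working_reaction": stat.working_reaction.tolist(),
                "balancing_reaction": stat.balancing_reaction.tolist(),
                "residual": stat.residual,
            },
            "variants": {},
        }
        case_art: dict = {"load_case": lc, "scenario": scenario, "statics": stat,
                          "variants": {}}

        fields = {}
        for v in VARIANTS:
            logger.info("stage solve %s / %s", case, v)
            res = solve(mesh, tables[v], lc, K=stiffness[v])
            strain = recover_strains(mesh, res.displacement)
            pf = principal_field(mesh, strain)
            fields[v] = pf
            bn = bite_nodes(mesh, case)
            bite_z = reaction_sum(res.reactions, bn, axis=2)
            tmj = {
                "working": [
                    res.reactions.get((int(mesh.node_sets["tmj_working"][0]), a), 0.0)
                    for a in range(3)
                ],
                "balancing": [
                    res.reactions.get((int(mesh.node_sets["tmj_balancing"][0]), a), 0.0)
                    for a in range(3)
                ],
            }
            g_rows = _gauge_rows(mesh, pf, case, v)
            b_rows = _bone_rows(mesh, pf, case, v)
            gauge_rows += g_rows
            bone_rows += b_rows
            case_data["variants"][v] = {
                "fe_bite_reaction": bite_z,
                "fe_tmj_reactions": tmj,
                "solver_residual": res.residual,
                "gauges": g_rows,
                "bones": b_rows,
            }
            case_art["variants"][v] = {
                "solution": res,
                "strain": strain,
                "principal": pf,
            }

        diffs = difference_fields(fields["fused"], fields["sutured"])
        case_data["difference_extrema"] = {
            k: [float(v.min()), float(v.max())] for k, v in diffs.items()
        }
        case_data["statics_vs_fe_gap"] = {
            v: abs(case_data["variants"][v]["fe_bite_reaction"] - stat.bite_force)
            / abs(stat.bite_force)
            for v in VARIANTS
        }
        case_art["differences"] = diffs

        if config.write_vtk:
            path = outdir / f"{case}.vtk"
            pf_s, pf_f = fields["sutured"], fields["fused"]
            export_vtk(
                mesh,
                path,
                cell_fields={
                    "eps1_sutured": pf_s.element_principals[:, 0],
                    "eps3_sutured": pf_s.element_principals[:, 2],
                    "eps1_fused": pf_f.element_principals[:, 0],
                    "eps3_fused": pf_f.element_principals[:, 2],
                    "dominance_sutured": pf_s.dominance,
                    **diffs,
                },
                point_fields={
                    "nodal_eps1_sutured": pf_s.nodal_eps1,
                    "nodal_eps3_sutured": pf_s.nodal_eps3,
                },
                displacement=case_art["variants"]["sutured"]["solution"]
                .displacement.u,
                title=f"suturefe {case}",
            )
            case_data["vtk"] = path.name
            report["files"].append(path.name)

        report["cases"][case] = case_data
        artifacts["cases"][case] = case_art

    gauges_df = pd.DataFrame(gauge_rows)
    bones_df = pd.DataFrame(bone_rows)
    gauges_df.to_csv(outdir / "gauges.csv", index=False)
    bones_df.to_csv(outdir / "summary.csv", index=False)
    report["files"] += ["gauges.csv", "summary.csv", "report.json"]
    rep = RunReport(data=report, artifacts=artifacts)
    (outdir / "report.json").write_text(rep.to_json() + "\n")
    logger.info("experiment complete: %s", outdir)
    return rep
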