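"""Determinate rigid-body bite-force prediction.

The cranium is treated as a rigid, massless body in static equilibrium
under the muscle-derived nodal loads, a vertical bite reaction at the
bite point and reactions at the two jaw joints (TMJs).  The unknown
reaction components mirror the finite-element constraint scheme exactly:

* unilateral biting — 6 unknowns for the 6 equilibrium equations:
  vertical bite force, full 3-component reaction at the balancing-side
  TMJ, and anterior-posterior (x) + dorsoventral (z) components at the
  working-side TMJ (the mediolateral DOF is free there);
* bilateral biting — symmetric about the sagittal plane, reduced to the
  3 in-plane equations for the vertical bite force and the (x, z)
  reaction at the joint-axis midpoint.

Because the unilateral unknowns coincide with the FE constrained DOFs,
the FE reaction forces must reproduce this solution, which makes the two
modules cross-checks of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BiteScenario:
    """Geometry and loading of one static bite analysis.

    ``muscle_forces`` is a list of ``(application point [mm], force [N])``
    pairs — the same nodal loads the FE model receives.
    """

    bite_point: np.ndarray  # (3,) mm
    tmj_working: np.ndarray  # (3,) mm
    tmj_balancing: np.ndarray  # (3,) mm
    muscle_forces: tuple  # ((point, force), ...)
    bite_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    laterality: str = "bilateral"

    def __post_init__(self) -> None:
        for name in ("bite_point", "tmj_working", "tmj_balancing", "bite_direction"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        if not np.isclose(np.linalg.norm(self.bite_direction), 1.0):
            raise ValueError("bite direction must be unit-norm")
        if self.laterality not in ("bilateral", "unilateral"):
            raise ValueError(f"unknown laterality {self.laterality!r}")


@dataclass(frozen=True)
class BiteSolution:
    """Solved reactions; residuals are checked before returning."""

    bite_force: float  # N, component along the bite direction
    working_reaction: np.ndarray  # (3,) N; free DOFs are exactly 0
    balancing_reaction: np.ndarray  # (3,) N
    residual: float  # max |force, moment residual| relative to the load scale


def _load_resultants(muscle_forces) -> tuple[np.ndarray, np.ndarray, float]:
    """Net force, net moment about the origin, and a load scale."""
    F = np.zeros(3)
    M = np.zeros(3)
    scale = 0.0
    for point, force in muscle_forces:
        p = np.asarray(point, dtype=float)
        f = np.asarray(force, dtype=float)
        F += f
        M += np.cross(p, f)
        scale += np.linalg.norm(f)
    return F, M, max(scale, 1e-30)


def _equilibrium_residuals(scenario: BiteScenario, sol: BiteSolution) -> np.ndarray:
    """Relative residuals (Fx, Fy, Fz, Mx, My, Mz) of a solution."""
    F, M, scale = _load_resultants(scenario.muscle_forces)
    d = scenario.bite_direction
    F_tot = F + sol.bite_force * d + sol.working_reaction + sol.balancing_reaction
    M_tot = (
        M
        + np.cross(scenario.bite_point, sol.bite_force * d)
        + np.cross(scenario.tmj_working, sol.working_reaction)
        + np.cross(scenario.tmj_balancing, sol.balancing_reaction)
    )
    # moment residual scaled by a characteristic arm length
    arm = max(
        np.linalg.norm(scenario.bite_point - scenario.tmj_balancing), 1e-30
    )
    return np.concatenate([np.abs(F_tot) / scale, np.abs(M_tot) / (scale * arm)])


def _check_equilibrium(scenario: BiteScenario, sol: BiteSolution) -> float:
    return float(_equilibrium_residuals(scenario, sol).max())


def solve_unilateral_bite(scenario: BiteScenario) -> BiteSolution:
    """Solve the full 6x6 static system of a unilateral bite.

    Unknowns: [bite force along the bite direction, balancing reaction
    (x, y, z), working reaction (x, z)].  Raises on rank-deficient
    geometry, reporting the condition number.
    """
    F, M, scale = _load_resultants(scenario.muscle_forces)
    d = scenario.bite_direction
    pb, pw, pbal = scenario.bite_point, scenario.tmj_working, scenario.tmj_balancing

    ex, ey, ez = np.eye(3)
    # columns: the force each unknown contributes, with application point
    columns = [
        (d, pb),
        (ex, pbal), (ey, pbal), (ez, pbal),
        (ex, pw), (ez, pw),
    ]
    A = np.zeros((6, 6))
    for j, (direction, point) in enumerate(columns):
        A[:3, j] = direction
        A[3:, j] = np.cross(point, direction)
    rhs = -np.concatenate([F, M])

    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"rank-deficient bite geometry (condition number {cond:.3e}); "
            "check that bite point and TMJs are non-collinear"
        )
    q = np.linalg.solve(A, rhs)
    sol = BiteSolution(
        bite_force=float(q[0]),
        balancing_reaction=q[1:4].copy(),
        working_reaction=np.array([q[4], 0.0, q[5]]),
        residual=0.0,
    )
    res = _check_equilibrium(scenario, sol)
    if res > 1e-9:
        raise ValueError(f"unilateral bite solution failed equilibrium: {res:.3e}")
    return BiteSolution(sol.bite_force, sol.working_reaction,
                        sol.balancing_reaction, res)


def solve_bilateral_bite(scenario: BiteScenario) -> BiteSolution:
    """Solve the sagittal-plane (x-z) equilibrium of a symmetric bite.

    The bite direction must be vertical and the muscle system symmetric
    about the sagittal plane (out-of-plane resultants are checked).  The
    joint reaction is resolved at the TMJ-axis midpoint and reported
    split evenly between the two joints.
    """
    if not np.allclose(scenario.bite_direction, [0.0, 0.0, 1.0]):
        raise ValueError("bilateral bite requires a vertical bite direction")
    F, M, scale = _load_resultants(scenario.muscle_forces)
    arm = max(np.linalg.norm(scenario.bite_point - scenario.tmj_balancing), 1e-30)
    pj = 0.5 * (scenario.tmj_working + scenario.tmj_balancing)
    # out-of-plane resultants about a point in the sagittal plane must vanish
    M_ref = M - np.cross(pj, F)
    if abs(F[1]) > 1e-6 * scale or max(abs(M_ref[0]), abs(M_ref[2])) > 1e-6 * scale * arm:
        raise ValueError(
            "muscle system is not symmetric about the sagittal plane; "
            "use solve_unilateral_bite"
        )
    pb = scenario.bite_point
    # unknowns: [bite Fz, joint Rx, joint Rz]; equations: Fx, Fz, My
    A = np.array(
        [
            [0.0, 1.0, 0.0],
            [1.0, 0.0, 1.0],
            [-pb[0], pj[2], -pj[0]],
        ]
    )
    rhs = -np.array([F[0], F[2], M[1]])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular bilateral bite geometry (condition number {cond:.3e})"
        )
    q = np.linalg.solve(A, rhs)
    joint = np.array([q[1], 0.0, q[2]])
    sol = BiteSolution(
        bite_force=float(q[0]),
        working_reaction=0.5 * joint,
        balancing_reaction=0.5 * joint,
        residual=0.0,
    )
    res = _equilibrium_residuals(scenario, sol)
    # the three solved (sagittal-plane) equations must balance exactly;
    # out-of-plane components only to the geometric symmetry of the
    # scenario (bite/TMJ nodes snapped to a mesh sit slightly off-midline)
    inplane = max(res[0], res[2], res[4])
    outplane = max(res[1], res[3], res[5])
    if inplane > 1e-9:
        raise ValueError(f"bilateral bite solution failed equilibrium: {inplane:.3e}")
    if outplane > 1e-2:
        raise ValueError(
            f"scenario too asymmetric for the sagittal-plane model "
            f"(out-of-plane residual {outplane:.3e}); use solve_unilateral_bite"
        )
    return BiteSolution(sol.bite_force, sol.working_reaction,
                        sol.balancing_reaction, float(res.max()))
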