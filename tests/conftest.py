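"""Shared fixtures: a fast small phantom for unit tests and one
session-scoped run of the full default experiment for the acceptance
checks (both load cases, sutured + fused variants)."""

from __future__ import annotations

from dataclasses import replace

import pytest

from suturefe.config import RunConfig
from suturefe.phantom import (
    PhantomSpec,
    SutureBand,
    ToothPeg,
    build_phantom,
    default_spec,
)
from suturefe.pipeline import run_experiment


def small_spec(patent: bool = True, **overrides) -> PhantomSpec:
    """A coarse but fully featured phantom (~10k elements) for fast tests."""
    sutures = (
        SutureBand("longitudinal", offset=10.0, width=2.0, amplitude=1.0,
                   wavelength=8.0, patent=patent, name="sagittal"),
        SutureBand("transverse", offset=18.0, width=2.0, amplitude=1.0,
                   wavelength=5.0, patent=patent, name="coronal"),
        SutureBand("transverse", offset=30.0, width=2.0, patent=patent,
                   name="lambdoid"),
    )
    pegs = (
        ToothPeg("incisor_left", x=2.5, y=12.5, radius=1.2, length=0.75,
                 pdl_thickness=1.0, pulp_radius=0.5),
        ToothPeg("incisor_right", x=2.5, y=7.5, radius=1.2, length=0.75,
                 pdl_thickness=1.0, pulp_radius=0.5),
        ToothPeg("molar_left", x=13.75, y=13.75, radius=1.2, length=0.75,
                 pdl_thickness=1.0, pulp_radius=0.5),
        ToothPeg("molar_right", x=13.75, y=6.25, radius=1.2, length=0.75,
                 pdl_thickness=1.0, pulp_radius=0.5),
    )
    spec = PhantomSpec(
        length=40.0, width=20.0, thickness=1.0, nx=60, ny=30, nz=2,
        sutures=sutures, pegs=pegs, trabecular_fraction=0.0,
        arch_curvature=0.7,
    )
    return replace(spec, **overrides) if overrides else spec


@pytest.fixture(scope="session")
def small_mesh():
    return build_phantom(small_spec())


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full default sutured-vs-fused experiment (both load cases)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(phantom=default_spec(), outdir=outdir, write_vtk=False,
                    log_level="WARNING")
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """The same experiment on the coarse phantom (fast pipeline checks)."""
    outdir = tmp_path_factory.mktemp("small_run")
    cfg = RunConfig(phantom=small_spec(), outdir=outdir, write_vtk=False,
                    log_level="WARNING")
    return run_experiment(cfg)
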