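"""Shared fixtures: small meshes and solved FE cases, built once per session.

Everything is generated programmatically; mesh resolutions are chosen so the
full suite runs on a single CPU in minutes (the coarse end of the
test-profile range, 0.15 mm, for assembly contact cases).
"""

from __future__ import annotations

import numpy as np
import pytest

from ossicrimp.analytical import CORTICAL_BONE, PTFE, TITANIUM, RingSpec
from ossicrimp.contact import ContactParams, LoadCase, solve_contact
from ossicrimp.geometry import (
    AssemblySpec,
    annulus_sector_mesh,
    build_assembly,
    cylinder_sector_mesh,
    press_fit_assembly,
)

BONE_MATS = {"body": CORTICAL_BONE}


@pytest.fixture(scope="session")
def quarter_cylinder_straight():
    """Straight-sided quarter cylinder for exact patch tests."""
    return cylinder_sector_mesh(0.4, 1.0, 0.15, phi_span_deg=90.0, order=2,
                                curved=False)


@pytest.fixture(scope="session")
def quarter_annulus():
    """Curved quarter annulus for the thick-walled-cylinder oracle."""
    return annulus_sector_mesh(0.4, 0.8, 0.4, 0.1, phi_span_deg=90.0, order=2)


@pytest.fixture(scope="session")
def assembly_mesh_default():
    """Default PTFE-geometry assembly at the coarse test resolution."""
    ring = RingSpec(0.8, 1.2, band_width_w=0.3, coverage_angle_theta=216.0,
                    interference_dr=0.0)
    return build_assembly(AssemblySpec(ring=ring), 0.15, order=2)


@pytest.fixture(scope="session")
def press_fit_solution():
    """Frictionless interference fit of a bone shaft in a PTFE hub (plane strain)."""
    b, c, delta, length = 0.4, 0.6, 0.002, 0.4
    mesh = press_fit_assembly(b, c, delta, length, h=0.08, phi_span_deg=90.0, order=2)
    load = LoadCase(
        mode="interference_fit", fixed_patches=(),
        fixed_components=(
            ("shaft_z0", "z"), ("shaft_z1", "z"), ("hub_z0", "z"), ("hub_z1", "z"),
            ("shaft_phi0", "y"), ("shaft_phi1", "x"),
            ("hub_phi0", "y"), ("hub_phi1", "x"),
        ))
    sol = solve_contact(mesh, {"incus": CORTICAL_BONE, "loop": PTFE}, load,
                        ContactParams(friction_mu=0.0))
    return {"mesh": mesh, "sol": sol, "b": b, "c": c, "delta": delta,
            "length": length}


def _solve_assembly(material, ring, load):
    mats = {"incus": CORTICAL_BONE, "loop": material, "shaft": material}
    mesh = build_assembly(AssemblySpec(
        ring=ring, material_map=mats), 0.15, order=2)
    return mesh, solve_contact(mesh, mats, load)


@pytest.fixture(scope="session")
def ptfe_case_solution():
    """One solved PTFE self-crimp case (OD 1.2) at test resolution."""
    from ossicrimp.analytical import open_ring_pressure

    analytic = RingSpec(0.8, 1.2, 0.3, 216.0, 0.002)
    ring = RingSpec(0.8, 1.2, 0.3, 216.0, 0.0)
    p = open_ring_pressure(analytic, PTFE)
    mesh, sol = _solve_assembly(PTFE, ring, LoadCase(
        mode="self_crimp_pressure", applied_pressure=p))
    return {"mesh": mesh, "sol": sol, "pressure": p}


@pytest.fixture(scope="session")
def titanium_case_solution():
    """One solved titanium crimp-force case (w 0.2, 300 mN)."""
    ring = RingSpec(0.8, 1.0, 0.2, 216.0, 0.0)
    mesh, sol = _solve_assembly(TITANIUM, ring, LoadCase(
        mode="crimp_force", crimping_force_F=0.3))
    return {"mesh": mesh, "sol": sol, "force": 0.3}


@pytest.fixture(scope="session")
def full_sweep_results():
    """The complete 12-case published grid at test resolution (shared by the
    trend and classification acceptance checks)."""
    from ossicrimp.sweep import default_grid, run_sweep

    return run_sweep(default_grid(), target_element_size=0.15, order=2)
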