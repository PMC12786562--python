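"""Contact solver verification: press-fit oracle, balance, Coulomb limits."""

import numpy as np
import pytest

from ossicrimp.analytical import CORTICAL_BONE, PTFE, TITANIUM, RingSpec
from ossicrimp.contact import (
    ContactParams,
    LoadCase,
    apply_crimp_force,
    solve_contact,
)
from ossicrimp.fem import FESystem, patch_area
from ossicrimp.geometry import AssemblySpec, build_assembly


def plane_strain_press_fit_pressure(b, c, delta, inner, outer):
    """Closed-form interface pressure of a solid shaft in a hub, plane strain.

    Radial displacement compliances at r=b (per unit pressure):
      hub:   u/p = b*((1-nu^2)*(c^2+b^2)/(c^2-b^2) + nu*(1+nu))/E
      shaft: u/p = -b*(1+nu)*(1-2nu)/E  (uniform biaxial compression)
    and p = delta / (u_hub - u_shaft).
    """
    e1, n1 = inner.youngs_modulus_E, inner.poisson_nu
    e2, n2 = outer.youngs_modulus_E, outer.poisson_nu
    st = (b * b + c * c) / (c * c - b * b)
    u_hub = b * ((1 - n2 * n2) * st + n2 * (1 + n2)) / e2
    u_shaft = -b * (1 + n1) * (1 - 2 * n1) / e1
    return delta / (u_hub - u_shaft)


class TestPressFitOracle:
    def test_interface_pressure_within_5_percent(self, press_fit_solution):
        d = press_fit_solution
        p_exact = plane_strain_press_fit_pressure(
            d["b"], d["c"], d["delta"], CORTICAL_BONE, PTFE)
        # quarter model: contact area = quarter circumference x length
        area = 0.25 * 2 * np.pi * d["b"] * d["length"]
        p_fe = d["sol"].total_contact_force / area
        assert p_fe == pytest.approx(p_exact, rel=0.05)

    def test_penetration_resolved(self, press_fit_solution):
        sol = press_fit_solution["sol"]
        assert sol.converged
        assert sol.convergence_log[-1]["max_penetration_mm"] < 1e-4

    def test_contact_force_consistent_across_passes(self, press_fit_solution):
        """Integrated contact pressure equals the closed-form resultant within 2%."""
        d = press_fit_solution
        p_exact = plane_strain_press_fit_pressure(
            d["b"], d["c"], d["delta"], CORTICAL_BONE, PTFE)
        area = 0.25 * 2 * np.pi * d["b"] * d["length"]
        assert d["sol"].total_contact_force == pytest.approx(
            p_exact * area, rel=0.02)


class TestLoadCases:
    def test_zero_load_gives_zero_fields(self, assembly_mesh_default):
        mats = {"incus": CORTICAL_BONE, "loop": PTFE, "shaft": PTFE}
        sol = solve_contact(assembly_mesh_default, mats,
                            LoadCase(mode="self_crimp_pressure", applied_pressure=0.0))
        assert np.abs(sol.nodal_displacements).max() < 1e-12
        assert np.nanmax(sol.von_mises_field["incus"]) < 1e-9

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(mode="squeeze")

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(mode="crimp_force", crimping_force_F=-1.0)

    def test_large_deformation_flag_not_supported(self):
        with pytest.raises(NotImplementedError):
            LoadCase(mode="crimp_force", crimping_force_F=0.3,
                     large_deformation=True)


class TestCrimpForceApplication:
    def test_resultant_magnitude_matches_request(self, assembly_mesh_default):
        mats = {"incus": CORTICAL_BONE, "loop": TITANIUM, "shaft": TITANIUM}
        sys = FESystem(assembly_mesh_default, mats)
        info = apply_crimp_force(sys, 0.3)
        # integrated |traction| = pressure x area = requested force
        assert info["mean_pressure_MPa"] * info["area_mm2"] == pytest.approx(
            0.3, rel=1e-3)

    def test_mean_pressure_close_to_analytic(self):
        """Mean applied pressure approximates F/Ac of the ring model (the load
        surface sits at the outer radius and excludes the stem footprint, so
        agreement is to a few percent, not exact)."""
        from ossicrimp.analytical import pressure_from_force

        ring = RingSpec(0.8, 1.0, 0.2, 216.0, 0.0)
        mesh = build_assembly(AssemblySpec(ring=ring), 0.15)
        mats = {"incus": CORTICAL_BONE, "loop": TITANIUM, "shaft": TITANIUM}
        sys = FESystem(mesh, mats)
        info = apply_crimp_force(sys, 0.3)
        assert info["mean_pressure_MPa"] == pytest.approx(
            pressure_from_force(0.3, ring), rel=0.25)

    def test_negative_force_rejected(self, assembly_mesh_default):
        mats = {"incus": CORTICAL_BONE, "loop": TITANIUM, "shaft": TITANIUM}
        sys = FESystem(assembly_mesh_default, mats)
        with pytest.raises(ValueError):
            apply_crimp_force(sys, -0.1)


class TestSolvedAssemblyCases:
    def test_global_force_balance(self, titanium_case_solution):
        """Reactions at the fixed patches balance the applied load within 0.5%."""
        mesh, sol = titanium_case_solution["mesh"], titanium_case_solution["sol"]
        mats = {"incus": CORTICAL_BONE, "loop": TITANIUM, "shaft": TITANIUM}
        sys = FESystem(mesh, mats)
        fn = np.zeros((mesh.n_nodes, 3))
        fn += sys.add_traction("loop_load_surface", lambda pts, nrm: (
            -titanium_case_solution["force"]
            / patch_area(mesh.nodes, mesh.patches["loop_load_surface"])
            * np.column_stack([pts[:, 0], pts[:, 1], np.zeros(len(pts))])
            / np.linalg.norm(pts[:, :2], axis=1)[:, None]))
        applied = fn.sum(axis=0)
        react = sol.reactions.sum(axis=0)
        assert np.linalg.norm(applied + react) <= 5e-3 * np.linalg.norm(applied)

    def test_coulomb_condition_pointwise(self, titanium_case_solution):
        sol = titanium_case_solution["sol"]
        mu = 0.25
        ok = sol.contact_shear <= mu * np.maximum(sol.contact_pressure, 0.0) + 1e-9
        assert ok.all()

    def test_contact_closed_under_load(self, ptfe_case_solution):
        sol = ptfe_case_solution["sol"]
        assert (sol.contact_status > 0).sum() > 0.5 * sol.contact_status.size
        assert sol.total_contact_force > 0

    def test_pinch_application_concentrates_load(self):
        """Concentrating the same force on clamp jaws raises the local peak
        above the uniform-arc value (sensitivity of the force introduction)."""
        from ossicrimp.safety import summarize_solution

        ring = RingSpec(0.8, 1.0, 0.2, 216.0, 0.0)
        mats = {"incus": CORTICAL_BONE, "loop": TITANIUM, "shaft": TITANIUM}
        mesh = build_assembly(AssemblySpec(ring=ring), 0.2)
        peaks = {}
        for mode in ("uniform", "pinch"):
            sol = solve_contact(mesh, mats, LoadCase(
                mode="crimp_force", crimping_force_F=0.3, force_application=mode))
            peaks[mode] = summarize_solution(sol).peak_incus_von_mises
        assert peaks["pinch"] > peaks["uniform"]

    def test_doubling_force_doubles_displacement(self):
        """With contact fully closed the small-strain response is linear."""
        ring = RingSpec(0.8, 1.0, 0.2, 216.0, 0.0)
        mats = {"incus": CORTICAL_BONE, "loop": TITANIUM, "shaft": TITANIUM}
        mesh = build_assembly(AssemblySpec(ring=ring), 0.2)
        sols = [solve_contact(mesh, mats,
                              LoadCase(mode="crimp_force", crimping_force_F=f))
                for f in (0.2, 0.4)]
        u1 = sols[0].nodal_displacements
        u2 = sols[1].nodal_displacements
        assert np.linalg.norm(u2 - 2 * u1) <= 0.02 * np.linalg.norm(u2)
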