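"""Mesh generator: validity, determinism, convergence and export round trips."""

import math

import numpy as np
import pytest

from ossicrimp.analytical import RingSpec, contact_area
from ossicrimp.fem import patch_area
from ossicrimp.geometry import (
    AssemblySpec,
    MeshingError,
    annulus_sector_mesh,
    build_assembly,
    cylinder_sector_mesh,
    mesh_quality_report,
    press_fit_assembly,
)
from ossicrimp.io import read_msh, write_msh, write_vtk

REQUIRED_PATCHES = [
    "contact_inner_loop", "target_incus_surface", "fixed_posterior_incus",
    "fixed_shaft_tip", "loop_load_surface",
]


def default_spec(od=1.2, w=0.3, dr=0.0):
    return AssemblySpec(ring=RingSpec(0.8, od, w, 216.0, dr))


def quadrature_volume(mesh):
    """Total volume by Gauss quadrature (captures quadratic curvature)."""
    from ossicrimp.fem import _GP11, _GW11, _inv3, _shape_tet

    _, dn = _shape_tet(mesh.order, _GP11 if mesh.order == 2 else
                       np.array([[0.25, 0.25, 0.25, 0.25]]))
    wts = _GW11 if mesh.order == 2 else np.array([1.0 / 6.0])
    x = mesh.nodes[mesh.elements]
    vol = 0.0
    for g in range(wts.size):
        jac = np.einsum("eai,aj->eij", x, dn[g])
        _, det = _inv3(jac)
        vol += wts[g] * det.sum()
    return float(vol)


class TestConformity:
    def test_interior_faces_shared_by_exactly_two_tets(self, assembly_mesh_default):
        from ossicrimp.geometry import _TET_FACES

        faces = assembly_mesh_default.elements[:, :4][:, _TET_FACES].reshape(-1, 3)
        _, counts = np.unique(np.sort(faces, axis=1), axis=0, return_counts=True)
        assert set(np.unique(counts)) <= {1, 2}

    def test_all_jacobians_positive(self, assembly_mesh_default):
        assert assembly_mesh_default.element_volumes().min() > 0

    def test_every_element_in_exactly_one_region(self, assembly_mesh_default):
        m = assembly_mesh_default
        assert set(np.unique(m.region_tags)) <= set(m.region_names)
        assert m.region_tags.shape[0] == m.n_elements


class TestBuildAssembly:
    def test_required_patches_nonempty(self, assembly_mesh_default):
        for name in REQUIRED_PATCHES:
            assert assembly_mesh_default.patches[name].shape[0] > 0, name

    def test_deterministic_rebuild(self):
        a = build_assembly(default_spec(), 0.15, seed=7)
        b = build_assembly(default_spec(), 0.15, seed=7)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(a.elements, b.elements)

    def test_interference_built_into_geometry(self):
        mesh = build_assembly(default_spec(dr=0.002), 0.2)
        loop_ids = mesh.patch_node_ids("contact_inner_loop")
        r = np.linalg.norm(mesh.nodes[loop_ids, :2], axis=1)
        assert np.allclose(r.min(), 0.398, atol=1e-6)

    def test_titanium_band_variants(self):
        for w in (0.2, 0.3, 0.5):
            mesh = build_assembly(AssemblySpec(
                ring=RingSpec(0.8, 1.0, w, 216.0, 0.0)), 0.15)
            zs = mesh.nodes[mesh.patch_node_ids("contact_inner_loop"), 2]
            assert zs.max() - zs.min() == pytest.approx(w, abs=1e-9)

    def test_out_of_range_element_size_rejected(self):
        with pytest.raises(MeshingError):
            build_assembly(default_spec(), 0.6)
        with pytest.raises(MeshingError):
            build_assembly(default_spec(), 0.01)

    def test_crimp_site_outside_incus_rejected(self):
        with pytest.raises(MeshingError):
            AssemblySpec(ring=RingSpec(0.8, 1.2, 0.3), crimp_offset_from_tip=3.5)

    def test_paper_scale_node_count(self):
        """At the published 0.05 mm element size the mesh lands within a
        factor 0.5-2 of the published 105,403 nodes (the original mesher and
        grading are unknown, so only the order of magnitude is meaningful)."""
        mesh = build_assembly(default_spec(), 0.05, order=2)
        assert 0.5 * 105_403 <= mesh.n_nodes <= 2.0 * 105_403


class TestGeometricAccuracy:
    def test_incus_volume_converges_to_cylinder(self):
        # pi r^2 L for r=0.4, L=3.0
        exact = math.pi * 0.16 * 3.0
        spec = default_spec()
        for h, tol in ((0.15, 0.02), (0.1, 0.02)):
            mesh = build_assembly(spec, h, order=2)
            incus = mesh.region_tags == 1
            sub = type(mesh)(
                nodes=mesh.nodes, elements=mesh.elements[incus],
                region_tags=mesh.region_tags[incus], patches={}, order=mesh.order,
                region_names=mesh.region_names)
            vol = quadrature_volume(sub)
            assert vol == pytest.approx(exact, rel=tol)

    def test_target_patch_area_matches_analytic_contact_area(self):
        ring = RingSpec(0.8, 1.2, 0.3, 216.0, 0.002)
        mesh = build_assembly(AssemblySpec(ring=ring), 0.12)
        area = patch_area(mesh.nodes, mesh.patches["target_incus_surface"])
        assert area == pytest.approx(contact_area(ring), rel=0.05)

    def test_refinement_increases_element_count(self):
        coarse = build_assembly(default_spec(), 0.2)
        fine = build_assembly(default_spec(), 0.12)
        assert fine.n_elements > coarse.n_elements
        assert fine.n_nodes > coarse.n_nodes


class TestQualityReport:
    def test_positive_jacobians_reported(self, assembly_mesh_default):
        rep = mesh_quality_report(assembly_mesh_default)
        assert rep["min_jacobian"] > 0
        assert 0 < rep["min_quality"] <= rep["median_quality"] <= 1.0
        assert rep["elements_per_region"]["incus"] > 0
        assert rep["elements_per_region"]["loop"] > 0
        assert rep["elements_per_region"]["shaft"] > 0

    def test_empty_mesh_rejected(self, assembly_mesh_default):
        m = assembly_mesh_default
        empty = type(m)(nodes=m.nodes, elements=m.elements[:0],
                        region_tags=m.region_tags[:0], patches={}, order=m.order)
        with pytest.raises(MeshingError):
            mesh_quality_report(empty)


class TestVerificationShapes:
    def test_cylinder_sector_patches(self):
        m = cylinder_sector_mesh(0.4, 1.0, 0.15, phi_span_deg=90.0)
        for p in ("lateral", "z0", "z1", "phi0", "phi1"):
            assert m.patches[p].shape[0] > 0

    def test_annulus_radii_are_respected(self):
        m = annulus_sector_mesh(0.4, 0.8, 0.4, 0.1, phi_span_deg=90.0)
        r_in = np.linalg.norm(m.nodes[m.patch_node_ids("inner"), :2], axis=1)
        r_out = np.linalg.norm(m.nodes[m.patch_node_ids("outer"), :2], axis=1)
        assert np.allclose(r_in, 0.4, atol=1e-9)
        assert np.allclose(r_out, 0.8, atol=1e-9)

    def test_press_fit_overlap(self):
        m = press_fit_assembly(0.4, 0.6, 0.002, 0.4, 0.1)
        bore = np.linalg.norm(m.nodes[m.patch_node_ids("contact_inner_loop"), :2],
                              axis=1)
        assert bore.min() == pytest.approx(0.398, abs=1e-9)


class TestExport:
    def test_msh_round_trip(self, tmp_path, assembly_mesh_default):
        path = tmp_path / "assembly.msh"
        write_msh(path, assembly_mesh_default)
        back = read_msh(path)
        np.testing.assert_allclose(back.nodes, assembly_mesh_default.nodes,
                                   atol=1e-10)
        np.testing.assert_array_equal(back.elements, assembly_mesh_default.elements)
        np.testing.assert_array_equal(back.region_tags,
                                      assembly_mesh_default.region_tags)
        for name in REQUIRED_PATCHES:
            np.testing.assert_array_equal(
                np.sort(back.patches[name].ravel()),
                np.sort(assembly_mesh_default.patches[name].ravel()))

    def test_vtk_is_readable_text(self, tmp_path, assembly_mesh_default):
        path = tmp_path / "assembly.vtk"
        write_vtk(path, assembly_mesh_default,
                  point_data={"f": np.zeros(assembly_mesh_default.n_nodes)})
        head = path.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")
        assert any(line.startswith("CELL_TYPES") for line in head[:20000])
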