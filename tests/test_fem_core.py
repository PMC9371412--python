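"""FEM core: element matrices, constrained solves, analytic oracles."""

import numpy as np
import pytest

from oraleis import fem_core as fc
from oraleis.materials import DispersiveMaterial


def quadrature_element_matrix(a, b, c, sx, sy, sz):
    """Independent oracle: 2x2x2 Gauss quadrature of the trilinear hex
    stiffness integral for a brick (a, b, c)."""
    g = 1.0 / np.sqrt(3.0)
    pts = [(-g, -g, -g), (g, -g, -g), (-g, g, -g), (g, g, -g),
           (-g, -g, g), (g, -g, g), (-g, g, g), (g, g, g)]
    K = np.zeros((8, 8), dtype=complex)
    J = np.diag([a / 2, b / 2, c / 2])
    detJ = np.prod(np.diag(J))
    S = np.diag([sx, sy, sz])
    for xi, eta, zeta in pts:
        G = np.zeros((3, 8))
        for l in range(8):
            px = -1 if (l & 1) == 0 else 1
            py = -1 if ((l >> 1) & 1) == 0 else 1
            pz = -1 if ((l >> 2) & 1) == 0 else 1
            G[0, l] = px * (1 + py * eta) * (1 + pz * zeta) / 8
            G[1, l] = py * (1 + px * xi) * (1 + pz * zeta) / 8
            G[2, l] = pz * (1 + px * xi) * (1 + py * eta) / 8
        B = np.linalg.solve(J, G)
        K += (B.T @ S @ B) * detJ
    return K


class TestElementMatrix:
    def test_matches_quadrature_oracle(self):
        K = fc.element_conductance_matrix(1e-3, 2e-3, 0.5e-3, 1.0, 1.0, 1.0)
        Kq = quadrature_element_matrix(1e-3, 2e-3, 0.5e-3, 1.0, 1.0, 1.0)
        np.testing.assert_allclose(K, Kq.real, rtol=1e-12, atol=1e-18)

    def test_complex_admittivity_scales_linearly(self):
        """With sigma* = a + jb isotropic, Im K = (b/a) Re K."""
        K = fc.element_conductance_matrix(1e-3, 1e-3, 1e-3,
                                          2 + 1j, 2 + 1j, 2 + 1j)
        np.testing.assert_allclose(K.imag, 0.5 * K.real, rtol=1e-12)

    def test_row_sums_vanish(self):
        """A constant potential drives no current (null vector)."""
        K = fc.element_conductance_matrix(1e-3, 3e-3, 0.2e-3, 1.0, 2.0, 3.0)
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-15)


class TestGrids:
    def test_uniform_cube_element_count(self):
        mesh = fc.build_graded_grid((1e-3, 1e-3, 1e-3),
                                    targets=(0.25e-3, 0.25e-3, 0.25e-3))
        assert mesh.n_elements == 64

    def test_interface_plane_is_a_grid_plane(self):
        mesh = fc.build_graded_grid((1e-3, 1e-3, 1e-3),
                                    interface_planes=((), (), (0.01e-3,)),
                                    targets=(1e-3, 1e-3, 0.5e-3))
        assert np.any(np.isclose(mesh.zs, 0.01e-3))

    def test_thin_membrane_gets_an_element(self):
        """An 8 nm interval between interface planes always receives at
        least one element, even with a coarse target size."""
        mesh = fc.build_graded_grid(
            (5e-6, 5e-6, 5e-6),
            interface_planes=((), (), (2e-6, 2e-6 + 8e-9)),
            targets=(1e-6, 1e-6, 1e-6))
        dz = np.diff(mesh.zs)
        assert np.any(np.isclose(dz, 8e-9))

    def test_interfaces_outside_extents_rejected(self):
        with pytest.raises(ValueError):
            fc.build_graded_grid((1e-3, 1e-3, 1e-3),
                                 interface_planes=((), (), (2e-3,)))

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            fc.HexMesh([0.0, 0.0, 1.0], [0.0, 1.0], [0.0, 1.0])


def _solve_stack(mesh, materials, f):
    system = fc.assemble(mesh, materials, f)
    sol = fc.solve(system, fc.BoundaryConditions(
        fixed={"top": 1.0, "bot": 0.0}))
    return system, sol


class TestSolve:
    def test_uniform_bar_linear_potential(self):
        mesh = fc.build_graded_grid((1e-3, 1e-3, 4e-3),
                                    targets=(0.5e-3, 0.5e-3, 0.5e-3))
        mesh.plane_node_set("bot", "z", 0.0)
        mesh.plane_node_set("top", "z", 4e-3)
        mat = DispersiveMaterial.constant("r", 1.0, 0.0)
        _, sol = _solve_stack(mesh, {"domain": mat}, 100.0)
        _, _, Z = mesh.node_coords()
        np.testing.assert_allclose(sol.phi.real, Z / 4e-3, atol=1e-10)

    def test_grounded_everywhere_gives_zero(self):
        mesh = fc.build_graded_grid((1e-3, 1e-3, 1e-3),
                                    targets=(0.5e-3,) * 3)
        mesh.plane_node_set("bot", "z", 0.0)
        mesh.plane_node_set("top", "z", 1e-3)
        mat = DispersiveMaterial.constant("r", 1.0, 10.0)
        system = fc.assemble(mesh, {"domain": mat}, 100.0)
        sol = fc.solve(system, fc.BoundaryConditions(
            fixed={"top": 0.0, "bot": 0.0}))
        np.testing.assert_allclose(sol.phi, 0.0, atol=1e-14)

    def test_current_injection_conservation(self):
        """Injected current returns in full through the grounded set."""
        mesh = fc.build_graded_grid((1e-3, 1e-3, 1e-3),
                                    targets=(0.25e-3,) * 3)
        mesh.plane_node_set("bot", "z", 0.0)
        mesh.plane_node_set("top", "z", 1e-3)
        mat = DispersiveMaterial.constant("r", 2.0, 50.0)
        system = fc.assemble(mesh, {"domain": mat}, 1e4)
        i_in = 3e-6 + 1e-6j
        sol = fc.solve(system, fc.BoundaryConditions(
            fixed={"bot": 0.0}, currents={"top": i_in}))
        i_gnd = fc.reaction_current(sol, system, "bot")
        assert i_gnd == pytest.approx(-i_in, rel=1e-10)

    def test_no_reference_is_ill_posed(self):
        mesh = fc.build_graded_grid((1e-3,) * 3, targets=(0.5e-3,) * 3)
        mesh.plane_node_set("top", "z", 1e-3)
        mat = DispersiveMaterial.constant("r", 1.0, 0.0)
        system = fc.assemble(mesh, {"domain": mat}, 100.0)
        with pytest.raises(ValueError, match="reference"):
            fc.solve(system, fc.BoundaryConditions(
                currents={"top": 1e-6}))

    def test_missing_material_raises(self):
        mesh = fc.build_graded_grid((1e-3,) * 3, targets=(0.5e-3,) * 3)
        with pytest.raises(KeyError):
            fc.assemble(mesh, {}, 100.0)

    def test_reaction_on_unconstrained_set_raises(self):
        mesh = fc.build_graded_grid((1e-3,) * 3, targets=(0.5e-3,) * 3)
        mesh.plane_node_set("bot", "z", 0.0)
        mesh.plane_node_set("top", "z", 1e-3)
        mesh.plane_node_set("side", "x", 0.0)
        mat = DispersiveMaterial.constant("r", 1.0, 0.0)
        system = fc.assemble(mesh, {"domain": mat}, 100.0)
        sol = fc.solve(system, fc.BoundaryConditions(
            fixed={"top": 1.0, "bot": 0.0}))
        with pytest.raises(KeyError):
            fc.reaction_current(sol, system, "side")


class TestSeriesLayersOracle:
    def test_single_layer_dc_limit(self):
        mat = DispersiveMaterial.constant("r", 1.0, 0.0)
        z = fc.analytic_series_layers([(1e-3, mat)], 1e-6, 76.0)
        assert z == pytest.approx(1000.0 + 0.0j)

    def test_two_layers_additive(self):
        mat = DispersiveMaterial.constant("r", 3.0, 20.0)
        one = fc.analytic_series_layers([(2e-3, mat)], 1e-6, 1e4)
        two = fc.analytic_series_layers([(1e-3, mat), (1e-3, mat)], 1e-6, 1e4)
        assert two == pytest.approx(one, rel=1e-12)

    def test_fem_matches_maxwell_wagner_curve(self, toy_stack):
        """FEM on a resistive/capacitive bilayer reproduces the analytic
        single-dispersion (interfacial polarization) curve."""
        layers = toy_stack["layers"]
        t_total = sum(t for t, _ in layers)
        side = np.sqrt(toy_stack["area_m2"])
        mesh = fc.build_graded_grid(
            (side, side, t_total),
            interface_planes=((), (), (layers[0][0],)),
            targets=(side / 2, side / 2, t_total / 10))
        mesh.label_regions(
            lambda cx, cy, cz: (cz > layers[0][0]).astype(int),
            [layers[0][1].name, layers[1][1].name])
        mesh.plane_node_set("bot", "z", 0.0)
        mesh.plane_node_set("top", "z", t_total)
        mats = {m.name: m for _, m in layers}
        for f, z_exp in zip(toy_stack["freqs_hz"],
                            toy_stack["expected_z_ohm"]):
            system, sol = _solve_stack(mesh, mats, f)
            z = 1.0 / fc.reaction_current(sol, system, "top")
            assert abs(z - z_exp) / abs(z_exp) < 5e-3

    def test_refinement_changes_stack_impedance_below_1pc(self, toy_stack):
        """One uniform refinement step moves |Z| by <1% (mesh convergence;
        the 1-D stack solution is already exact on the coarse grid)."""
        layers = toy_stack["layers"]
        t_total = sum(t for t, _ in layers)
        side = np.sqrt(toy_stack["area_m2"])
        mats = {m.name: m for _, m in layers}
        zs = []
        for n in (4, 8):
            mesh = fc.build_graded_grid(
                (side, side, t_total),
                interface_planes=((), (), (layers[0][0],)),
                targets=(side / 2, side / 2, t_total / n))
            mesh.label_regions(
                lambda cx, cy, cz: (cz > layers[0][0]).astype(int),
                [layers[0][1].name, layers[1][1].name])
            mesh.plane_node_set("bot", "z", 0.0)
            mesh.plane_node_set("top", "z", t_total)
            system, sol = _solve_stack(mesh, mats, 1e4)
            zs.append(1.0 / fc.reaction_current(sol, system, "top"))
        assert abs(abs(zs[1]) - abs(zs[0])) / abs(zs[0]) < 0.01


class TestExport:
    def test_vtk_roundtrip_header(self, tmp_path):
        mesh = fc.build_graded_grid((1e-3,) * 3, targets=(0.5e-3,) * 3)
        path = tmp_path / "mesh.vtk"
        fc.export_vtk(mesh, path, point_data={
            "phi": np.zeros(mesh.n_nodes, dtype=complex)})
        text = path.read_text()
        assert "RECTILINEAR_GRID" in text
        assert "phi_re" in text and "phi_im" in text
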