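"""Tissue-scale stacks, meshing, electrodes and tetrapolar solves."""

import numpy as np
import pytest

from oraleis import tissue_model as tm
from oraleis.materials import (AnisotropicMaterial, DispersiveMaterial,
                               keratin_stratum_corneum, substrate_material)

UNIFORM = AnisotropicMaterial.isotropic(
    DispersiveMaterial.constant("uniform", 3.0, 0.0))

#: fast mesh for solver-behaviour tests (not accuracy tests)
TINY = tm.MeshResolution(core_h=0.4e-3, core_margin=0.4e-3, growth=2.0,
                         stroma_h0=0.2e-3, stroma_growth=2.0)


@pytest.fixture(scope="module")
def flat_props():
    """Frequency-independent epithelial stand-in properties."""
    mk = lambda n, r: AnisotropicMaterial.isotropic(
        DispersiveMaterial.constant(n, r, 100.0))
    return {"superficial": mk("sup", 900.0), "prickle": mk("pri", 150.0),
            "basal": mk("bas", 60.0)}


@pytest.fixture(scope="module")
def case2(config):
    return config.cases[2]


class TestLayerStack:
    def test_case2_mean_thicknesses(self, case2, flat_props):
        stack = tm.build_layer_stack(case2, flat_props,
                                     keratin=keratin_stratum_corneum(40.0))
        t = {l.name: l.thickness for l in stack.layers}
        assert t["keratinised"] == pytest.approx(14.0e-6)
        assert t["basal"] == pytest.approx(15.7e-6)
        assert t["prickle"] == pytest.approx(100.5e-6)
        assert t["superficial"] == pytest.approx(182.0e-6)
        assert t["saliva"] == pytest.approx(0.01e-3)
        assert sum(t.values()) == pytest.approx(5e-3)

    def test_non_keratinised_case_has_no_keratin_layer(self, config,
                                                       flat_props):
        stack = tm.build_layer_stack(config.cases[1], flat_props)
        names = [l.name for l in stack.layers]
        assert "keratinised" not in names
        t = {l.name: l.thickness for l in stack.layers}
        assert t["superficial"] == pytest.approx(274.9e-6)

    def test_substrate_limits_stroma_to_1mm(self, config, flat_props):
        stack = tm.build_layer_stack(
            config.cases[3], flat_props,
            keratin=keratin_stratum_corneum(40.0),
            substrate=substrate_material("muscle"))
        t = {l.name: l.thickness for l in stack.layers}
        assert t["stroma"] == pytest.approx(1e-3)
        assert t["substrate_muscle"] == pytest.approx(
            5e-3 - 1e-3 - sum(v for k, v in t.items()
                              if k not in ("stroma", "substrate_muscle")))

    def test_missing_keratin_for_keratinised_case(self, case2, flat_props):
        with pytest.raises(ValueError, match="keratin"):
            tm.build_layer_stack(case2, flat_props)

    def test_negative_thickness_under_mean_minus_sd_reported(self, flat_props):
        case = tm.TissueCase(99, "x", "Non-keratinised", "x",
                             basal_um=(10.0, 15.0), prickle_um=(100.0, 5.0),
                             superficial_um=(200.0, 10.0))
        with pytest.raises(ValueError, match="basal"):
            tm.build_layer_stack(case, flat_props, thickness_mode="mean-sd")

    def test_unknown_mode_rejected(self, case2, flat_props):
        with pytest.raises(ValueError, match="mode"):
            tm.build_layer_stack(case2, flat_props,
                                 keratin=keratin_stratum_corneum(40.0),
                                 thickness_mode="median")


class TestElectrodeLayout:
    def test_overlapping_electrodes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tm.ElectrodeLayout.collinear(pitch=0.5e-3, radius=0.3e-3)

    def test_electrode_outside_surface_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tm.ElectrodeLayout(centres={
                "drive": (-25e-3, 0.0), "m1": (-1e-3, 0.0),
                "m2": (1e-3, 0.0), "receive": (3e-3, 0.0)})

    def test_missing_role_rejected(self):
        with pytest.raises(ValueError, match="drive"):
            tm.ElectrodeLayout(centres={"a": (0.0, 0.0)})


class TestTissueMesh:
    def test_grid_conforms_to_every_interface(self, case2, flat_props):
        stack = tm.build_layer_stack(case2, flat_props,
                                     keratin=keratin_stratum_corneum(40.0))
        mesh = tm.build_tissue_mesh(stack, tm.ElectrodeLayout.collinear(),
                                    TINY)
        for depth in stack.interfaces():
            assert np.any(np.isclose(mesh.zs, depth, rtol=0, atol=1e-12))

    def test_electrode_pixelation_error_at_default_resolution(self):
        """Pixelated electrode footprint area within 10% of the disc."""
        stack = tm.LayerStack((tm.Layer("stroma", 5e-3, UNIFORM),))
        layout = tm.ElectrodeLayout.collinear(pitch=2.4e-3)
        mesh = tm.build_tissue_mesh(stack, layout, "standard")
        ideal = np.pi * layout.radius ** 2
        for name, area in mesh.electrode_area.items():
            assert abs(area - ideal) / ideal <= 0.10, name

    def test_duplicate_layer_names_rejected(self):
        stack = tm.LayerStack((tm.Layer("stroma", 2e-3, UNIFORM),
                               tm.Layer("stroma", 3e-3, UNIFORM)))
        with pytest.raises(ValueError, match="duplicate"):
            tm.build_tissue_mesh(stack, tm.ElectrodeLayout.collinear(), TINY)


@pytest.fixture(scope="module")
def homogeneous():
    stack = tm.LayerStack((tm.Layer("stroma", 5e-3, UNIFORM),))
    layout = tm.ElectrodeLayout.collinear(pitch=2.0e-3)
    mesh = tm.build_tissue_mesh(stack, layout, TINY)
    return stack, layout, mesh


class TestTetrapolar:

    def test_linearity_in_drive_current(self, homogeneous):
        stack, layout, mesh = homogeneous
        mats = {l.name: l.material for l in stack.layers}
        z1 = tm.tetrapolar_impedance(mesh, mats, layout, 1e3)
        doubled = tm.ElectrodeLayout(centres=layout.centres,
                                     radius=layout.radius,
                                     drive_current=2 * layout.drive_current)
        z2 = tm.tetrapolar_impedance(mesh, mats, doubled, 1e3)
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_reciprocity(self, homogeneous):
        """Exchanging the drive pair with the measurement pair leaves the
        transfer impedance unchanged."""
        stack, layout, mesh = homogeneous
        mats = {l.name: l.material for l in stack.layers}
        z = tm.tetrapolar_impedance(mesh, mats, layout, 1e3)
        c = layout.centres
        swapped = tm.ElectrodeLayout(
            centres={"drive": c["m1"], "receive": c["m2"],
                     "m1": c["drive"], "m2": c["receive"]},
            radius=layout.radius, drive_current=layout.drive_current)
        mesh2 = tm.build_tissue_mesh(stack, swapped, TINY)
        z_sw = tm.tetrapolar_impedance(
            mesh2, mats, swapped, 1e3)
        assert z_sw == pytest.approx(z, rel=1e-6)

    def test_purely_resistive_stack_has_flat_spectrum(self, homogeneous):
        stack, layout, _ = homogeneous
        sp = tm.spectrum(stack, layout, [76.0, 1e4, 625e3], TINY)
        assert np.ptp(sp.abs_z) / sp.abs_z[0] < 1e-9
        assert np.allclose(sp.phase_deg, 0.0, atol=1e-6)

    def test_boundary_insensitivity(self, homogeneous):
        """Enlarging the lateral footprint changes |Z| by <1%."""
        stack, layout, _ = homogeneous
        z_ref = tm.spectrum(stack, layout, [1e3], TINY).z[0]
        z_big = tm.spectrum(stack, layout, [1e3], TINY,
                            half_extent=28e-3).z[0]
        assert abs(abs(z_big) - abs(z_ref)) / abs(z_ref) < 0.01

    def test_spectrum_caching_returns_identical_values(self, homogeneous):
        stack, layout, _ = homogeneous
        a = tm.spectrum(stack, layout, [76.0, 1e4], TINY)
        b = tm.spectrum(stack, layout, [76.0, 1e4], TINY)
        np.testing.assert_array_equal(a.z, b.z)

    def test_spectrum_csv_roundtrip_bit_identical(self, homogeneous,
                                                  tmp_path):
        import pandas as pd

        stack, layout, _ = homogeneous
        sp = tm.spectrum(stack, layout, [76.0, 1e4], TINY)
        path = tmp_path / "spectrum.csv"
        sp.to_csv(path)
        df = pd.read_csv(path)
        np.testing.assert_array_equal(df["re_z_ohm"].to_numpy(), sp.z.real)
        np.testing.assert_array_equal(df["im_z_ohm"].to_numpy(), sp.z.imag)
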