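"""Unit tests for the bio-optical layer model, artery law and voxel builder."""

import numpy as np
import pytest

from mcbp import tissue
from mcbp.tissue import (CompositeAbsorptionSpec,
                         EpidermisAbsorptionParams, FingerGeometrySpec,
                         GeometryError, LayerOpticalProperties,
                         artery_absorption, artery_diameter, artery_state,
                         artery_volume_fractions, baseline_absorption,
                         build_voxel_model, compact_benchmark_geometry,
                         composite_absorption, epidermis_absorption,
                         melanin_absorption, stratum_corneum_absorption)


class TestAbsorptionLaws:
    @pytest.mark.parametrize("lam,expected", [
        (905, 7.84e7 * 905 ** -3.255),
        (940, 7.84e7 * 940 ** -3.255),
    ])
    def test_baseline_power_law(self, lam, expected):
        assert baseline_absorption(lam) == pytest.approx(expected, rel=1e-12)

    def test_baseline_decreasing_in_wavelength(self):
        assert baseline_absorption(905) > baseline_absorption(940)
        lams = np.linspace(400, 1100, 50)
        assert np.all(np.diff(baseline_absorption(lams)) < 0)

    @pytest.mark.parametrize("lam,expected", [
        (905, 6.6e10 * 905 ** -3.3),
        (940, 6.6e10 * 940 ** -3.3),
    ])
    def test_melanin_power_law(self, lam, expected):
        assert melanin_absorption(lam) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("func", [baseline_absorption, melanin_absorption])
    def test_nonpositive_wavelength_rejected(self, func):
        with pytest.raises(ValueError):
            func(0)
        with pytest.raises(ValueError):
            func(-905)

    def test_epidermis_degenerate_mixtures(self):
        base = EpidermisAbsorptionParams(V_m=0.0, V_w=0.0)
        assert epidermis_absorption(905, base) == pytest.approx(
            baseline_absorption(905), rel=1e-12)
        pure_mel = EpidermisAbsorptionParams(V_m=1.0, V_w=0.0)
        assert epidermis_absorption(905, pure_mel) == pytest.approx(
            melanin_absorption(905), rel=1e-12)

    def test_epidermis_convex_combination(self):
        # independent arithmetic: explicit weighted sum of the constituents
        params = EpidermisAbsorptionParams(V_m=0.10, V_w=0.20, mu_a_wat=0.0075)
        expected = (0.10 * melanin_absorption(905)
                    + 0.20 * 0.0075
                    + 0.70 * baseline_absorption(905))
        assert epidermis_absorption(905, params) == pytest.approx(expected, rel=1e-12)

    def test_epidermis_fraction_validation(self):
        with pytest.raises(ValueError):
            EpidermisAbsorptionParams(V_m=0.7, V_w=0.5)
        with pytest.raises(ValueError):
            EpidermisAbsorptionParams(V_m=-0.1, V_w=0.2)

    def test_stratum_corneum_pure_water_limit(self):
        assert stratum_corneum_absorption(905, 1.0, 0.0075) == pytest.approx(0.0075)

    def test_stratum_corneum_dry_value(self):
        # frozen from direct evaluation: (0.1 - 0.3e-4*905) + 0.125*mu_a0(905)
        assert stratum_corneum_absorption(905, 0.0, 0.0075) == pytest.approx(
            0.0751798874947101, rel=1e-10)

    def test_stratum_corneum_mixture(self):
        dry = stratum_corneum_absorption(905, 0.0, 0.0267)
        mixed = stratum_corneum_absorption(905, 0.05, 0.0267)
        assert mixed == pytest.approx(0.95 * dry + 0.05 * 0.0267, rel=1e-12)

    def test_composite_absorption_against_loop(self):
        spec = CompositeAbsorptionSpec(
            component_mu_a=(0.5, 1.2), volume_fractions=(0.3, 0.2),
            baseline_mu_a=0.02)
        total = 0.0  # brute-force loop oracle
        for mu, v in zip(spec.component_mu_a, spec.volume_fractions):
            total += mu * v
        total += spec.baseline_mu_a * (1 - sum(spec.volume_fractions))
        assert composite_absorption(spec) == pytest.approx(total, rel=1e-12)

    def test_composite_degenerate_cases(self):
        one = CompositeAbsorptionSpec((0.7,), (1.0,), 0.02)
        assert composite_absorption(one) == pytest.approx(0.7)
        none = CompositeAbsorptionSpec((0.7, 0.3), (0.0, 0.0), 0.02)
        assert composite_absorption(none) == pytest.approx(0.02)

    def test_composite_length_mismatch(self):
        with pytest.raises(ValueError):
            CompositeAbsorptionSpec((0.1, 0.2), (0.5,), 0.02)


class TestArteryModel:
    def test_unit_pressure_diameter(self):
        assert artery_diameter(1.0) == pytest.approx(0.8531, rel=1e-12)

    def test_diameter_at_100_mmHg(self):
        assert artery_diameter(100.0) == pytest.approx(0.8531 * 100 ** 0.1023,
                                                       rel=1e-12)

    def test_diameter_strictly_increasing(self):
        p = np.linspace(42, 200, 159)
        d = artery_diameter(p)
        assert np.all(np.diff(d) > 0)
        assert artery_diameter(200) > artery_diameter(42)

    def test_diameter_rejects_nonpositive_pressure(self):
        with pytest.raises(ValueError):
            artery_diameter(0.0)

    def test_volume_fractions_no_wall(self):
        vb, vw = artery_volume_fractions(1.0, 0.0)
        assert vb == pytest.approx(1.0) and vw == pytest.approx(0.0)

    def test_volume_fractions_large_diameter_limit(self):
        vb, _ = artery_volume_fractions(1e6, 0.2)
        assert vb == pytest.approx(1.0, abs=1e-6)

    def test_volume_fractions_arithmetic(self):
        d = 1.3668
        vb, vw = artery_volume_fractions(d, 0.2)
        assert vb == pytest.approx(0.6834 ** 2 / 0.8834 ** 2, rel=1e-12)
        assert vb + vw == pytest.approx(1.0, abs=1e-15)

    def test_v_blood_increasing_in_diameter(self):
        d = np.linspace(0.5, 2.0, 40)
        vb = np.array([artery_volume_fractions(x, 0.2)[0] for x in d])
        assert np.all(np.diff(vb) > 0)

    def test_artery_absorption_table_values(self):
        assert artery_absorption(905, 1.0, 0.0) == pytest.approx(0.011160)
        assert artery_absorption(940, 0.0, 1.0) == pytest.approx(0.009316)

    def test_artery_absorption_mixture(self):
        expected = 0.5985 * 0.011778 + 0.4015 * 0.009316
        assert artery_absorption(940, 0.5985, 0.4015) == pytest.approx(
            expected, rel=1e-12)

    def test_artery_absorption_unknown_wavelength(self):
        with pytest.raises(KeyError):
            artery_absorption(800, 0.5, 0.5)
        val = artery_absorption(800, 0.5, 0.5,
                                blood_mu_a={800: 0.01}, wall_mu_a={800: 0.02})
        assert val == pytest.approx(0.015)

    def test_artery_state_invariants(self):
        st = artery_state(100, 940)
        assert st.v_blood + st.v_vw == pytest.approx(1.0, abs=1e-12)
        assert st.v_blood == pytest.approx(st.V_B / st.V_T, rel=1e-12)
        assert st.V_T == pytest.approx(st.V_B + st.V_VW, rel=1e-12)
        assert st.outer_diameter == pytest.approx(st.diameter + 0.4)


class TestDefaultProperties:
    @pytest.mark.parametrize("lam", [905, 940])
    def test_table_constants_exact(self, lam):
        """Assembled layer properties equal the packaged constants exactly."""
        props = tissue.DEFAULT_PROPERTIES[lam]
        assert props["stratum_corneum"].mu_a == (0.11350 if lam == 905 else 0.09745)
        assert props["stratum_corneum"].mu_s == 100.0
        assert props["deep_blood_net_dermis"].g == 0.95
        assert props["fat"].mu_s == (6.33 if lam == 905 else 5.42)
        assert props["bone"].n == 1.37
        for p in props.values():
            assert p.mu_a >= 0 and p.mu_s >= 0 and -1 <= p.g <= 1 and p.n >= 1

    def test_invalid_layer_properties_rejected(self):
        with pytest.raises(ValueError):
            LayerOpticalProperties("x", mu_a=-0.1, mu_s=1, g=0, n=1.4)
        with pytest.raises(ValueError):
            LayerOpticalProperties("x", mu_a=0.1, mu_s=1, g=1.5, n=1.4)
        with pytest.raises(ValueError):
            LayerOpticalProperties("x", mu_a=0.1, mu_s=1, g=0, n=0.9)


class TestVoxelBuilder:
    def test_artery_voxels_monotone_in_pressure(self):
        g = FingerGeometrySpec(lateral_extent=2.0)
        counts = [build_voxel_model(g, p, 940).artery_voxel_count()
                  for p in (42, 100, 200)]
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[0] > 0

    def test_stratum_corneum_single_voxel_layer(self):
        g = FingerGeometrySpec(lateral_extent=1.0)
        grid = build_voxel_model(g, 100, 940)
        sc_label = next(i for i, p in grid.property_lut.items()
                        if p.layer_name == "stratum_corneum")
        profile = grid.labels[0, 0, :]
        assert (profile == sc_label).sum() == 2  # one per mirrored side
        assert profile[0] == sc_label and profile[-1] == sc_label

    def test_total_depth_matches_stack_plus_artery_band(self):
        g = FingerGeometrySpec(lateral_extent=1.0)
        grid = build_voxel_model(g, 100, 940)
        stack_sum = sum(t for _, t in g.layer_stack)          # 5.0 mm
        mirrored = 2 * stack_sum - g.layer_stack[-1][1]       # bone not doubled
        expected = mirrored + grid.artery.outer_diameter
        assert abs(grid.total_thickness - expected) <= 2 * g.voxel_pitch

    def test_deterministic_build(self):
        g = FingerGeometrySpec(lateral_extent=2.0)
        h1 = build_voxel_model(g, 120, 905).content_hash()
        h2 = build_voxel_model(g, 120, 905).content_hash()
        assert h1 == h2

    def test_every_label_resolves(self):
        grid = build_voxel_model(FingerGeometrySpec(lateral_extent=2.0), 80, 940)
        assert set(np.unique(grid.labels)) <= set(grid.property_lut)

    def test_two_media_artery(self):
        g = FingerGeometrySpec(lateral_extent=2.0, homogenize_artery=False)
        grid = build_voxel_model(g, 100, 940)
        names = {p.layer_name for p in grid.property_lut.values()}
        assert {"artery_lumen", "artery_wall"} <= names
        st = grid.artery
        lumen = next(i for i, p in grid.property_lut.items()
                     if p.layer_name == "artery_lumen")
        wall = next(i for i, p in grid.property_lut.items()
                    if p.layer_name == "artery_wall")
        assert grid.property_lut[lumen].mu_a == pytest.approx(st.mu_blood)
        assert grid.property_lut[wall].mu_a == pytest.approx(st.mu_vw)

    def test_overwrite_mode_overflow_raises(self):
        g = FingerGeometrySpec(lateral_extent=2.0, artery_embedding="overwrite")
        with pytest.raises(GeometryError):
            build_voxel_model(g, 100, 940)

    def test_compact_geometry_accepts_full_pressure_range(self):
        g = compact_benchmark_geometry(lateral_extent=2.0)
        for p in (42, 200):
            grid = build_voxel_model(g, p, 940)
            z0, z1 = grid.artery_z_range
            b0, b1 = grid.dermal_band_z()
            assert b0 <= z0 and z1 <= b1

    def test_hdf5_export(self, tmp_path):
        import h5py

        grid = build_voxel_model(FingerGeometrySpec(lateral_extent=1.0), 90, 905)
        path = tmp_path / "grid.h5"
        grid.to_hdf5(path)
        with h5py.File(path) as f:
            assert np.array_equal(f["labels"][...], grid.labels)
            assert f.attrs["pressure_mmHg"] == 90.0
            assert str(len(grid.property_lut) - 1) in f["properties"]

    def test_out_of_range_pressure_warns(self):
        g = FingerGeometrySpec(lateral_extent=1.0)
        with pytest.warns(UserWarning):
            build_voxel_model(g, 220, 940)

    def test_unknown_wavelength_needs_overrides(self):
        g = FingerGeometrySpec(lateral_extent=1.0)
        with pytest.raises(KeyError):
            build_voxel_model(g, 100, 800)
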