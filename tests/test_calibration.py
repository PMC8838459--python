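"""Calibration dataset construction and boosted-tree fitting."""

import numpy as np
import pandas as pd
import pytest

from mcbp.calibration import (FEATURE_COLUMNS, CalibrationDataset,
                              CalibrationModel, build_calibration_dataset,
                              fit_calibration, predict_calibrated_intensity)


def synthetic_features(n, seed=0, smooth_target=True):
    """Feature frame + reference pressures whose table targets are a smooth
    function of the features (by construction of the affine coupling)."""
    rng = np.random.default_rng(seed)
    sbp = rng.uniform(85, 180, n)
    dbp = rng.uniform(50, 95, n)
    feats = pd.DataFrame({
        "systolic_intensity": 2e5 - 800.0 * np.log(sbp),
        "diastolic_intensity": 2e5 - 800.0 * np.log(dbp),
        "skewness": rng.normal(0.8, 0.1, n),
        "kurtosis": rng.normal(0.2, 0.1, n),
        "bmi": rng.uniform(19, 34, n),
        "pulse_rate": rng.uniform(55, 105, n),
    }, index=pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id"))
    refs = pd.DataFrame({"sbp": sbp, "dbp": dbp}, index=feats.index)
    return feats, refs


class TestDatasetConstruction:
    def test_grid_point_target_exact(self, synthetic_table):
        feats, refs = synthetic_features(25, seed=1)
        refs.iloc[0, refs.columns.get_loc("sbp")] = 100.0  # exact grid point
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        i = list(ds.features.index).index(refs.index[0])
        grid_i = np.where(synthetic_table.pressures == 100.0)[0][0]
        assert ds.targets[i] == synthetic_table.intensities[grid_i]

    def test_row_count_preserved(self, synthetic_table):
        feats, refs = synthetic_features(30, seed=2)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        assert len(ds.features) == 30 and len(ds.targets) == 30

    def test_diastolic_branch_ignores_sbp(self, synthetic_table):
        feats, refs = synthetic_features(25, seed=3)
        ds1 = build_calibration_dataset(feats, refs, synthetic_table, "diastolic")
        refs_perm = refs.copy()
        refs_perm["sbp"] = np.random.default_rng(0).permutation(refs["sbp"].values)
        ds2 = build_calibration_dataset(feats, refs_perm, synthetic_table,
                                        "diastolic")
        np.testing.assert_array_equal(ds1.targets, ds2.targets)

    def test_out_of_range_reference_excluded(self, synthetic_table):
        feats, refs = synthetic_features(25, seed=4)
        refs.iloc[0, refs.columns.get_loc("sbp")] = 230.0
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        assert refs.index[0] in ds.excluded
        assert len(ds.features) == 24

    def test_missing_values_rejected(self, synthetic_table):
        feats, refs = synthetic_features(25, seed=5)
        feats.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            build_calibration_dataset(feats, refs, synthetic_table, "systolic")


class TestFitting:
    def test_noiseless_smooth_mapping_recovered(self, synthetic_table):
        """Targets an exact smooth function of the features: CV R^2 >= 0.99."""
        feats, refs = synthetic_features(200, seed=6)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        model = fit_calibration(ds, seed=0)
        assert model.cv_r2 >= 0.99

    def test_pure_noise_target_not_learnable(self, synthetic_table):
        feats, refs = synthetic_features(200, seed=7)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        rng = np.random.default_rng(1)
        noise = rng.permutation(ds.targets)  # break any feature relation
        ds_noise = CalibrationDataset(branch="systolic", features=ds.features,
                                      targets=noise)
        model = fit_calibration(ds_noise, seed=0)
        assert model.cv_r2 <= 0.1

    def test_determinism(self, synthetic_table):
        feats, refs = synthetic_features(40, seed=8)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        m1 = fit_calibration(ds, seed=5)
        m2 = fit_calibration(ds, seed=5)
        assert m1.cv_r2 == m2.cv_r2
        p1 = predict_calibrated_intensity(m1, feats)
        p2 = predict_calibrated_intensity(m2, feats)
        np.testing.assert_array_equal(p1, p2)

    def test_row_order_invariant_cv(self, synthetic_table):
        feats, refs = synthetic_features(40, seed=9)
        perm = np.random.default_rng(0).permutation(len(feats))
        ds1 = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        ds2 = build_calibration_dataset(feats.iloc[perm], refs, synthetic_table,
                                        "systolic")
        m1 = fit_calibration(ds1, seed=5)
        m2 = fit_calibration(ds2, seed=5)
        assert m1.cv_r2 == pytest.approx(m2.cv_r2, rel=1e-6)

    def test_too_few_rows(self, synthetic_table):
        feats, refs = synthetic_features(10, seed=10)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        with pytest.raises(ValueError):
            fit_calibration(ds)

    def test_constant_target_rejected(self, synthetic_table):
        feats, _ = synthetic_features(25, seed=11)
        ds = CalibrationDataset(branch="systolic", features=feats,
                                targets=np.full(25, 0.02))
        with pytest.raises(ValueError):
            fit_calibration(ds)

    def test_branch_independence(self, synthetic_table):
        """Changing diastolic targets never changes systolic predictions."""
        feats, refs = synthetic_features(30, seed=12)
        ds_sys = build_calibration_dataset(feats, refs, synthetic_table,
                                           "systolic")
        m_sys = fit_calibration(ds_sys, seed=3)
        base = predict_calibrated_intensity(m_sys, feats)
        refs2 = refs.copy()
        refs2["dbp"] = refs2["dbp"] * 0.9
        ds_sys2 = build_calibration_dataset(feats, refs2, synthetic_table,
                                            "systolic")
        m_sys2 = fit_calibration(ds_sys2, seed=3)
        np.testing.assert_array_equal(
            base, predict_calibrated_intensity(m_sys2, feats))


class TestPrediction:
    def test_training_rows_reproduced(self, synthetic_table):
        feats, refs = synthetic_features(50, seed=13)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        model = fit_calibration(ds, seed=0)
        pred = predict_calibrated_intensity(model, ds.features)
        rel = np.abs(pred - ds.targets) / np.abs(ds.targets)
        assert rel.max() < 0.01

    def test_column_order_invariance(self, synthetic_table):
        feats, refs = synthetic_features(30, seed=14)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        model = fit_calibration(ds, seed=0)
        shuffled = feats[list(reversed(FEATURE_COLUMNS))]
        np.testing.assert_array_equal(
            predict_calibrated_intensity(model, feats),
            predict_calibrated_intensity(model, shuffled))

    def test_single_mapping_input(self, synthetic_table):
        feats, refs = synthetic_features(30, seed=15)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        model = fit_calibration(ds, seed=0)
        row = feats.iloc[0].to_dict()
        out = predict_calibrated_intensity(model, row)
        assert out.shape == (1,) and np.isfinite(out[0]) and out[0] >= 0

    def test_missing_feature_rejected(self, synthetic_table):
        feats, refs = synthetic_features(30, seed=16)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        model = fit_calibration(ds, seed=0)
        with pytest.raises(ValueError):
            predict_calibrated_intensity(model, {"systolic_intensity": 1.0})

    def test_save_load_round_trip(self, synthetic_table, tmp_path):
        feats, refs = synthetic_features(30, seed=17)
        ds = build_calibration_dataset(feats, refs, synthetic_table, "systolic")
        model = fit_calibration(ds, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        back = CalibrationModel.load(path)
        np.testing.assert_allclose(
            predict_calibrated_intensity(back, feats),
            predict_calibrated_intensity(model, feats), rtol=1e-6)
        assert back.branch == "systolic"
        fi = back.feature_importances
        assert fi.sum() == pytest.approx(1.0, abs=1e-6)
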