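import numpy as np
import pytest
from scipy import stats

from photobf import shape
from photobf.errors import InsufficientSampleError, ValidationError
from photobf.model import (
    FeatureScaler,
    SubjectRecord,
    SVRConfig,
    _design_matrix,
    _feature_columns,
    build_features,
    cross_validate,
    grid_search_train,
    split_strata,
)
from photobf.shape import BSEncoding, ShapeCurves


def _record(i, rng, bf=None, bv=None, with_curves=False, fc_offset=0.0):
    h = float(rng.uniform(155, 190))
    bmi = float(rng.uniform(18, 40))
    w = bmi * (h / 100) ** 2
    bv = float(rng.uniform(45, 110)) if bv is None else bv
    bf = float(np.clip(0.3 * bv + 10.0 if bf is None else bf, 1.0, 69.0))
    curves = None
    if with_curves:
        curves = ShapeCurves(
            fc=np.full(12, 30.0 + fc_offset) + rng.normal(0, 0.3, 12),
            sc=np.full(12, 10.0 + fc_offset) + rng.normal(0, 0.3, 12),
            trunk_span=(0, 100),
        )
    return SubjectRecord(
        subject_id=f"s{i}", age=float(rng.uniform(20, 70)), sex=int(rng.random() < 0.5),
        race=int(rng.random() < 0.5), height_cm=h, weight_kg=w, bmi=bmi,
        bf_dxa_pct=bf, bv_photo_L=bv, curves=curves,
    )


def _cohort(n, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return [_record(i, rng, **kw) for i in range(n)]


class TestSubjectRecord:
    def test_bmi_consistency_enforced(self):
        rng = np.random.default_rng(0)
        rec = _record(0, rng)
        with pytest.raises(ValidationError):
            SubjectRecord(
                subject_id="x", age=30, sex=0, race=0, height_cm=170, weight_kg=70,
                bmi=30.0, bf_dxa_pct=25.0, bv_photo_L=70.0,
            )

    def test_bf_range_enforced(self):
        with pytest.raises(ValidationError):
            SubjectRecord(
                subject_id="x", age=30, sex=0, race=0, height_cm=170, weight_kg=70,
                bmi=70 / 1.7**2, bf_dxa_pct=75.0, bv_photo_L=70.0,
            )


class TestBuildFeatures:
    def test_nophoto_length_four(self):
        rec = _cohort(1)[0]
        assert build_features(rec, "nophoto").shape == (4,)

    def test_volume_shape_length(self):
        rec = _cohort(1)[0]
        enc = BSEncoding(fc_onehot=np.eye(4)[1], sc_onehot=np.eye(3)[0])
        assert build_features(rec, "volume_shape", enc).shape == (4 + 1 + 4 + 3,)

    def test_missing_field_named(self):
        rec = _cohort(1)[0]
        object.__setattr__(rec, "age", None)
        with pytest.raises(ValidationError, match="age"):
            build_features(rec, "nophoto")

    def test_standardized_columns_mean0_sd1(self):
        recs = _cohort(40)
        X = np.vstack([build_features(r, "volume") for r in recs])
        cols = _feature_columns("volume", None)
        scaler = FeatureScaler.fit(X, cols)
        Z = scaler.transform(X)
        assert np.allclose(Z[:, scaler.continuous_idx].mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z[:, scaler.continuous_idx].std(axis=0), 1, atol=1e-12)
        # binary indicators untouched
        sex_col = cols.index("sex")
        assert set(np.unique(Z[:, sex_col])) <= {0.0, 1.0}


class TestGridSearch:
    def test_noiseless_target_recovered(self):
        recs = _cohort(90, seed=5)
        train, test = recs[:60], recs[60:]
        model = grid_search_train(train, SVRConfig.coarse(seed=0), "volume")
        X, y, _ = _design_matrix(test, "volume", None)
        r = np.corrcoef(model.predict(X), y)[0, 1]
        assert r >= 0.99

    def test_deterministic_hyperparameters(self):
        recs = _cohort(40, seed=7)
        m1 = grid_search_train(recs, SVRConfig.coarse(seed=3), "nophoto")
        m2 = grid_search_train(recs, SVRConfig.coarse(seed=3), "nophoto")
        assert (m1.gamma, m1.cost, m1.nu) == (m2.gamma, m2.cost, m2.nu)

    def test_permuted_target_control(self):
        """Shuffled labels must not yield significantly positive held-out r."""
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = _cohort(40, seed=seed)
            y = np.array([r.bf_dxa_pct for r in recs])
            perm = rng.permutation(y)
            shuffled = [
                SubjectRecord(
                    subject_id=r.subject_id, age=r.age, sex=r.sex, race=r.race,
                    height_cm=r.height_cm, weight_kg=r.weight_kg, bmi=r.bmi,
                    bf_dxa_pct=float(p), bv_photo_L=r.bv_photo_L,
                )
                for r, p in zip(recs, perm)
            ]
            model = grid_search_train(shuffled[:27], SVRConfig.coarse(seed=seed), "volume")
            X, yt, _ = _design_matrix(shuffled[27:], "volume", None)
            pred = model.predict(X)
            if np.std(pred) == 0:  # degenerate flat predictor: no association
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(pred, yt)[0, 1]))
        t, p_two = stats.ttest_1samp(rs, 0.0)
        p_one = p_two / 2 if t > 0 else 1 - p_two / 2
        assert p_one > 0.05

    def test_zero_variance_target_rejected(self):
        recs = _cohort(30, seed=1)
        flat = [
            SubjectRecord(
                subject_id=r.subject_id, age=r.age, sex=r.sex, race=r.race,
                height_cm=r.height_cm, weight_kg=r.weight_kg, bmi=r.bmi,
                bf_dxa_pct=25.0, bv_photo_L=r.bv_photo_L,
            )
            for r in recs
        ]
        with pytest.raises(ValidationError):
            grid_search_train(flat, SVRConfig.coarse(seed=0), "nophoto")

    def test_nu_one_accepted_by_backend(self):
        recs = _cohort(25, seed=2)
        cfg = SVRConfig(gamma_exponents=(-2,), cost_exponents=(2,), nu_grid=(1.0,), seed=0)
        model = grid_search_train(recs, cfg, "nophoto")
        assert model.nu == 1.0

    def test_full_grid_is_as_printed(self):
        cfg = SVRConfig()
        assert cfg.gamma_exponents == tuple(range(-10, 11))
        assert cfg.cost_exponents == tuple(range(-10, 11))
        assert len(cfg.nu_grid) == 10
        assert cfg.nu_grid[0] == 0.1 and cfg.nu_grid[-1] == 1.0


@pytest.fixture(scope="module")
def cv_result():
    cohort = _cohort(45, seed=3, with_curves=True)
    return cohort, cross_validate(cohort, SVRConfig.coarse(seed=0), seed=0)


class TestCrossValidate:
    def test_every_subject_predicted_once(self, cv_result):
        cohort, res = cv_result
        assert sorted(res.predictions["subject_id"]) == sorted(r.subject_id for r in cohort)
        assert res.predictions["subject_id"].is_unique

    def test_fold_sizes_balanced(self, cv_result):
        _, res = cv_result
        sizes = res.predictions.groupby("fold").size()
        assert sizes.max() - sizes.min() <= 1

    def test_no_leakage_scaler_from_train_only(self, cv_result):
        cohort, res = cv_result
        by_id = {r.subject_id: r for r in cohort}
        for prov in res.provenance:
            train = [by_id[i] for i in prov.train_ids]
            X = np.vstack([build_features(r, "nophoto") for r in train])
            expected = FeatureScaler.fit(X, _feature_columns("nophoto", None)).mean
            assert np.allclose(prov.scaler_means["nophoto"][: len(expected)], expected)

    def test_no_leakage_centroids_from_train_only(self, cv_result):
        from photobf.model import _hash_centroids

        cohort, res = cv_result
        by_id = {r.subject_id: r for r in cohort}
        for prov in res.provenance:
            refit = shape.fit_shape_clusters(
                [by_id[i].curves for i in prov.train_ids], seed=0
            )
            assert _hash_centroids(refit) == prov.centroid_hash

    def test_folds_disjoint(self, cv_result):
        _, res = cv_result
        for prov in res.provenance:
            assert not set(prov.train_ids) & set(prov.test_ids)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InsufficientSampleError):
            cross_validate(_cohort(20, with_curves=True), SVRConfig.coarse(), seed=0)


def test_split_strata_by_age():
    rng = np.random.default_rng(0)
    recs = _cohort(10)
    strata = split_strata(recs)
    assert all(r.age >= 19 for r in strata["adults"])
    assert all(r.age < 19 for r in strata["children"])
    assert len(strata["adults"]) + len(strata["children"]) == len(recs)
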