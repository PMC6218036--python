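import numpy as np
import pytest

from photobf import shape
from photobf.anatomy import KeyPoints
from photobf.errors import InsufficientSampleError, ResolutionError, ValidationError
from photobf.imaging import BACK, SIDE, BodyMask
from photobf.shape import ShapeCurves, encode_shape, extract_curves, fit_shape_clusters


def _trunk_pair(widths_cm, side_width_cm=20.0, scale=0.5, h_cm=100.0):
    """Back mask with per-row width from a top->bottom profile; boxy side mask."""
    n_rows = int(h_cm / scale)
    n_cols = 240
    back = np.zeros((n_rows + 40, n_cols), dtype=bool)
    cx = n_cols // 2
    for i in range(n_rows):
        t = i / (n_rows - 1)
        w_px = int(round(np.interp(t, np.linspace(0, 1, len(widths_cm)), widths_cm) / scale))
        back[20 + i, cx - w_px // 2 : cx - w_px // 2 + w_px] = True
    side = np.zeros_like(back)
    w_px = int(side_width_cm / scale)
    side[20 : 20 + n_rows, cx - w_px // 2 : cx - w_px // 2 + w_px] = True
    bm = BodyMask(back, BACK, scale_cm_per_px=scale)
    sm = BodyMask(side, SIDE, scale_cm_per_px=scale)
    kp = KeyPoints(
        left_upper=(20, int(cx - widths_cm[0] / scale / 2)),
        right_upper=(20, int(cx + widths_cm[0] / scale / 2)),
        lower=(20 + n_rows - 1, cx),
        head_top=(19, cx),
    )
    return bm, sm, kp


class TestExtractCurves:
    def test_rectangular_trunk_constant_fc(self):
        bm, sm, kp = _trunk_pair([40.0, 40.0])
        curves = extract_curves(bm, sm, kp)
        assert np.allclose(curves.fc, 40.0, atol=0.5)

    def test_flat_side_contour_constant_sc(self):
        bm, sm, kp = _trunk_pair([40.0, 40.0], side_width_cm=20.0)
        curves = extract_curves(bm, sm, kp)
        assert np.ptp(curves.sc) <= 0.5  # rectangle centered on the CBL
        assert np.allclose(curves.sc, 10.0, atol=0.5)  # back edge at +w/2

    def test_trapezoid_fc_linear(self):
        bm, sm, kp = _trunk_pair([40.0, 30.0])
        curves = extract_curves(bm, sm, kp)
        expected = np.linspace(40.0, 30.0, 12)
        assert np.allclose(curves.fc, expected, atol=0.5 + 1e-9)  # 1 px at 0.5 cm/px

    def test_fc_invariant_to_horizontal_translation(self):
        bm, sm, kp = _trunk_pair([40.0, 34.0])
        rolled = BodyMask(np.roll(bm.mask, 15, axis=1), BACK, bm.scale_cm_per_px)
        kp2 = KeyPoints(
            left_upper=(kp.left_upper[0], kp.left_upper[1] + 15),
            right_upper=(kp.right_upper[0], kp.right_upper[1] + 15),
            lower=(kp.lower[0], kp.lower[1] + 15),
            head_top=(kp.head_top[0], kp.head_top[1] + 15),
        )
        c1 = extract_curves(bm, sm, kp)
        c2 = extract_curves(rolled, sm, kp2)
        assert np.allclose(c1.fc, c2.fc)

    def test_sc_invariant_to_background_columns(self):
        bm, sm, kp = _trunk_pair([40.0, 34.0])
        padded = BodyMask(
            np.pad(sm.mask, ((0, 0), (0, 37))), SIDE, sm.scale_cm_per_px
        )
        c1 = extract_curves(bm, sm, kp)
        c2 = extract_curves(bm, padded, kp)
        assert np.allclose(c1.sc, c2.sc)

    def test_short_trunk_resolution_error(self):
        bm, sm, kp = _trunk_pair([40.0, 40.0])
        kp_short = KeyPoints(
            left_upper=kp.left_upper,
            right_upper=kp.right_upper,
            lower=(kp.left_upper[0] + 20, kp.lower[1]),
            head_top=kp.head_top,
        )
        with pytest.raises(ResolutionError):
            extract_curves(bm, sm, kp_short)

    def test_exactly_twelve_points(self, phantom_features):
        assert phantom_features.curves.fc.shape == (12,)
        assert phantom_features.curves.sc.shape == (12,)


def _blob_curves(k, n_per, seed, sep=10.0):
    rng = np.random.default_rng(seed)
    centers = 30.0 + np.arange(k)[:, None] * sep
    X = np.vstack([rng.normal(c, 0.5, size=(n_per, 12)) for c in centers])
    return [ShapeCurves(fc=x, sc=x - 25.0, trunk_span=(0, 100)) for x in X]


class TestClustering:
    @pytest.mark.parametrize("k", [2, 3])
    def test_recovers_planted_k(self, k):
        model = fit_shape_clusters(_blob_curves(k, 30, seed=5), seed=0)
        assert model.k_fc == k
        assert model.k_sc == k

    def test_deterministic_given_seed(self):
        curves = _blob_curves(3, 20, seed=8)
        m1 = fit_shape_clusters(curves, seed=11)
        m2 = fit_shape_clusters(curves, seed=11)
        assert np.array_equal(m1.fc.centroids, m2.fc.centroids)
        assert np.array_equal(m1.sc.centroids, m2.sc.centroids)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            fit_shape_clusters(_blob_curves(2, 5, seed=1), seed=0)

    def test_calinski_harabasz_matches_bruteforce(self):
        # Independent implementation of the between/within dispersion ratio
        # [(B/(k-1)) / (W/(n-k))] checked against the fitted criterion trace.
        curves = _blob_curves(3, 9, seed=2)  # n = 27 <= 30
        X = np.vstack([c.fc for c in curves])
        model = fit_shape_clusters(curves, seed=0)
        from sklearn.cluster import KMeans

        for k, score in model.fc.criterion_scores.items():
            labels = KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(X)
            overall = X.mean(axis=0)
            B = sum(
                (labels == j).sum() * np.sum((X[labels == j].mean(axis=0) - overall) ** 2)
                for j in range(k)
            )
            W = sum(
                np.sum((X[labels == j] - X[labels == j].mean(axis=0)) ** 2)
                for j in range(k)
            )
            brute = (B / (k - 1)) / (W / (len(X) - k))
            assert score == pytest.approx(brute, abs=1e-9 * max(1.0, brute))


class TestEncoding:
    def test_training_encodings_match_assignments(self):
        curves = _blob_curves(3, 20, seed=3)
        model = fit_shape_clusters(curves, seed=0)
        for c, label in zip(curves, model.fc.labels):
            enc = encode_shape(c, model)
            assert enc.fc_onehot[label] == 1.0

    def test_onehot_sums_to_one(self):
        curves = _blob_curves(2, 15, seed=4)
        model = fit_shape_clusters(curves, seed=0)
        enc = encode_shape(curves[0], model)
        assert enc.fc_onehot.sum() == 1.0
        assert enc.sc_onehot.sum() == 1.0

    def test_centroid_exact_hit(self):
        curves = _blob_curves(3, 20, seed=6)
        model = fit_shape_clusters(curves, seed=0)
        probe = ShapeCurves(
            fc=model.fc.centroids[1], sc=model.sc.centroids[0], trunk_span=(0, 1)
        )
        enc = encode_shape(probe, model)
        assert enc.fc_onehot[1] == 1.0
        assert enc.sc_onehot[0] == 1.0

    def test_tie_breaks_to_lowest_index(self):
        from photobf.shape import CurveClustering, ShapeClusterModel

        cents = np.vstack([np.full(12, 1.0), np.full(12, 3.0)])
        sub = CurveClustering(k=2, centroids=cents, criterion_scores={},
                              labels=np.array([0, 1]), seed=0)
        model = ShapeClusterModel(fc=sub, sc=sub)
        probe = ShapeCurves(fc=np.full(12, 2.0), sc=np.full(12, 2.0), trunk_span=(0, 1))
        enc = encode_shape(probe, model)
        assert enc.fc_onehot[0] == 1.0

    def test_nonfinite_curves_rejected(self):
        curves = _blob_curves(2, 15, seed=9)
        model = fit_shape_clusters(curves, seed=0)
        bad = ShapeCurves(fc=np.full(12, 5.0), sc=np.full(12, np.nan), trunk_span=(0, 1))
        with pytest.raises(ValidationError):
            encode_shape(bad, model)
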