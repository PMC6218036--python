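import math

import numpy as np
import pytest

from photobf.agreement import bland_altman, compare_methods, lin_ccc, meng_test
from photobf.errors import ValidationError


def _triple(seed=0, n=20):
    rng = np.random.default_rng(seed)
    x = rng.normal(30, 8, n)
    y1 = x + rng.normal(0, 3, n)
    y2 = 0.7 * x + rng.normal(0, 6, n)
    return x, y1, y2


def _meng_bruteforce(x, y1, y2):
    """Step-by-step evaluation of the dependent-correlation Z formula."""
    n = len(x)
    r1 = np.corrcoef(x, y1)[0, 1]
    r2 = np.corrcoef(x, y2)[0, 1]
    r12 = np.corrcoef(y1, y2)[0, 1]
    z1 = 0.5 * math.log((1 + r1) / (1 - r1))
    z2 = 0.5 * math.log((1 + r2) / (1 - r2))
    rbar2 = (r1 * r1 + r2 * r2) / 2
    f = (1 - r12) / (2 * (1 - rbar2))
    f = 1.0 if f > 1.0 else f
    h = (1 - f * rbar2) / (1 - rbar2)
    return (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r12) * h))


class TestMengTest:
    def test_equal_correlations_give_zero(self):
        x, y1, _ = _triple()
        y2 = y1 * 2.0 + 5.0  # same correlation with x, r12 < 1
        z, p = meng_test(x, y1, y2)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_stepwise_formula(self):
        x, y1, y2 = _triple(seed=3)
        z, _ = meng_test(x, y1, y2)
        assert z == pytest.approx(_meng_bruteforce(x, y1, y2), abs=1e-8)

    def test_antisymmetric(self):
        x, y1, y2 = _triple(seed=4)
        z12, _ = meng_test(x, y1, y2)
        z21, _ = meng_test(x, y2, y1)
        assert z12 == -z21

    def test_scale_invariance(self):
        x, y1, y2 = _triple(seed=5)
        z, _ = meng_test(x, y1, y2)
        z_scaled, _ = meng_test(x, 3.7 * y1, y2)
        assert z == pytest.approx(z_scaled, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            meng_test([1, 2, 3], [1, 2, 3.1], [3, 2, 1])

    def test_perfect_correlation_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValidationError):
            meng_test(x, x.copy(), x[::-1] + np.random.default_rng(0).normal(0, 1, 10))


class TestLinCCC:
    def test_identity_gives_one(self):
        x = np.random.default_rng(0).normal(30, 5, 50)
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_constant_offset_closed_form(self):
        # var(x) = v, y = x + c  ->  ccc = 2v / (2v + c^2); v = 1, c = 1 -> 2/3
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200_000)
        v = np.var(x)
        c = 1.0
        assert lin_ccc(x, x + c) == pytest.approx(2 * v / (2 * v + c**2), abs=1e-12)
        assert lin_ccc(x, x + c) == pytest.approx(2 / 3, abs=0.01)

    def test_sign_flip_gives_minus_one(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])  # mean zero
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 40)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 40)
            assert abs(lin_ccc(x, y)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_double_constant_rejected(self):
        with pytest.raises(ValidationError):
            lin_ccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.random.default_rng(0).normal(30, 5, 30)
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_constant_offset(self):
        x = np.random.default_rng(1).normal(30, 5, 30)
        ba = bland_altman(x, x + 1.0)
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert (ba.loa_low, ba.loa_high) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_mean_diff_equals_mean_difference_exactly(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(30, 5, 100), rng.normal(31, 6, 100)
        ba = bland_altman(x, y)
        assert ba.mean_diff == pytest.approx(np.mean(y) - np.mean(x), abs=1e-12)

    def test_gaussian_coverage_94_to_96(self):
        rng = np.random.default_rng(7)
        x = rng.normal(30, 8, 10_000)
        y = x + rng.normal(0, 2.5, 10_000)
        ba = bland_altman(x, y)
        assert 0.94 <= ba.within_limits_frac <= 0.96

    def test_relative_mode_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0, -1.0], [-1.0, 1.0], mode="relative")

    def test_limits_ordered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 1, 50)
        ba = bland_altman(x, y)
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    _vec = arrays(
        np.float64, 25,
        elements=st.floats(min_value=-50, max_value=50, allow_nan=False, width=64),
    )

    @given(x=_vec, y=_vec)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ccc_bounded_by_pearson_property(x, y):
        """Lin's inequality |ccc| <= |r| on arbitrary paired vectors."""
        if np.var(x) < 1e-6 or np.var(y) < 1e-6:
            return
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lin_ccc(x, y)) <= abs(r) + 1e-9

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_compare_methods_report_fields():
    rng = np.random.default_rng(11)
    x = rng.normal(30, 8, 80)
    photo = x + rng.normal(0, 3, 80)
    nophoto = x + rng.normal(0, 6, 80)
    rep = compare_methods(x, photo, nophoto)
    assert rep.r_dp > rep.r_db
    assert rep.z_meng > 0
    assert 0 < rep.p_two_sided <= 1
    assert abs(rep.ccc["photo"]) <= 1 and abs(rep.ccc["nophoto"]) <= 1
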