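import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coxdist import StepCurve, ccc, curve_area, curve_iou, kaplan_meier, rmse
from coxdist.errors import ValidationError


def km_oracle(time, event):
    """Brute-force product-limit estimator: explicit loop over event times.

    Returns the distinct event times and the survival probability after each.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s, out_t, out_s = 1.0, [], []
    for t in np.unique(time[event == 1]):
        at_risk = np.sum(time >= t)
        deaths = np.sum((time == t) & (event == 1))
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def random_curve(rng, max_breaks=8):
    k = rng.integers(1, max_breaks + 1)
    bp = np.sort(rng.uniform(0.5, 20.0, size=k))
    bp = np.unique(bp)
    vals = np.sort(rng.uniform(0.0, 1.0, size=bp.size))[::-1]
    return StepCurve(bp, vals, domain_end=float(bp[-1] + rng.uniform(0, 5)))


class TestKaplanMeier:
    def test_all_events_hand_example(self):
        c = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(c([1, 2, 3]), [2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert c(0.5) == 1.0

    def test_censoring_causes_no_drop(self):
        c = kaplan_meier([1, 2], [1, 0])
        assert c(1.0) == pytest.approx(0.5)
        assert c(2.0) == pytest.approx(0.5)  # censored at 2: curve stays
        assert c.domain_end == 2.0

    def test_no_events_curve_is_one(self):
        c = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert np.all(c(np.linspace(0, 3, 10)) == 1.0)

    def test_matches_brute_force_oracle_on_random_data(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = rng.integers(1, 21)
            time = rng.integers(1, 10, size=n).astype(float)  # ties likely
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                event[rng.integers(n)] = 1
            ot, os_ = km_oracle(time, event)
            c = kaplan_meier(time, event)
            np.testing.assert_allclose(c(ot), os_, rtol=1e-12, atol=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValidationError):
            kaplan_meier([0.0, 1.0], [1, 1])


class TestCurveArea:
    def test_unit_curve(self):
        c = StepCurve(np.array([10.0]), np.array([1.0]), 10.0)
        assert curve_area(c, dx=0.1, t_max=10.0) == pytest.approx(10.0)

    def test_zero_curve(self):
        # a step curve implicitly starts at 1, so the first rectangle is the
        # only nonzero term: the area is bounded by one rectangle, dx * 1
        c = StepCurve(np.array([1e-9]), np.array([0.0]), 10.0)
        assert curve_area(c, dx=0.1, t_max=10.0) <= 0.1 + 1e-12

    def test_two_step_closed_form(self):
        c = StepCurve(np.array([5.0]), np.array([0.5]), 10.0)
        assert abs(curve_area(c, dx=0.1, t_max=10.0) - 7.5) <= 0.1

    def test_halving_dx_shrinks_error_vs_exact_integral(self):
        rng = np.random.default_rng(7)
        worse = 0
        for _ in range(20):
            c = random_curve(rng)
            t_max = c.domain_end
            # exact step-function integral
            edges = np.concatenate(([0.0], c.breakpoints[c.breakpoints < t_max], [t_max]))
            exact = float(np.sum(np.diff(edges) * c(edges[:-1])))
            e1 = abs(curve_area(c, dx=0.2, t_max=t_max) - exact)
            e2 = abs(curve_area(c, dx=0.1, t_max=t_max) - exact)
            if e2 > e1 + 1e-12:
                worse += 1
            assert e1 <= 0.2 * (c.breakpoints.size + 1) * 1.0 + 1e-9
        assert worse <= 2  # halving dx shrinks the error on nearly all curves


class TestCurveIoU:
    def test_identical_curves(self):
        c = StepCurve(np.array([2.0, 5.0]), np.array([0.7, 0.2]), 8.0)
        assert curve_iou(c, c) == pytest.approx(1.0, abs=1e-12)

    def test_constant_half_curve(self):
        ones = StepCurve(np.array([10.0]), np.array([1.0]), 10.0)
        half = StepCurve(np.array([0.05]), np.array([0.5]), 10.0)
        assert abs(curve_iou(ones, half) - 0.5) <= 0.1

    def test_symmetry_and_bounds_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a, b = random_curve(rng), random_curve(rng)
            v = curve_iou(a, b)
            assert v == curve_iou(b, a)
            assert 0.0 <= v <= 1.0

    def test_degrading_predictions_lowers_iou(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(50, size=400) + 0.1
        truth = kaplan_meier(t, np.ones(400, int))
        ious = []
        for factor in (1.0, 2.0, 5.0, 10.0):
            pred = kaplan_meier(t * factor, np.ones(400, int))
            ious.append(curve_iou(pred, truth))
        assert all(a > b for a, b in zip(ious, ious[1:]))


class TestScalarMetrics:
    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([3.0, 4.0], [1.0, 2.0]) == pytest.approx(2.0)
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_ccc_perfect_and_anti_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ccc(x, x) == pytest.approx(1.0)
        z = x - x.mean()
        assert ccc(-z, z) == pytest.approx(-1.0)

    def test_ccc_against_direct_formula(self):
        pred = np.array([1.0, 2.0, 3.0])
        truth = np.array([2.0, 2.0, 2.5])
        cov = np.mean((pred - pred.mean()) * (truth - truth.mean()))
        expected = 2 * cov / (pred.var() + truth.var() + (pred.mean() - truth.mean()) ** 2)
        assert ccc(pred, truth) == pytest.approx(expected, rel=1e-12)

    def test_ccc_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ccc([1.0, 1.0], [1.0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20),
           st.randoms(use_true_random=False))
    def test_ccc_bounded_by_pearson(self, ys, rnd):
        truth = np.asarray(ys)
        pred = truth + np.array([rnd.uniform(-50, 50) for _ in ys])
        if pred.var() == 0 or truth.var() == 0:
            return
        r = np.corrcoef(pred, truth)[0, 1]
        assert abs(ccc(pred, truth)) <= abs(r) + 1e-9
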