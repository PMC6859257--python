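"""Objective, start boxes and the multistart simplex optimizer.

Closed-form polynomial least squares and scipy's own Nelder–Mead serve
as independent oracles for the in-package optimizer.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from pairscreen.errors import (DegenerateInputError, DegenerateTargetError,
                               UnfittableError)
from pairscreen.fitting import (FitConfig, fit, fit_batch, goodness_of_fit,
                                normalized_sse, start_box)
from pairscreen.prototypes import get_prototype, list_prototypes

from conftest import make_pair

LINEAR = get_prototype("linear")
QUADRATIC = get_prototype("quadratic")
CUBIC = get_prototype("cubic")


def poly_oracle_sse_ratio(x, y, degree):
    """Closed-form normalized SSE of the least-squares polynomial."""
    coeffs = np.polynomial.polynomial.Polynomial.fit(x, y, degree)
    resid = y - coeffs(x)
    return float(np.sum(resid**2) / np.sum((y - y.mean())**2))


class TestObjective:
    def test_exact_fit_scores_zero(self):
        pair = make_pair([0, 1, 2], [1, 3, 5])
        assert normalized_sse(LINEAR, (2, 1), pair) == 0.0

    def test_constant_at_mean_scores_one(self):
        pair = make_pair([0, 1, 2, 3], [2.0, 4.0, 1.0, 5.0])
        ybar = pair.y_values.mean()
        assert normalized_sse(LINEAR, (0.0, ybar), pair) == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        # residuals (-0.1, 0.3, -0.3, 0.1): SSE = 0.2, SST = 2
        pair = make_pair([0, 1, 2, 3], [0, 1, 1, 2])
        assert normalized_sse(LINEAR, (0.6, 0.1), pair) == pytest.approx(
            0.1, abs=1e-12)

    def test_constant_response_is_degenerate(self):
        pair = make_pair([0, 1, 2], [5.0, 5.0, 5.0])
        with pytest.raises(DegenerateTargetError):
            normalized_sse(LINEAR, (0, 5), pair)

    def test_infeasible_parameters_score_infinite(self):
        pair = make_pair([1, 2, 3], [1, 2, 3])
        log = get_prototype("logarithmic")
        assert normalized_sse(log, (0, 1, -5, 0), pair) == np.inf

    @pytest.mark.parametrize("ratio,expected", [(0.0, 1.0), (1.0, 0.0),
                                                (0.1, 0.9), (2.5, -1.5)])
    def test_goodness_of_fit_scale(self, ratio, expected):
        assert goodness_of_fit(ratio) == pytest.approx(expected)


class TestStartBox:
    def test_linear_box_covers_data_slopes(self):
        pair = make_pair(np.linspace(0, 10, 8), np.linspace(0, 1, 8))
        (slo, shi), (ilo, ihi) = start_box(LINEAR, pair, inflation=2.0)
        assert slo <= -(1 / 10) and shi >= (1 / 10)
        assert ilo <= 0.0 and ihi >= 1.0

    def test_sigmoid_location_inside_inflated_x_range(self):
        rng = np.random.default_rng(3)
        pair = make_pair(rng.uniform(2, 8, 10), rng.uniform(0, 5, 10))
        box = start_box(get_prototype("sigmoid"), pair, inflation=2.0)
        e_lo, e_hi = box[4]
        xmid = (pair.x_values.min() + pair.x_values.max()) / 2
        half = (pair.x_values.max() - pair.x_values.min()) / 2 * 2.0
        assert e_lo == pytest.approx(xmid - half)
        assert e_hi == pytest.approx(xmid + half)

    def test_log_box_keeps_argument_positive_at_all_corners(self):
        rng = np.random.default_rng(4)
        pair = make_pair(rng.uniform(-5, 5, 12), rng.uniform(1, 3, 12))
        box = start_box(get_prototype("logarithmic"), pair)
        b_lo, b_hi = box[1]
        c_lo, _ = box[2]
        worst = min(b * x for b in (b_lo, b_hi)
                    for x in (pair.x_values.min(), pair.x_values.max()))
        assert worst + c_lo > 0

    def test_boxes_scale_with_response(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 15)
        y = rng.uniform(1, 4, 15)
        for proto in (LINEAR, QUADRATIC, CUBIC):
            b1 = start_box(proto, make_pair(x, y))
            b2 = start_box(proto, make_pair(x, 2 * y))
            # slope-like and offset-like intervals double with y
            for (lo1, hi1), (lo2, hi2) in zip(b1, b2):
                assert lo2 == pytest.approx(2 * lo1, rel=1e-12)
                assert hi2 == pytest.approx(2 * hi1, rel=1e-12)

    def test_zero_ranges_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            start_box(LINEAR, make_pair([2, 2, 2], [0, 1, 2]))
        with pytest.raises(DegenerateInputError):
            start_box(LINEAR, make_pair([0, 1, 2], [3, 3, 3]))


class TestFit:
    def test_linear_matches_ols_on_hand_fixture(self):
        pair = make_pair([0, 1, 2, 3], [0, 1, 1, 2])
        res = fit(LINEAR, pair)
        assert res.converged
        assert res.gof == pytest.approx(0.9, abs=1e-6)
        assert res.params[0] == pytest.approx(0.6, abs=1e-4)
        assert res.params[1] == pytest.approx(0.1, abs=1e-4)

    def test_quadratic_exact_on_parabola(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = fit(QUADRATIC, make_pair(x, x**2))
        assert res.gof == pytest.approx(1.0, abs=1e-8)

    def test_cubic_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 30)
        y = 0.3 * x**3 - 2 * x**2 + x + 4 + rng.normal(0, 2.0, 30)
        res = fit(CUBIC, make_pair(x, y))
        oracle = poly_oracle_sse_ratio(x, y, 3)
        assert res.sse_ratio == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("proto,degree", [(LINEAR, 1), (QUADRATIC, 2),
                                              (CUBIC, 3)])
    def test_polynomial_oracle_equivalence_random_fixtures(self, proto,
                                                           degree):
        rng = np.random.default_rng(100 + degree)
        pairs = []
        for _ in range(10):
            n = int(rng.integers(degree + 3, 51))
            x = rng.uniform(0, 10, n)
            coef = rng.normal(0, 1, degree + 1)
            y = np.polyval(coef, x) + rng.normal(0, 0.5, n)
            pairs.append(make_pair(x, y))
        for res, pair in zip(fit_batch(proto, pairs), pairs):
            oracle = poly_oracle_sse_ratio(pair.x_values, pair.y_values,
                                           degree)
            assert res.sse_ratio == pytest.approx(oracle, abs=1e-6)

    def test_agrees_with_scipy_nelder_mead_on_exponential(self):
        """Independent-optimizer cross-check on a non-linear family."""
        rng = np.random.default_rng(21)
        x = np.sort(rng.uniform(0, 10, 25))
        y = 0.8 * np.exp(0.45 * x) + 3 + rng.normal(0, 1.0, 25)
        pair = make_pair(x, y)
        proto = get_prototype("exponential")
        res = fit(proto, pair)
        sst = np.sum((y - y.mean())**2)

        def obj(p):
            a, b, c, d = p
            arg = b * x + c
            if np.any(np.abs(arg) > 700):
                return np.inf
            f = a * np.exp(arg) + d
            return np.sum((f - y)**2) / sst

        best = np.inf
        for s in range(30):
            r = minimize(obj, np.random.default_rng(s).uniform(-1, 1, 4)
                         * [5, 0.2, 1, 5] + [0, 0.4, 0, 0],
                         method="Nelder-Mead",
                         options=dict(maxiter=8000, xatol=1e-10,
                                      fatol=1e-12, adaptive=True))
            best = min(best, r.fun)
        assert res.sse_ratio <= best + 1e-6

    def test_noise_free_recovery_each_family(self):
        """Planted curves inside the start box are recovered ~exactly."""
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0.0, 10.0, 25))
        truth = {
            "linear": (2.0, 1.0),
            "sigmoid": (1.0, 9.0, 4.0, 0.15, 5.0),
            "exponential": (0.5, 0.55, 0.0, 2.0),
            "quadratic": (1.0, -8.0, 18.0),
            "cubic": (0.2, -3.0, 12.0, 1.0),
            "logarithmic": (1.0, 2.0, 0.3, 0.0),
        }
        for proto in list_prototypes():
            from pairscreen.prototypes import evaluate
            y = evaluate(proto, truth[proto.name], x)
            res = fit(proto, make_pair(x, y))
            assert res.gof >= 0.999, proto.name

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(13)
        pair = make_pair(rng.uniform(0, 10, 20), rng.uniform(0, 5, 20))
        a = fit(get_prototype("sigmoid"), pair)
        b = fit(get_prototype("sigmoid"), pair)
        assert a == b

    def test_restart_monotonicity_with_nested_seeds(self):
        """Best objective over k+m starts <= best over the first k."""
        rng = np.random.default_rng(17)
        pair = make_pair(rng.uniform(0, 10, 18), rng.uniform(0, 5, 18))
        proto = get_prototype("sigmoid")
        prev = np.inf
        for k in (2, 5, 9, 14):
            res = fit(proto, pair, FitConfig(n_starts=k, polish_rounds=0))
            assert res.sse_ratio <= prev + 1e-15
            prev = res.sse_ratio

    def test_polish_only_improves(self):
        rng = np.random.default_rng(19)
        pair = make_pair(rng.uniform(0, 10, 18), rng.uniform(0, 5, 18))
        proto = get_prototype("sigmoid")
        raw = fit(proto, pair, FitConfig(polish_rounds=0))
        polished = fit(proto, pair, FitConfig(polish_rounds=3))
        assert polished.sse_ratio <= raw.sse_ratio

    def test_preconditions_raise_skip_signals(self):
        with pytest.raises(UnfittableError) as err:
            fit(CUBIC, make_pair([0, 1, 2], [0, 1, 2]))
        assert err.value.reason == "n_too_small"
        with pytest.raises(UnfittableError) as err:
            fit(LINEAR, make_pair([0, 1, 2], [5, 5, 5]))
        assert err.value.reason == "sst_zero"
        with pytest.raises(UnfittableError) as err:
            fit(LINEAR, make_pair([1, 1, 1], [0, 1, 2]))
        assert err.value.reason == "degenerate_x"

    def test_gof_bounds_and_sign(self):
        rng = np.random.default_rng(23)
        for seed in range(5):
            r = np.random.default_rng(seed)
            pair = make_pair(r.uniform(0, 10, 15), r.uniform(0, 5, 15))
            res = fit(LINEAR, pair)
            assert res.sse_ratio >= 0
            assert res.gof <= 1


class TestFitBatch:
    def test_batch_matches_single_fits(self):
        rng = np.random.default_rng(29)
        pairs = [make_pair(rng.uniform(0, 10, 5 + 3 * i),
                           rng.uniform(0, 5, 5 + 3 * i),
                           px=f"P{i + 1}", py=f"P{i + 2}")
                 for i in range(4)]
        from pairscreen.prototypes import evaluate
        for proto in (LINEAR, get_prototype("logarithmic")):
            batch = fit_batch(proto, pairs)
            for b, pair in zip(batch, pairs):
                single = fit(proto, pair)
                # identical objective; fitted curves agree (raw
                # coordinates may drift along redundant directions)
                assert b.sse_ratio == pytest.approx(single.sse_ratio,
                                                    abs=1e-9)
                yscale = np.ptp(pair.y_values)
                np.testing.assert_allclose(
                    evaluate(proto, b.params, pair.x_values),
                    evaluate(proto, single.params, pair.x_values),
                    atol=1e-3 * yscale)

    def test_batch_reports_skip_reasons_in_place(self):
        good = make_pair([0, 1, 2, 3, 4], [0, 1, 3, 2, 5])
        tiny = make_pair([0, 1], [0, 1])
        flat = make_pair([0, 1, 2, 3, 4], [2, 2, 2, 2, 2])
        out = fit_batch(QUADRATIC, [good, tiny, flat])
        assert out[0].converged
        assert isinstance(out[1], UnfittableError)
        assert out[1].reason == "n_too_small"
        assert isinstance(out[2], UnfittableError)
        assert out[2].reason == "sst_zero"
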