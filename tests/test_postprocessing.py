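"""Filtering, difference matrices, trends, significance and seriation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairscreen.errors import DegenerateTargetError
from pairscreen.postprocessing import (FilterSpec, classify_marker_timing,
                                       filter_results,
                                       permutation_significance,
                                       population_difference, rank_by_change,
                                       rank_differences, seriate_matrix,
                                       time_course)
from pairscreen.screening import GofMatrix

from conftest import make_pair


def results_frame(rows):
    """Build a minimal best-results table for filter tests."""
    defaults = {"search_key": "k", "time_point": 0, "population": "VII",
                "prototype": "linear", "sse_ratio": 0.1, "converged": True,
                "self_pair": False, "pearson": np.nan, "skip_reason": "",
                "params": ""}
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d["self_pair"] = d["x_parameter"] == d["y_parameter"]
        out.append(d)
    return pd.DataFrame(out)


class TestFilter:
    def test_threshold_predicate(self):
        df = results_frame([
            {"x_parameter": "P1", "y_parameter": "P2", "gof": 0.9, "n": 15},
            {"x_parameter": "P1", "y_parameter": "P3", "gof": 0.65, "n": 20},
            {"x_parameter": "P2", "y_parameter": "P3", "gof": 0.8, "n": 10},
        ])
        out = filter_results(df, FilterSpec(min_n=12, min_gof=0.7))
        assert len(out) == 1
        assert out.iloc[0]["y_parameter"] == "P2"

    def test_identity_filter(self):
        df = results_frame([
            {"x_parameter": "P1", "y_parameter": "P1", "gof": -5.0, "n": 2},
            {"x_parameter": "P1", "y_parameter": "P2", "gof": 0.0, "n": 3},
        ])
        spec = FilterSpec(min_n=1, min_gof=-np.inf,
                          exclude_self_pairs=False,
                          dedupe_orientation=False)
        pd.testing.assert_frame_equal(filter_results(df, spec), df)

    def test_orientation_dedupe_keeps_better_fit(self):
        df = results_frame([
            {"x_parameter": "P1", "y_parameter": "P2", "gof": 0.8, "n": 15},
            {"x_parameter": "P2", "y_parameter": "P1", "gof": 0.9, "n": 15},
        ])
        out = filter_results(df, FilterSpec(min_n=12, min_gof=0.7))
        assert len(out) == 1
        assert out.iloc[0]["x_parameter"] == "P2"

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_row_scan(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(20):
            px, py = rng.choice(["P1", "P2", "P3", "P4"], 2, replace=True)
            rows.append({"x_parameter": px, "y_parameter": py,
                         "gof": float(rng.uniform(-0.5, 1.0)),
                         "n": int(rng.integers(2, 30))})
        df = results_frame(rows)
        spec = FilterSpec(min_n=12, min_gof=0.7, exclude_self_pairs=True,
                          dedupe_orientation=False)
        out = filter_results(df, spec)
        expected = {i for i, r in enumerate(rows)
                    if r["n"] >= 12 and r["gof"] >= 0.7
                    and r["x_parameter"] != r["y_parameter"]}
        assert set(out.index) == expected

    def test_idempotent_and_subset(self):
        df = results_frame([
            {"x_parameter": "P1", "y_parameter": "P2", "gof": 0.9, "n": 15},
            {"x_parameter": "P3", "y_parameter": "P4", "gof": 0.75,
             "n": 13}])
        spec = FilterSpec()
        once = filter_results(df, spec)
        twice = filter_results(once, spec)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once.index) <= set(df.index)


def gof_matrix(vals, axis=None, t=0, pop="I", proto="best"):
    vals = np.asarray(vals, dtype=float)
    p = vals.shape[0]
    axis = tuple(axis or [f"P{i + 1}" for i in range(p)])
    return GofMatrix(axis, t, pop, proto, vals,
                     np.full((p, p), 20, dtype=np.int64),
                     np.empty((p, p), dtype=object))


class TestPopulationDifference:
    def test_identical_matrices_give_zero(self):
        m = gof_matrix([[1.0, 0.5], [0.5, 1.0]])
        diff = population_difference(m, m)
        np.testing.assert_array_equal(diff.to_numpy(), 0.0)

    def test_antisymmetry_under_swap(self):
        a = gof_matrix([[1.0, 0.8], [0.8, 1.0]])
        b = gof_matrix([[1.0, 0.2], [0.2, 1.0]], pop="II")
        d1 = population_difference(a, b).to_numpy()
        d2 = population_difference(b, a).to_numpy()
        np.testing.assert_allclose(d1, -d2)

    def test_undefined_propagates(self):
        a = gof_matrix([[1.0, np.nan], [0.3, 1.0]])
        b = gof_matrix([[1.0, 0.5], [0.1, 1.0]], pop="II")
        d = population_difference(a, b).to_numpy()
        assert np.isnan(d[0, 1])
        assert d[1, 0] == pytest.approx(0.2)

    def test_axis_mismatch_is_contract_error(self):
        a = gof_matrix([[1.0]])
        b = gof_matrix([[1.0]], axis=["Q1"])
        with pytest.raises(ValueError, match="axes"):
            population_difference(a, b)

    def test_ranking_orders_by_absolute_difference(self):
        d = pd.DataFrame([[0.0, -0.9, 0.2],
                          [-0.9, 0.0, 0.5],
                          [0.2, 0.5, 0.0]],
                         index=["P1", "P2", "P3"],
                         columns=["P1", "P2", "P3"])
        rk = rank_differences(d)
        assert (rk.iloc[0].x_parameter, rk.iloc[0].y_parameter) == \
            ("P1", "P2")
        assert rk.iloc[0].difference == pytest.approx(-0.9)
        assert list(rk.abs_difference) == sorted(rk.abs_difference,
                                                 reverse=True)


class TestTrends:
    def test_time_course_profile(self):
        best = pd.DataFrame([
            {"x_parameter": "P1", "y_parameter": "P2", "population": "II",
             "time_point": t, "gof": g}
            for t, g in [(0, 0.1), (60, 0.5), (180, 0.9)]])
        prof = time_course(best, "P1", "P2", "II", [0, 60, 120, 180])
        np.testing.assert_allclose(prof[[0, 1, 3]], [0.1, 0.5, 0.9])
        assert np.isnan(prof[2])

    def test_rank_by_change_scores_and_exclusion(self):
        profiles = {
            "late": np.array([0.2, 0.3, 0.9]),
            "flat": np.array([0.5, 0.5, 0.5]),
            "sparse": np.array([np.nan, np.nan, 0.8]),
        }
        rk = rank_by_change(profiles, min_defined=2)
        assert list(rk.cell) == ["late", "flat"]
        assert rk.iloc[0].score == pytest.approx(0.7)
        assert rk.iloc[1].score == 0.0

    def test_change_score_ignores_time_order(self):
        a = rank_by_change({"c": np.array([0.1, 0.9, 0.4])})
        b = rank_by_change({"c": np.array([0.9, 0.4, 0.1])})
        assert a.iloc[0].score == b.iloc[0].score

    @pytest.mark.parametrize("profile,label", [
        ([0.95, 0.96, 0.97], "lockstep"),
        ([0.9, 0.5, 0.1], "early"),
        ([0.1, 0.5, 0.9], "late"),
        ([0.5, 0.5, 0.5], "other"),
        ([0.9, 0.5, 0.9], "other"),
        ([np.nan, 0.1, 0.9], "late"),  # leading undefined entries skipped
    ])
    def test_marker_timing_labels(self, profile, label):
        assert classify_marker_timing(profile, high=0.7, low=0.3) == label


class TestPermutationSignificance:
    def test_exact_linear_data_gives_minimal_p(self):
        x = np.arange(20.0)
        pair = make_pair(x, 2 * x + 1)
        p = permutation_significance(pair, policy="refit-linear",
                                     n_permutations=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_constant_response_is_degenerate(self):
        pair = make_pair(np.arange(10.0), np.full(10, 3.0))
        with pytest.raises(DegenerateTargetError):
            permutation_significance(pair, n_permutations=9, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        pair = make_pair(rng.normal(size=15), rng.normal(size=15))
        p1 = permutation_significance(pair, n_permutations=49, seed=7)
        p2 = permutation_significance(pair, n_permutations=49, seed=7)
        assert p1 == p2

    def test_refit_best_policy_on_exact_curve(self):
        """Full-refit policy also flags a planted non-linear relation."""
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 12))
        y = 1.0 * x**2 - 8 * x + 18
        pair = make_pair(x, y)
        p = permutation_significance(pair, policy="refit-best",
                                     n_permutations=9, seed=1)
        assert p == pytest.approx(1 / 10)


class TestSeriation:
    def test_two_block_matrix_becomes_contiguous(self):
        p = 8
        blocks = [set(range(4)), set(range(4, 8))]
        m = np.full((p, p), 0.05)
        for blk in blocks:
            for i in blk:
                for j in blk:
                    m[i, j] = 0.9
        np.fill_diagonal(m, 1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(p)
        shuffled = m[np.ix_(perm, perm)]
        order = seriate_matrix(shuffled)
        labels = [0 if perm[i] < 4 else 1 for i in order]
        # each planted block occupies one contiguous run
        changes = sum(a != b for a, b in zip(labels, labels[1:]))
        assert changes == 1

    def test_identity_matrix_keeps_catalogue_order(self):
        order = seriate_matrix(np.eye(5))
        np.testing.assert_array_equal(order, np.arange(5))

    def test_returns_bijection(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, (7, 7))
        order = seriate_matrix(m)
        assert sorted(order) == list(range(7))
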