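from itertools import combinations

import numpy as np
import pytest

from conftest import planted_matrix
from cppkit.errors import CppkitError, EmptySampleError, SingleClassError
from cppkit.matrix import FeatureMatrix
from cppkit.selection import (
    SelectionReport,
    ert_select,
    filter_by_mwu,
    mann_whitney_u,
    select_features,
    svd_reduce,
)


def exact_two_sided_p(x, y):
    """Exhaustive-permutation two-sided p-value (tie-free samples only)."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    lo = min(u_obs, n1 * n2 - u_obs)
    total = count = 0
    indices = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in indices - set(comb)]
        u = sum(1 for a in xs for b in ys if a > b)
        total += 1
        count += u <= lo
    return min(1.0, 2.0 * count / total)


class TestMannWhitney:
    def test_fully_separated_small(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_two_vs_two(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_constant_samples(self):
        res = mann_whitney_u([5.0] * 4, [5.0] * 4)
        assert res.u_statistic == 8.0  # n^2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            mann_whitney_u([], [1.0])

    def test_matches_permutation_oracle(self, rng):
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                pooled = rng.permutation(np.arange(n1 + n2, dtype=float) + 1)
                x, y = pooled[:n1], pooled[n1:]
                res = mann_whitney_u(x, y)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(
                    exact_two_sided_p(x, y), rel=1e-12
                )

    def test_large_samples_use_approximation(self, rng):
        res = mann_whitney_u(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "normal-approximation"
        assert 0.0 <= res.p_value <= 1.0


class TestFilterByMwu:
    def test_signal_kept_noise_dropped(self):
        kept_signal = dropped_noise = 0
        for seed in range(1, 21):
            m = planted_matrix(n_per_class=100, n_noise=20, seed=seed)
            report = filter_by_mwu(m)
            kept_signal += "signal" in report.kept
            noise_kept = sum(1 for n in report.kept if n.startswith("noise"))
            dropped_noise += noise_kept <= 4  # ~alpha of 20 expected
        assert kept_signal == 20
        assert dropped_noise >= 19

    def test_alpha_one_keeps_all_nonconstant(self):
        m = planted_matrix(n_per_class=50, n_noise=10)
        report = filter_by_mwu(m, alpha=1.0)
        assert set(report.kept) == set(m.names)

    def test_all_constant_matrix_keeps_nothing(self):
        m = FeatureMatrix(
            ids=["a", "b", "c", "d"],
            names=["c1", "c2"],
            values=np.ones((4, 2)),
            labels=np.array([1, 1, 0, 0]),
        )
        report = filter_by_mwu(m)
        assert report.kept == []
        assert report.p_values == {"c1": 1.0, "c2": 1.0}

    def test_kept_set_invariant_to_monotone_transform(self, rng):
        m = planted_matrix(n_per_class=40, n_noise=15, seed=3)
        baseline = filter_by_mwu(m).kept
        transformed = m.values.copy()
        transformed[:, 0] = np.exp(transformed[:, 0])
        transformed[:, 1] = transformed[:, 1] ** 3
        transformed[:, 2] = 5 * transformed[:, 2] - 2
        m2 = FeatureMatrix(m.ids, m.names, transformed, m.labels)
        assert filter_by_mwu(m2).kept == baseline

    def test_single_class_rejected(self):
        m = planted_matrix(n_per_class=10, n_noise=2)
        m.labels = np.ones(m.n_rows, dtype=int)
        with pytest.raises(SingleClassError):
            filter_by_mwu(m)


class TestErtSelect:
    def test_planted_feature_ranks_first(self):
        m = planted_matrix(n_per_class=100, n_noise=50, seed=7)
        report = ert_select(m, top_k=10, n_estimators=100, seed=7)
        assert report.selected[0] == "signal"

    def test_constant_feature_importance_zero(self):
        m = planted_matrix(n_per_class=50, n_noise=5, seed=7)
        values = np.column_stack([m.values, np.full(m.n_rows, 3.0)])
        m2 = FeatureMatrix(m.ids, m.names + ["flat"], values, m.labels)
        report = ert_select(m2, top_k=7, n_estimators=50, seed=0)
        assert report.importances["flat"] == 0.0

    def test_full_topk_is_permutation(self):
        m = planted_matrix(n_per_class=30, n_noise=8, seed=2)
        report = ert_select(m, top_k=m.n_features, n_estimators=50, seed=2)
        assert sorted(report.selected) == sorted(m.names)

    def test_deterministic_under_seed(self):
        m = planted_matrix(n_per_class=50, n_noise=20, seed=5)
        a = ert_select(m, top_k=10, n_estimators=100, seed=9)
        b = ert_select(m, top_k=10, n_estimators=100, seed=9)
        assert a.selected == b.selected
        assert a.importances == b.importances

    def test_topk_exceeding_columns_rejected(self):
        m = planted_matrix(n_per_class=10, n_noise=3)
        with pytest.raises(CppkitError):
            ert_select(m, top_k=10)


class TestPipeline:
    def test_filter_runs_before_ranking(self):
        m = planted_matrix(n_per_class=60, n_noise=30, seed=4)
        reduced, report = select_features(m, top_k=5, n_estimators=50, seed=4)
        # every selected feature must have passed the filter
        assert set(report.selected) <= set(report.kept)
        assert reduced.names == report.selected
        assert reduced.names[0] == "signal"

    def test_report_json_roundtrip(self, tmp_path):
        m = planted_matrix(n_per_class=30, n_noise=10, seed=8)
        _, report = select_features(m, top_k=3, n_estimators=50, seed=8)
        path = tmp_path / "sel.json"
        report.to_json(path)
        back = SelectionReport.from_json(path)
        assert back.selected == report.selected
        assert back.kept == report.kept
        assert back.importances == report.importances


class TestSvd:
    def test_rank_one_exact_capture(self):
        base = np.outer(np.arange(1.0, 7.0), [2.0, -1.0, 0.5, 3.0])
        m = FeatureMatrix([f"r{i}" for i in range(6)],
                          ["a", "b", "c", "d"], base)
        reduced, reducer = svd_reduce(m, 1)
        recon = reducer.inverse_transform(reduced.values)
        assert np.abs(recon - base).max() < 1e-9

    def test_full_rank_explains_everything(self, rng):
        values = rng.normal(size=(12, 5))
        m = FeatureMatrix([f"r{i}" for i in range(12)],
                          [f"f{j}" for j in range(5)], values)
        _, reducer = svd_reduce(m, 5)
        assert reducer.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        values = rng.normal(size=(10, 8))
        m = FeatureMatrix([f"r{i}" for i in range(10)],
                          [f"f{j}" for j in range(8)], values)
        k = 3
        reduced, reducer = svd_reduce(m, k)
        centered = values - values.mean(axis=0)
        eigval, eigvec = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(eigval)[::-1][:k]
        # best rank-k approximation from the covariance eigenbasis
        basis = eigvec[:, order]
        oracle = centered @ basis @ basis.T + values.mean(axis=0)
        recon = reducer.inverse_transform(reduced.values)
        assert np.abs(recon - oracle).max() < 1e-9

    def test_rank_deficient_request_clamped(self):
        base = np.outer(np.arange(1.0, 7.0), [2.0, -1.0, 0.5])
        m = FeatureMatrix([f"r{i}" for i in range(6)], ["a", "b", "c"], base)
        with pytest.warns(UserWarning, match="clamping"):
            reduced, _ = svd_reduce(m, 3)
        assert reduced.n_features == 1

    def test_out_of_range_components_rejected(self, rng):
        m = FeatureMatrix(["r0", "r1"], ["a", "b"], rng.normal(size=(2, 2)))
        with pytest.raises(CppkitError):
            svd_reduce(m, 3)
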