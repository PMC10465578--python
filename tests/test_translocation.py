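import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from conftest import make_collection
from orgmapkit.errors import AnalysisError, ConfigurationError
from orgmapkit.translocation import (
    DeltaProfileSet,
    OutlierParams,
    call_movers,
    combine_and_score,
    compute_delta_profiles,
    consistency_filter,
    mr_analysis,
    replicate_outlier_pvalues,
    reproducibility_score,
)

UNIFORM = [1 / 6.0] * 6


def delta_set(arrays):
    """DeltaProfileSet from one matrix per replicate."""
    frames = {
        rep + 1: pd.DataFrame(
            np.asarray(arr, dtype=float),
            index=[f"P{i + 1}" for i in range(len(arr))],
            columns=["1K", "3K", "6K", "12K", "24K", "80K"],
        )
        for rep, arr in enumerate(arrays)
    }
    return DeltaProfileSet(deltas=frames, fractions=["1K", "3K", "6K", "12K", "24K", "80K"])


class TestOutlierParams:
    def test_even_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            OutlierParams(iterations=30)

    def test_support_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            OutlierParams(support_fraction=0.3)


class TestConsistencyFilter:
    def test_identical_replicates_retained(self):
        control = make_collection("control", [[UNIFORM], [UNIFORM]])
        treated = make_collection("treated", [[UNIFORM], [UNIFORM]])
        assert list(consistency_filter(control, treated)) == ["P1"]

    def test_orthogonal_replicates_removed(self):
        a = [[1, 0, 0, 0, 0, 0]]
        b = [[0, 1, 0, 0, 0, 0]]
        control = make_collection("control", [a, b])
        treated = make_collection("treated", [[UNIFORM], [UNIFORM]])
        assert len(consistency_filter(control, treated)) == 0

    def test_cosine_exactly_at_cut_is_retained(self):
        # cos((1,0,...), (0.9, sqrt(0.19), 0...)) == 0.9 exactly
        a = [[1, 0, 0, 0, 0, 0]]
        b = [[0.9, np.sqrt(1 - 0.81), 0, 0, 0, 0]]
        control = make_collection("control", [a, b])
        treated = make_collection("treated", [[UNIFORM], [UNIFORM]])
        assert list(consistency_filter(control, treated, min_cosine=0.9)) == ["P1"]


class TestDeltaProfiles:
    def test_hand_subtraction(self):
        control = make_collection("control", [[[0.5, 0.5, 0, 0, 0, 0]]])
        treated = make_collection("treated", [[[0.1, 0.5, 0.4, 0, 0, 0]]])
        deltas = compute_delta_profiles(control, treated)
        np.testing.assert_allclose(
            deltas.deltas[1].loc["P1"], [-0.4, 0, 0.4, 0, 0, 0], atol=1e-12
        )

    def test_identical_conditions_give_zero(self):
        coll = make_collection("control", [[UNIFORM]])
        treated = make_collection("treated", [[UNIFORM]])
        deltas = compute_delta_profiles(coll, treated)
        np.testing.assert_allclose(deltas.deltas[1].to_numpy(), 0.0)

    def test_deltas_sum_to_zero(self, small_maps):
        control, treated, _ = small_maps
        deltas = compute_delta_profiles(control, treated)
        for rep in deltas.replicates:
            sums = deltas.deltas[rep].sum(axis=1).to_numpy()
            np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_unpaired_replicate_is_error(self):
        control = make_collection("control", [[UNIFORM], [UNIFORM]])
        treated = make_collection("treated", [[UNIFORM]])
        with pytest.raises(AnalysisError, match="pair"):
            compute_delta_profiles(control, treated)


class TestOutlierPvalues:
    def toy_deltas(self, n=50, seed=0, planted=None):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 0.01, size=(n, 6))
        X -= X.mean(axis=1, keepdims=True)
        if planted is not None:
            X[0] = planted
        return delta_set([X])

    def test_classical_mode_matches_brute_force_mahalanobis(self):
        deltas = self.toy_deltas()
        params = OutlierParams(support_fraction=1.0)
        result = replicate_outlier_pvalues(deltas, params)

        from scipy.linalg import helmert

        Z = deltas.deltas[1].to_numpy() @ helmert(6).T
        diff = Z - Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False, ddof=0)
        d2 = np.array([row @ np.linalg.inv(cov) @ row for row in diff])
        np.testing.assert_allclose(
            result[1].to_numpy(), chi2.sf(d2, 5), atol=1e-8
        )

    def test_delta_at_center_has_p_one(self):
        # symmetric pairs around zero put the mean exactly at the origin
        base = np.vstack([np.eye(6) - 1 / 6.0, -(np.eye(6) - 1 / 6.0)])
        X = np.vstack([base * s for s in (0.01, 0.02, 0.03, 0.04)] + [np.zeros((1, 6))])
        result = replicate_outlier_pvalues(
            delta_set([X]), OutlierParams(support_fraction=1.0)
        )
        assert result[1].iloc[-1] == pytest.approx(1.0)

    def test_planted_shift_has_smallest_p(self):
        planted = np.array([0.3, -0.3, 0, 0, 0, 0])
        deltas = self.toy_deltas(planted=planted)
        result = replicate_outlier_pvalues(deltas, OutlierParams(seed=1))
        assert result[1].idxmin() == "P1"

    def test_too_few_proteins_is_error(self):
        deltas = self.toy_deltas(n=5)
        with pytest.raises(AnalysisError, match="proteins"):
            replicate_outlier_pvalues(deltas, OutlierParams(support_fraction=1.0))


class TestCombineAndScore:
    def test_all_ones_give_zero_m(self):
        scores = combine_and_score(
            pd.DataFrame({"p1": [1.0], "p2": [1.0], "p3": [1.0]})
        )
        assert scores["fisher_x2"].iloc[0] == 0.0
        assert scores["combined_p"].iloc[0] == 1.0
        assert scores["M"].iloc[0] == 0.0

    def test_fisher_statistic_matches_oracle(self):
        p = pd.DataFrame({"p1": [0.5], "p2": [0.5], "p3": [0.5]})
        scores = combine_and_score(p)
        x2 = -2 * np.log(0.5) * 3
        assert scores["fisher_x2"].iloc[0] == pytest.approx(x2, abs=1e-12)
        assert x2 == pytest.approx(4.1589, abs=1e-4)
        assert scores["combined_p"].iloc[0] == pytest.approx(
            chi2.sf(x2, 6), abs=1e-12
        )

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        pvals = pd.DataFrame(rng.uniform(size=(40, 3)), columns=["p1", "p2", "p3"])
        scores = combine_and_score(pvals)
        combined = scores["combined_p"].to_numpy()

        m = len(combined)
        order = np.argsort(combined)
        q_sorted = combined[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(scores["q"].to_numpy(), expected, atol=1e-12)

    def test_bh_adjusted_p_of_005_gives_m_13(self):
        # a single tested protein whose Fisher-combined p is exactly 0.05
        p0 = float(np.exp(-chi2.isf(0.05, 6) / 6))
        scores = combine_and_score(pd.DataFrame({"p1": [p0], "p2": [p0], "p3": [p0]}))
        assert scores["q"].iloc[0] == pytest.approx(0.05, abs=1e-12)
        assert scores["M"].iloc[0] == pytest.approx(-np.log10(0.05), abs=1e-12)
        assert round(scores["M"].iloc[0], 1) == 1.3

    def test_combined_p_monotone_in_each_p(self):
        base = combine_and_score(
            pd.DataFrame({"p1": [0.5], "p2": [0.5], "p3": [0.5]})
        )["combined_p"].iloc[0]
        for col in ("p1", "p2", "p3"):
            frame = pd.DataFrame({"p1": [0.5], "p2": [0.5], "p3": [0.5]})
            frame[col] = 0.1
            smaller = combine_and_score(frame)["combined_p"].iloc[0]
            assert smaller < base

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            scores = combine_and_score(
                pd.DataFrame({"p1": [0.0], "p2": [0.5], "p3": [0.5]})
            )
        assert np.isfinite(scores["M"].iloc[0])


class TestReproducibilityScore:
    def test_identical_deltas_score_one(self):
        d = np.array([[0.1, -0.1, 0, 0, 0, 0]])
        R = reproducibility_score(delta_set([d, d, d]))
        assert R.iloc[0] == pytest.approx(1.0)

    def test_one_flipped_delta_scores_minus_one(self):
        d = np.array([[0.1, -0.1, 0.05, -0.05, 0, 0]])
        R = reproducibility_score(delta_set([d, d, -d]))
        # pairwise r = (1, -1, -1) -> median -1
        assert R.iloc[0] == pytest.approx(-1.0)

    def test_two_replicates_use_single_correlation(self):
        a = np.array([[0.1, -0.1, 0.02, -0.02, 0, 0]])
        b = np.array([[0.08, -0.12, 0.04, 0, 0, 0]])
        R = reproducibility_score(delta_set([a, b]))
        expected = np.corrcoef(a[0], b[0])[0, 1]
        assert R.iloc[0] == pytest.approx(expected)

    def test_constant_delta_reported_missing(self):
        flat = np.zeros((1, 6))
        other = np.array([[0.1, -0.1, 0, 0, 0, 0]])
        R = reproducibility_score(delta_set([flat, other, other]))
        assert np.isnan(R.iloc[0])


class TestCallMovers:
    def records(self, M, R, p):
        return pd.DataFrame(
            {"p1": [p[0]], "p2": [p[1]], "p3": [p[2]], "M": [M], "R": [R]},
            index=["P1"],
        )

    def test_all_rules_met_is_significant(self):
        out = call_movers(self.records(1.4, 0.8, (0.01, 0.05, 0.2)))
        assert bool(out["significant"].iloc[0])

    def test_single_small_replicate_p_excluded(self):
        out = call_movers(self.records(1.4, 0.8, (0.01, 0.2, 0.3)))
        assert not bool(out["significant"].iloc[0])

    def test_m_below_cut_not_significant(self):
        out = call_movers(self.records(1.2, 0.9, (0.01, 0.01, 0.01)))
        assert not bool(out["significant"].iloc[0])

    def test_hits_sorted_by_m_descending(self):
        records = pd.DataFrame(
            {
                "p1": [0.01, 0.01],
                "p2": [0.01, 0.01],
                "p3": [0.01, 0.01],
                "M": [1.5, 2.5],
                "R": [0.9, 0.9],
            },
            index=["A", "B"],
        )
        out = call_movers(records)
        assert list(out.index) == ["B", "A"]


class TestEndToEnd:
    def test_planted_movers_dominate_hit_list(self, small_maps):
        control, treated, truth = small_maps
        records = mr_analysis(control, treated)
        hits = set(records.index[records["significant"]])
        planted = set(truth.movers.index)
        assert planted <= hits
        assert len(hits - planted) <= 1
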