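import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from conftest import make_collection
from orgmapkit.downstream import (
    cluster_delta_profiles,
    cycling_cluster,
    endosomal_shift_scores,
    enrichment_test,
    robust_z,
    shift_magnitude_class,
)
from orgmapkit.errors import AnalysisError

FRACTIONS = ["1K", "3K", "6K", "12K", "24K", "80K"]


def delta_frame(rows, ids=None):
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=ids or [f"P{i + 1}" for i in range(len(rows))],
        columns=FRACTIONS,
    )


class TestShiftClustering:
    def test_identical_deltas_share_a_cluster(self):
        d = [0.2, -0.2, 0.1, -0.1, 0, 0]
        clustering = cluster_delta_profiles(delta_frame([d, d]), threshold=0.5)
        assert clustering.labels["P1"] == clustering.labels["P2"]

    def test_anticorrelated_deltas_split(self):
        d = np.array([0.2, -0.2, 0.1, -0.1, 0, 0])
        clustering = cluster_delta_profiles(
            delta_frame([d, -d]), threshold=1.9
        )
        assert clustering.labels["P1"] != clustering.labels["P2"]

    def test_four_protein_set_matches_hand_traced_agglomeration(self):
        # two tight groups: {P1, P2} strongly correlated, {P3, P4} strongly
        # correlated, groups anti-correlated with each other
        a = np.array([0.3, -0.3, 0.1, -0.1, 0, 0])
        b = np.array([0.28, -0.31, 0.12, -0.09, 0.0, 0.0])
        clustering = cluster_delta_profiles(
            delta_frame([a, b, -a, -b]), threshold=0.5
        )
        labels = clustering.labels
        assert labels["P1"] == labels["P2"]
        assert labels["P3"] == labels["P4"]
        assert labels["P1"] != labels["P3"]

        # brute-force complete-linkage trace on the 1 - r distances
        corr = np.corrcoef([a, b, -a, -b])
        dist = 1 - corr
        # first merge: smallest distance pair; complete linkage keeps the
        # max distance to the merged cluster, which stays < threshold only
        # within groups
        assert dist[0, 1] < 0.5 and dist[2, 3] < 0.5
        assert dist[0, 2] > 1.5 and dist[1, 3] > 1.5

    def test_constant_delta_is_error(self):
        d = [0.2, -0.2, 0.1, -0.1, 0, 0]
        with pytest.raises(AnalysisError, match="P2"):
            cluster_delta_profiles(delta_frame([d, [0] * 6]), threshold=0.5)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(8, 6))
        rows -= rows.mean(axis=1, keepdims=True)
        frame = delta_frame(rows)
        base = cluster_delta_profiles(frame, threshold=0.8).labels
        shuffled = cluster_delta_profiles(
            frame.iloc[[5, 2, 7, 0, 1, 6, 3, 4]], threshold=0.8
        ).labels
        # same partition up to label renaming
        for pid_a in frame.index:
            for pid_b in frame.index:
                assert (base[pid_a] == base[pid_b]) == (
                    shuffled[pid_a] == shuffled[pid_b]
                )


class TestEnrichment:
    def clustering_of(self, labels):
        return type(
            "FakeClustering",
            (),
            {
                "labels": pd.Series(labels),
                "clusters": {
                    c: sorted(k for k, v in labels.items() if v == c)
                    for c in set(labels.values())
                },
            },
        )()

    def test_p_matches_hypergeometric_oracle(self):
        # 10-protein cluster with 5 term members; 100-protein background
        # with 10 term members total
        labels = {f"P{i}": (1 if i < 10 else 2) for i in range(100)}
        annotations = {f"P{i}": {"T"} for i in list(range(5)) + list(range(50, 55))}
        result = enrichment_test(self.clustering_of(labels), annotations)
        row = result.table.set_index(["cluster", "term"]).loc[(1, "T")]
        # one-sided Fisher == hypergeometric upper tail
        expected = hypergeom.sf(5 - 1, 100, 10, 10)
        assert row["p"] == pytest.approx(expected, abs=1e-10)
        assert result.table["q"].ge(result.table["p"] - 1e-15).all()

    def test_ubiquitous_term_not_enriched(self):
        labels = {f"P{i}": (1 if i < 5 else 2) for i in range(20)}
        annotations = {f"P{i}": {"T"} for i in range(20)}
        result = enrichment_test(self.clustering_of(labels), annotations)
        assert (result.table["p"] == 1.0).all()
        assert not result.table["enriched"].any()

    def test_term_absent_from_background_skipped(self):
        labels = {"P1": 1, "P2": 1, "P3": 2}
        annotations = {"P9": {"T"}}  # P9 not clustered
        result = enrichment_test(self.clustering_of(labels), annotations)
        assert len(result.table) == 0


class TestCyclingCluster:
    def test_correlation_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(6, 6))
        rows -= rows.mean(axis=1, keepdims=True)
        _, matrix = cycling_cluster(delta_frame(rows), threshold=1.0)
        np.testing.assert_allclose(matrix.to_numpy(), matrix.to_numpy().T)
        np.testing.assert_allclose(np.diag(matrix.to_numpy()), 1.0)

    def test_identical_correlation_rows_cluster_together(self):
        d = np.array([0.3, -0.3, 0.1, -0.1, 0, 0])
        e = np.array([0.1, 0.1, -0.3, 0.3, -0.1, -0.1])
        clustering, _ = cycling_cluster(
            delta_frame([d, d, e]), threshold=0.5
        )
        assert clustering.labels["P1"] == clustering.labels["P2"]
        assert clustering.labels["P1"] != clustering.labels["P3"]

    def test_shared_shift_direction_pairs_up(self, small_maps):
        control, treated, truth = small_maps
        movers = truth.movers
        # two movers with the same source/destination plus one static protein
        grouped = movers.groupby(["source", "destination"]).size()
        source, destination = grouped.idxmax()
        pair = movers[
            (movers["source"] == source)
            & (movers["destination"] == destination)
        ].index[:2]
        if len(pair) < 2:
            pytest.skip("generator did not plant two co-directional movers")
        static = [
            p
            for p in control.complete_ids()
            if p not in set(movers.index)
        ][:1]
        ids = list(pair) + static
        from orgmapkit.translocation import compute_delta_profiles

        deltas = compute_delta_profiles(control, treated, ids=ids)
        mean_delta = pd.DataFrame(
            deltas.array().mean(axis=0), index=deltas.ids, columns=FRACTIONS
        )
        clustering, _ = cycling_cluster(mean_delta, threshold=1.0)
        assert clustering.labels[pair[0]] == clustering.labels[pair[1]]
        assert clustering.labels[static[0]] != clustering.labels[pair[0]]


class TestEndosomalShifts:
    def test_median_shift_scores_zero(self, small_maps):
        control, treated, truth = small_maps
        endosome = truth.markers.labels.index[
            truth.markers.labels == "Endosome"
        ]
        scores = endosomal_shift_scores(control, treated, endosome)
        median_delta = scores["delta_corr"].median()
        closest = (scores["delta_corr"] - median_delta).abs().idxmin()
        assert abs(scores.loc[closest, "z"]) < 0.5
        assert scores.loc[closest, "magnitude_class"] == "no relevant shift"

    def test_magnitude_bins(self):
        assert shift_magnitude_class(4.5) == "very large"
        assert shift_magnitude_class(3.5) == "large"
        assert shift_magnitude_class(2.5) == "medium"
        assert shift_magnitude_class(1.5) == "small"
        assert shift_magnitude_class(0.7) == "very small"
        assert shift_magnitude_class(0.2) == "no relevant shift"
        assert shift_magnitude_class(-2.0) == "no relevant shift"

    def test_robust_z_matches_mad_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=200)
        z = robust_z(values)
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        np.testing.assert_allclose(z, (values - med) / (1.4826 * mad), atol=1e-12)

    def test_z_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=100)
        base = robust_z(values)
        np.testing.assert_allclose(robust_z(values + 5.0), base, atol=1e-9)
        np.testing.assert_allclose(robust_z(values * 3.0), base, atol=1e-9)

    def test_too_few_markers_is_error(self, small_maps):
        control, treated, _ = small_maps
        with pytest.raises(AnalysisError, match="two endosome markers"):
            endosomal_shift_scores(control, treated, ["SYN000001"])

    def test_planted_golgi_to_endosome_movers_score_high(self, small_maps):
        control, treated, truth = small_maps
        endosome = truth.markers.labels.index[
            truth.markers.labels == "Endosome"
        ]
        to_endosome = truth.movers[
            truth.movers["destination"] == "Endosome"
        ].index
        if len(to_endosome) == 0:
            pytest.skip("no planted endosome-bound mover")
        scores = endosomal_shift_scores(control, treated, endosome)
        assert (scores.loc[to_endosome, "z"] > 2).all()
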