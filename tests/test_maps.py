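"""Stochastic map estimation, joints, diagnostics, cluster-score map."""

import numpy as np
import pandas as pd
import pytest

from mgportrait.maps import (
    EstimationError,
    ItemRef,
    JointScoreDistribution,
    StochasticMap,
    estimate_joint,
    estimate_map,
    fit_cluster_score_map,
    impute_item,
    map_diagnostics,
    map_from_counts,
    sample_qol_from_level,
)
from mgportrait.schema import ScoreTable
from mgportrait.structure import cluster_qol
from mgportrait.synthetic import CohortConfig, generate_cohort

SRC = ItemRef("MG-ADL", "eyelid_drop")
TGT = ItemRef("QMG", "ptosis")


def _pair_table(pairs):
    """Build a table from (source value, target value) pairs, one visit each."""
    recs = []
    for i, (x, y) in enumerate(pairs):
        recs.append((f"P{i}", 0, "MG-ADL", "eyelid_drop", None, x))
        recs.append((f"P{i}", 0, "QMG", "ptosis", None, y))
    return ScoreTable.from_records(recs)


class TestEstimateMap:
    def test_hand_enumerated_counts(self):
        # pairings {(0,0)x3, (0,1)x1, (1,1)x2}
        table = _pair_table([(0, 0)] * 3 + [(0, 1)] + [(1, 1)] * 2)
        smap = estimate_map(table, SRC, TGT)
        assert np.allclose(smap.P[0], [0.75, 0.25, 0, 0])
        assert np.allclose(smap.P[1], [0, 1, 0, 0])
        assert list(smap.row_support) == [4, 2, 0, 0]
        # zero-support rows fall back to the target marginal, flagged
        marginal = [3 / 6, 3 / 6, 0, 0]
        assert np.allclose(smap.P[2], marginal)
        assert list(smap.marginal_filled) == [False, False, True, True]

    def test_identity_pairing_gives_identity_rows(self):
        table = _pair_table([(v, v) for v in (0, 1, 2, 3)] * 5)
        smap = estimate_map(table, SRC, TGT)
        assert np.allclose(smap.P, np.eye(4))

    def test_no_pairings_is_estimation_error(self):
        recs = [("P1", 0, "MG-ADL", "eyelid_drop", None, 1)]
        with pytest.raises(EstimationError, match="no pairings"):
            estimate_map(ScoreTable.from_records(recs), SRC, TGT)

    def test_record_order_and_patient_label_invariance(self):
        pairs = [(0, 1), (1, 1), (2, 3), (3, 3), (0, 0)] * 4
        t1 = _pair_table(pairs)
        df = t1.df.sample(frac=1, random_state=0).reset_index(drop=True)
        df["patient_id"] = "X" + df["patient_id"].str[1:]
        t2 = ScoreTable(df)
        m1, m2 = estimate_map(t1, SRC, TGT), estimate_map(t2, SRC, TGT)
        assert np.array_equal(m1.counts, m2.counts)

    def test_rater_pairs_count_once_each(self):
        recs = []
        for r in ("R1", "R2"):
            recs.append(("P1", 0, "MG-ADL", "eyelid_drop", r, 1))
            recs.append(("P1", 0, "QMG", "ptosis", r, 2))
        smap = estimate_map(ScoreTable.from_records(recs), SRC, TGT)
        assert smap.counts[1, 2] == 2
        assert smap.counts.sum() == 2

    def test_rows_stochastic(self, small_cohort):
        _, table, _, _ = small_cohort
        smap = estimate_map(table, SRC, TGT)
        assert np.allclose(smap.P.sum(axis=1), 1.0, atol=1e-9)
        assert (smap.P >= 0).all()

    def test_direct_inverse_counts_are_transposes(self, small_cohort):
        _, table, _, _ = small_cohort
        direct = estimate_map(table, SRC, TGT)
        inverse = estimate_map(table, TGT, SRC)
        assert np.array_equal(direct.counts, inverse.counts.T)

    def test_pseudo_count_smoothing(self):
        table = _pair_table([(0, 0)] * 4)
        smap = estimate_map(table, SRC, TGT, pseudo_count=1.0)
        assert smap.P[0, 0] == pytest.approx(5 / 8)
        assert smap.smoothing == "pseudo_count=1"

    def test_serialization_roundtrip(self, small_cohort):
        _, table, _, _ = small_cohort
        smap = estimate_map(table, SRC, TGT)
        again = StochasticMap.from_dict(smap.to_dict())
        assert np.allclose(again.P, smap.P)
        assert np.array_equal(again.counts, smap.counts)


class TestImputeItem:
    def test_returns_requested_row(self):
        P = np.array([[1, 0, 0, 0], [0.6, 0.3, 0.1, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        smap = StochasticMap(
            source=SRC, target=TGT, source_domain=(0, 1, 2, 3),
            target_domain=(0, 1, 2, 3), counts=(P * 10).astype(int), P=P,
            row_support=np.array([10, 10, 10, 10]),
            marginal_filled=np.zeros(4, bool),
        )
        probs, flagged = impute_item(smap, 1)
        assert np.allclose(probs, [0.6, 0.3, 0.1, 0])
        assert not flagged

    def test_identity_map_point_mass(self):
        table = _pair_table([(v, v) for v in range(4)])
        probs, _ = impute_item(estimate_map(table, SRC, TGT), 2)
        assert np.allclose(probs, [0, 0, 1, 0])

    def test_marginal_filled_row_flagged(self):
        table = _pair_table([(0, 0)] * 3)
        probs, flagged = impute_item(estimate_map(table, SRC, TGT), 3)
        assert flagged and np.allclose(probs, [1, 0, 0, 0])

    def test_out_of_domain_rejected(self):
        table = _pair_table([(0, 0)] * 3)
        with pytest.raises(ValueError, match="domain"):
            impute_item(estimate_map(table, SRC, TGT), 9)


class TestEstimateJoint:
    def test_printed_example_matrix(self):
        # counts proportional to a published-style two-item joint layout
        counts = {(0, 0): 1, (0, 1): 1, (1, 0): 5, (1, 1): 2, (2, 2): 1}
        pairs = [xy for xy, c in counts.items() for _ in range(c)]
        joint = estimate_joint(_pair_table(pairs), SRC, TGT)
        expected = np.array(
            [[0.1, 0.1, 0, 0], [0.5, 0.2, 0, 0], [0, 0, 0.1, 0], [0, 0, 0, 0]]
        )
        assert np.allclose(joint.Q, expected)
        assert joint.Q.sum() == pytest.approx(1.0, abs=1e-12)
        # marginals agree with direct counting
        assert np.allclose(joint.marginal_a(), [0.2, 0.7, 0.1, 0])
        assert np.allclose(joint.marginal_b(), [0.6, 0.3, 0.1, 0])

    def test_single_pairing_point_mass(self):
        joint = estimate_joint(_pair_table([(2, 3)]), SRC, TGT)
        assert joint.Q[2, 3] == 1.0
        assert joint.Q.sum() == 1.0

    def test_conditioning(self):
        joint = estimate_joint(_pair_table([(0, 0), (1, 0), (1, 1)]), SRC, TGT)
        assert np.allclose(joint.condition_on_b(0), [0.5, 0.5, 0, 0])
        with pytest.raises(EstimationError):
            joint.condition_on_b(3)


class TestMapDiagnostics:
    def test_identity_map(self):
        table = _pair_table([(v, v) for v in range(4)] * 3)
        diag = map_diagnostics(estimate_map(table, SRC, TGT))
        assert diag.bijectivity_fraction == 1.0
        assert diag.bias == 0.0

    def test_systematic_underscoring(self):
        # target always source-1 (clipped at 0)
        pairs = [(x, max(x - 1, 0)) for x in range(4)] * 5
        diag = map_diagnostics(estimate_map(_pair_table(pairs), SRC, TGT))
        assert diag.bias < 0
        assert diag.bijectivity_fraction < 1.0


class TestClusterScoreMap:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = CohortConfig(n_patients=150, seed=9)
        table, _, _ = generate_cohort(cfg)
        model = cluster_qol(table, 4, seed=9)
        return fit_cluster_score_map(model, table, "MG-ADL"), table

    def test_monotone_cluster_means(self, fitted):
        cs, _ = fitted
        means = cs.cluster_stats["mean"].dropna().to_numpy()
        assert cs.monotone
        assert (np.diff(means) >= 0).all()

    def test_level_stats_complete(self, fitted):
        cs, _ = fitted
        assert list(cs.level_stats.index) == [1, 2, 3, 4]
        assert cs.level_stats["mean"].notna().all()
        assert (cs.level_stats["sd"].dropna() >= 0).all()
        assert cs.qol_total_max == 60 and cs.target_total_max == 24

    def test_level_of_uses_quartile_edges(self, fitted):
        cs, _ = fitted
        assert cs.level_of(0.0) == 1
        assert cs.level_of(1.0) == 4
        levels = cs.level_of(np.array([0.0, 0.5, 1.0]))
        assert (np.diff(levels) >= 0).all()

    def test_serialization_roundtrip(self, fitted):
        cs, _ = fitted
        from mgportrait.maps import ClusterScoreMap

        again = ClusterScoreMap.from_dict(cs.to_dict())
        pd.testing.assert_frame_equal(again.cluster_stats, cs.cluster_stats)
        assert np.allclose(again.level_edges, cs.level_edges)

    def test_constant_scores_give_equal_means_zero_sd(self):
        from mgportrait.schema import get_instrument
        from mgportrait.structure import QoLClusterModel

        recs = []
        for i in range(8):
            for it in get_instrument("MG-ADL").items:
                recs.append((f"P{i}", 0, "MG-ADL", it.item_id, None, 1))
            for it in get_instrument("MG-QOL15").items:
                recs.append((f"P{i}", 0, "MG-QOL15", it.item_id, None, 2))
        table = ScoreTable.from_records(recs)
        idx = pd.MultiIndex.from_arrays(
            [[f"P{i}" for i in range(8)], [0.0] * 8, [""] * 8],
            names=["patient_id", "visit_month", "rater_id"],
        )
        model = QoLClusterModel(
            k=2,
            assignments=pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=idx, name="cluster"),
            centroids=pd.DataFrame(
                np.full((2, 15), 2.0),
                index=pd.RangeIndex(1, 3, name="cluster"),
                columns=[it.item_id for it in get_instrument("MG-QOL15").items],
            ),
            silhouette=np.zeros(8),
            cluster_order=[0, 1],
            mean_silhouette=0.0,
        )
        cs = fit_cluster_score_map(model, table, "MG-ADL")
        assert (cs.cluster_stats["mean"] == 8).all()
        assert (cs.cluster_stats["sd"] == 0).all()


class TestSampleQoLFromLevel:
    def _cs(self, sd):
        from mgportrait.maps import ClusterScoreMap

        stats = pd.DataFrame(
            {"mean": [10.0, 20, 30, 40], "sd": [sd] * 4, "n": [10] * 4},
            index=pd.RangeIndex(1, 5, name="level"),
        )
        return ClusterScoreMap(
            target_instrument="MG-ADL",
            cluster_stats=stats.copy(),
            level_edges=np.array([0.25, 0.5, 0.75]),
            level_stats=stats,
            qol_total_max=60,
            target_total_max=24,
            monotone=True,
        )

    def test_zero_sigma_degenerate(self):
        cs = self._cs(0.0)
        draws = sample_qol_from_level(cs, 2, seed=0, size=50)
        assert (draws == 20).all()

    def test_sample_mean_near_mu(self):
        cs = self._cs(5.0)
        draws = sample_qol_from_level(cs, 3, seed=1, size=20_000)
        assert draws.mean() == pytest.approx(30, abs=3 * 5 / np.sqrt(20_000) + 0.05)

    def test_out_of_range_mu_clips_to_boundary(self):
        from mgportrait.maps import ClusterScoreMap

        stats = pd.DataFrame(
            {"mean": [70.0] * 4, "sd": [0.5] * 4, "n": [10] * 4},
            index=pd.RangeIndex(1, 5, name="level"),
        )
        cs = ClusterScoreMap(
            target_instrument="MG-ADL", cluster_stats=stats.copy(),
            level_edges=np.array([0.25, 0.5, 0.75]), level_stats=stats,
            qol_total_max=60, target_total_max=24, monotone=True,
        )
        draws = sample_qol_from_level(cs, 1, seed=0, size=100)
        assert (draws == 60).all()

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            sample_qol_from_level(self._cs(1.0), 5, seed=0)


class TestMapFromCounts:
    def test_row_stochastic_for_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 20, size=(4, 4))
            smap = map_from_counts(counts, SRC, TGT, range(4), range(4))
            assert np.allclose(smap.P.sum(axis=1), 1.0, atol=1e-9)
            assert (smap.P >= 0).all()
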