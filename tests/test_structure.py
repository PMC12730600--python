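"""Correlation, regrouping and QoL clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mgportrait.schema import ScoreTable, get_instrument
from mgportrait.structure import (
    CorrelationResult,
    centroid_monotonicity,
    cluster_qol,
    correlation_matrix,
    regroup_strong_pairs,
    select_qol_k,
)
from mgportrait.synthetic import generate_qol_archetype_table


def _paired_item_table(rng, n=300):
    """MG-ADL table where double_vision duplicates eyelid_drop and the rest
    are independent uniforms."""
    recs = []
    for i in range(n):
        v = int(rng.integers(0, 4))
        recs.append((f"P{i}", 0, "MG-ADL", "eyelid_drop", None, v))
        recs.append((f"P{i}", 0, "MG-ADL", "double_vision", None, v))
        recs.append((f"P{i}", 0, "MG-ADL", "talking", None, int(rng.integers(0, 4))))
        recs.append((f"P{i}", 0, "MG-ADL", "chewing", None, int(rng.integers(0, 4))))
    return ScoreTable.from_records(recs)


class TestCorrelationMatrix:
    def test_duplicated_item_has_unit_correlation(self):
        table = _paired_item_table(np.random.default_rng(0))
        corr = correlation_matrix(table, "MG-ADL")
        assert corr.rho.loc["eyelid_drop", "double_vision"] == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        table = _paired_item_table(np.random.default_rng(1), n=1000)
        corr = correlation_matrix(table, "MG-ADL")
        assert abs(corr.rho.loc["talking", "chewing"]) < 0.1

    def test_symmetry_unit_diagonal_and_bounds(self, small_cohort):
        _, table, _, _ = small_cohort
        corr = correlation_matrix(table, "QMG")
        R = corr.rho.to_numpy()
        assert np.allclose(R, R.T, equal_nan=True)
        assert np.allclose(np.diag(R), 1.0)
        finite = np.isfinite(R)
        assert (np.abs(R[finite]) <= 1).all()
        P = corr.pval.to_numpy()
        assert ((P[np.isfinite(P)] >= 0) & (P[np.isfinite(P)] <= 1)).all()

    def test_absent_instrument_rejected(self, small_cohort):
        _, table, _, _ = small_cohort
        with pytest.raises(Exception, match="MG-CE"):
            correlation_matrix(table, "MG-CE")

    def test_sparse_pairs_left_missing(self):
        recs = [
            ("P1", 0, "MG-ADL", "talking", None, 1),
            ("P1", 0, "MG-ADL", "chewing", None, 2),
            ("P2", 0, "MG-ADL", "talking", None, 0),
        ]
        corr = correlation_matrix(ScoreTable.from_records(recs), "MG-ADL")
        assert np.isnan(corr.rho.loc["talking", "chewing"])
        assert corr.n_pairs.loc["talking", "chewing"] == 1


def _corr_from_matrix(items, rho, pval=None):
    idx = pd.Index(items, name="item_id")
    R = pd.DataFrame(rho, index=idx, columns=idx)
    P = pd.DataFrame(
        pval if pval is not None else np.zeros_like(rho), index=idx, columns=idx
    )
    return CorrelationResult("MG-ADL", R, P, P * 0 + 100)


class TestRegroupStrongPairs:
    def test_single_strong_pair_blocks(self):
        items = ["left_leg", "right_leg", "head"]
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.9
        g = regroup_strong_pairs(_corr_from_matrix(items, R))
        assert g.blocks == [frozenset({"left_leg", "right_leg"}), frozenset({"head"})]

    def test_all_zero_gives_singletons(self):
        items = ["a", "b", "c"]
        g = regroup_strong_pairs(_corr_from_matrix(items, np.eye(3)))
        assert all(len(b) == 1 for b in g.groups)

    def test_chain_forms_single_block(self):
        # A-B = 0.6, B-C = 0.6, A-C = 0.1: transitive closure joins all three
        items = ["a", "b", "c"]
        R = np.array([[1, 0.6, 0.1], [0.6, 1, 0.6], [0.1, 0.6, 1]])
        g = regroup_strong_pairs(_corr_from_matrix(items, R))
        assert g.blocks == [frozenset({"a", "b", "c"})]

    def test_insignificant_edge_ignored(self):
        items = ["a", "b"]
        R = np.array([[1, 0.9], [0.9, 1]])
        P = np.array([[0, 0.5], [0.5, 0]])
        g = regroup_strong_pairs(_corr_from_matrix(items, R, P))
        assert all(len(b) == 1 for b in g.groups)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            regroup_strong_pairs(_corr_from_matrix(["a"], np.eye(1)), rho_threshold=1.5)

    def test_relabeling_invariance(self):
        items = ["a", "b", "c", "d"]
        rng = np.random.default_rng(0)
        R = np.eye(4)
        R[0, 2] = R[2, 0] = 0.7
        g1 = regroup_strong_pairs(_corr_from_matrix(items, R))
        perm = [3, 1, 0, 2]
        items2 = [items[i] for i in perm]
        R2 = R[np.ix_(perm, perm)]
        g2 = regroup_strong_pairs(_corr_from_matrix(items2, R2))
        assert set(g1.blocks) == set(g2.blocks)

    def test_planted_blocks_recovered_exactly(self, midsize_cohort):
        _, table, _, _ = midsize_cohort
        adl = regroup_strong_pairs(correlation_matrix(table, "MG-ADL"))
        assert set(adl.blocks) == {
            frozenset({"talking", "chewing", "swallowing"}),
            frozenset({"breathing"}),
            frozenset({"brush_teeth"}),
            frozenset({"sit_to_stand"}),
            frozenset({"double_vision", "eyelid_drop"}),
        }
        qmg = regroup_strong_pairs(correlation_matrix(table, "QMG"))
        assert set(qmg.blocks) == {
            frozenset({"left_leg", "right_leg"}),
            frozenset({"head"}),
            frozenset({"left_grip", "right_grip", "left_arm", "right_arm"}),
            frozenset({"vital"}),
            frozenset({"speech"}),
            frozenset({"swallow", "facial"}),
            frozenset({"ptosis", "vision"}),
        }


class TestClusterQoL:
    def test_planted_archetypes_recovered(self):
        table, truth = generate_qol_archetype_table(n_samples=200, seed=0)
        model = cluster_qol(table, 4, seed=0)
        labels = model.assignments.reset_index().merge(
            truth.reset_index(), on=["patient_id", "visit_month"]
        )
        assert adjusted_rand_score(labels["archetype_level"], labels["cluster"]) >= 0.9

    def test_relabeling_orders_centroid_means(self):
        table, _ = generate_qol_archetype_table(n_samples=120, seed=1)
        model = cluster_qol(table, 4, seed=1)
        means = model.centroids.mean(axis=1).to_numpy()
        assert (np.diff(means) > 0).all()

    def test_fixed_seed_reproducible(self):
        table, _ = generate_qol_archetype_table(n_samples=100, seed=2)
        m1 = cluster_qol(table, 3, seed=5)
        m2 = cluster_qol(table, 3, seed=5)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)
        assert -1 <= m1.mean_silhouette <= 1

    def test_degenerate_duplicate_profiles_flagged(self):
        recs = []
        qol_items = [it.item_id for it in get_instrument("MG-QOL15").items]
        for i in range(6):
            for item in qol_items:
                recs.append((f"P{i}", 0, "MG-QOL15", item, None, 2))
        table = ScoreTable.from_records(recs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cluster_qol(table, 2, seed=0)
        assert model.degenerate

    def test_invalid_k_rejected(self):
        table, _ = generate_qol_archetype_table(n_samples=20, seed=0)
        with pytest.raises(ValueError):
            cluster_qol(table, 1, seed=0)
        with pytest.raises(ValueError):
            cluster_qol(table, 20, seed=0)

    def test_incomplete_vectors_rejected(self):
        recs = [("P1", 0, "MG-QOL15", "frustration", None, 2)]
        with pytest.raises(ValueError, match="incomplete"):
            cluster_qol(ScoreTable.from_records(recs), 2, seed=0)


class TestCentroidMonotonicity:
    def test_monotone_and_violations_reported(self):
        table, _ = generate_qol_archetype_table(n_samples=200, seed=3)
        model = cluster_qol(table, 4, seed=3)
        ok, violating = centroid_monotonicity(model)
        assert ok and violating == []
        # break one item by hand
        model.centroids.iloc[2, model.centroids.columns.get_loc("walking")] = 0.0
        ok, violating = centroid_monotonicity(model)
        assert not ok and violating == ["walking"]


class TestSelectQoLK:
    def test_planted_four_selected(self):
        table, _ = generate_qol_archetype_table(n_samples=200, seed=0)
        assert select_qol_k(table, range(2, 7), seed=0) == 4

    def test_singleton_range(self):
        table, _ = generate_qol_archetype_table(n_samples=60, seed=1)
        assert select_qol_k(table, [2], seed=1) == 2

    def test_pure_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(4)
        qol_items = [it.item_id for it in get_instrument("MG-QOL15").items]
        recs = [
            (f"P{i}", 0, "MG-QOL15", item, None, int(rng.integers(0, 5)))
            for i in range(150)
            for item in qol_items
        ]
        table = ScoreTable.from_records(recs)
        with pytest.warns(UserWarning, match="monotone"):
            k = select_qol_k(table, range(3, 7), seed=4)
        assert k == 3
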