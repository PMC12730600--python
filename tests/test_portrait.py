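"""Portrait assembly, rater aggregation and the weighted composite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgportrait.maps import ItemRef, StochasticMap, estimate_joint, estimate_map
from mgportrait.portrait import (
    CompositeWeights,
    PortraitError,
    aggregate_raters,
    assemble_all_portraits,
    assemble_portrait,
    composite_score,
    empirical_marginals,
)
from mgportrait.schema import ScoreTable, get_instrument


def _full_visit_records(pid="P1", month=0, adl=1, qmg=1, qol=2):
    recs = []
    for name, v in (("MG-ADL", adl), ("QMG", qmg), ("MG-QOL15", qol)):
        for it in get_instrument(name).items:
            recs.append((pid, month, name, it.item_id, None, v))
    return recs


class TestAggregateRaters:
    def test_two_equal_raters(self):
        assert np.allclose(aggregate_raters([2, 3]), [0, 0, 0.5, 0.5])

    def test_single_rater_point_mass(self):
        assert np.allclose(aggregate_raters([1]), [0, 1, 0, 0])

    def test_weighted_histogram(self):
        got = aggregate_raters([0, 0, 3], weights=[1, 1, 2])
        assert np.allclose(got, [0.5, 0, 0, 0.5])

    def test_errors(self):
        with pytest.raises(ValueError):
            aggregate_raters([])
        with pytest.raises(ValueError):
            aggregate_raters([1, 2], weights=[1, -1])
        with pytest.raises(ValueError):
            aggregate_raters([9])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.integers(0, 3), min_size=1, max_size=8),
        seed=st.integers(0, 10_000),
    )
    def test_normalized_and_permutation_invariant(self, vals, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 2.0, len(vals))
        p = aggregate_raters(vals, w)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(len(vals))
        p2 = aggregate_raters([vals[i] for i in perm], w[perm])
        assert np.allclose(p, p2)


class TestAssemblePortrait:
    def test_observed_visit_all_point_masses(self):
        table = ScoreTable.from_records(_full_visit_records(adl=2, qmg=1, qol=3))
        p = assemble_portrait(table, "P1", 0)
        assert all(e.provenance == "observed" for e in p.entries.values())
        for e in p.entries.values():
            assert np.isclose(e.probs.max(), 1.0)
        assert p.totals["MG-ADL"].probs[16] == pytest.approx(1.0)  # 8 items x 2
        assert p.expected_total("MG-ADL") == pytest.approx(16 / 24)

    def test_map_imputation_reproduces_published_row(self):
        """A QMG ptosis of 1 with the MG-ADL ocular item missing yields the
        map row (0.6, 0.3, 0.1, 0) as the imputed distribution."""
        recs = [("P1", 0, "QMG", it.item_id, None, 1) for it in get_instrument("QMG").items]
        table = ScoreTable.from_records(recs)
        P = np.array([[1, 0, 0, 0], [0.6, 0.3, 0.1, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        smap = StochasticMap(
            source=ItemRef("QMG", "ptosis"),
            target=ItemRef("MG-ADL", "eyelid_drop"),
            source_domain=(0, 1, 2, 3), target_domain=(0, 1, 2, 3),
            counts=(P * 10).astype(int), P=P,
            row_support=np.array([10, 10, 10, 10]),
            marginal_filled=np.zeros(4, bool),
        )
        p = assemble_portrait(table, "P1", 0, maps=[smap], instruments=("MG-ADL", "QMG"))
        entry = p.entries[ItemRef("MG-ADL", "eyelid_drop")]
        assert entry.provenance == "imputed_map"
        assert np.allclose(entry.probs, [0.6, 0.3, 0.1, 0])

    def test_joint_conditioning_preferred_over_map(self):
        recs = [("P1", 0, "QMG", it.item_id, None, 0) for it in get_instrument("QMG").items]
        table = ScoreTable.from_records(recs)
        pair_recs = []
        for i, (x, y) in enumerate([(0, 0), (0, 1), (1, 1)] * 10):
            pair_recs.append((f"Q{i}", 0, "QMG", "ptosis", None, x))
            pair_recs.append((f"Q{i}", 0, "MG-ADL", "eyelid_drop", None, y))
        hist = ScoreTable.from_records(pair_recs)
        joint = estimate_joint(
            hist, ItemRef("MG-ADL", "eyelid_drop"), ItemRef("QMG", "ptosis")
        )
        smap = estimate_map(
            hist, ItemRef("QMG", "ptosis"), ItemRef("MG-ADL", "eyelid_drop")
        )
        p = assemble_portrait(
            table, "P1", 0, maps=[smap], joints=[joint], instruments=("MG-ADL", "QMG")
        )
        assert p.entries[ItemRef("MG-ADL", "eyelid_drop")].provenance == "imputed_joint"

    def test_marginal_fallback_when_no_partner(self):
        table = ScoreTable.from_records(_full_visit_records())
        p = assemble_portrait(table, "P1", 0, instruments=("MG-ADL", "QMG", "MG-CE"))
        ce_entry = p.entries[ItemRef("MG-CE", "ptosis")]
        assert ce_entry.provenance == "imputed_marginal"
        assert ce_entry.probs.sum() == pytest.approx(1.0)

    def test_rater_aggregation_provenance(self):
        recs = []
        for r, v in (("R1", 1), ("R2", 2)):
            for it in get_instrument("MG-ADL").items:
                recs.append(("P1", 0, "MG-ADL", it.item_id, r, v))
        table = ScoreTable.from_records(recs)
        p = assemble_portrait(table, "P1", 0, instruments=("MG-ADL",))
        e = p.entries[ItemRef("MG-ADL", "talking")]
        assert e.provenance == "rater_aggregated"
        assert np.allclose(e.probs, [0, 0.5, 0.5, 0])

    def test_nothing_observed_is_error(self):
        table = ScoreTable.from_records(_full_visit_records())
        with pytest.raises(PortraitError, match="month 3"):
            assemble_portrait(table, "P1", 3)

    def test_convolution_of_two_bernoulli_items(self):
        # two items each (0.5, 0.5, 0, 0): total over {0,1,2} = (.25, .5, .25)
        from mgportrait.portrait import PortraitEntry, _convolve_total
        from mgportrait.schema import Instrument, Item

        ins = Instrument("TWO", (Item("a", "a", 0, 3), Item("b", "b", 0, 3)))
        entries = [
            PortraitEntry(np.array([0.5, 0.5, 0, 0]), "imputed_marginal"),
            PortraitEntry(np.array([0.5, 0.5, 0, 0]), "imputed_marginal"),
        ]
        total = _convolve_total(entries, ins)
        assert np.allclose(total.probs[:3], [0.25, 0.5, 0.25])

    def test_totals_expectation_linear_in_items(self, small_cohort):
        _, table, _, _ = small_cohort
        portraits = assemble_all_portraits(table)
        (pid, month), p = next(iter(portraits.items()))
        for name in ("MG-ADL", "QMG"):
            ins = get_instrument(name)
            item_sum = sum(
                p.entries[ItemRef(name, it.item_id)].expectation for it in ins.items
            )
            assert p.totals[name].expectation == pytest.approx(item_sum, abs=1e-8)

    def test_idempotent_for_complete_visits(self):
        table = ScoreTable.from_records(_full_visit_records(adl=1, qmg=2, qol=0))
        p1 = assemble_portrait(table, "P1", 0)
        p2 = assemble_portrait(table, "P1", 0, maps=[], joints=[])
        for ref in p1.entries:
            assert np.allclose(p1.entries[ref].probs, p2.entries[ref].probs)
            assert p1.entries[ref].provenance == p2.entries[ref].provenance


class TestCompositeScore:
    def _portrait(self, adl=1, qmg=1, qol=2):
        table = ScoreTable.from_records(_full_visit_records(adl=adl, qmg=qmg, qol=qol))
        return assemble_portrait(table, "P1", 0)

    def test_degenerate_weights_reduce_to_adl(self):
        p = self._portrait(adl=2)
        comp = composite_score(p, CompositeWeights(1, 0, 0))
        assert comp.expectation == pytest.approx(16 / 24)
        assert len(comp.values) == 1

    def test_point_mass_arithmetic(self):
        # normalized totals 0.2/0.4/0.8 hand-built via direct substitution
        from mgportrait.portrait import ScorePortrait, TotalDistribution

        def point(total_max, frac):
            probs = np.zeros(total_max + 1)
            probs[int(round(frac * total_max))] = 1.0
            return TotalDistribution(probs, total_max)

        p = ScorePortrait(
            "P1", 0.0, entries={},
            totals={
                "MG-ADL": point(10, 0.2),
                "QMG": point(10, 0.4),
                "MG-QOL15": point(10, 0.8),
            },
        )
        comp = composite_score(p, CompositeWeights(0.5, 0.25, 0.25))
        assert comp.expectation == pytest.approx(0.4)

    def test_expectation_is_weighted_sum(self, small_cohort):
        _, table, _, _ = small_cohort
        portraits = assemble_all_portraits(table)
        p = next(iter(portraits.values()))
        w = CompositeWeights(0.5, 0.3, 0.2)
        comp = composite_score(p, w)
        expected = (
            0.5 * p.expected_total("MG-ADL")
            + 0.3 * p.expected_total("QMG")
            + 0.2 * p.expected_total("MG-QOL15")
        )
        assert comp.expectation == pytest.approx(expected, abs=1e-9)
        assert comp.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_instrument_listed_in_error(self):
        table = ScoreTable.from_records(_full_visit_records())
        p = assemble_portrait(table, "P1", 0, instruments=("MG-ADL", "QMG"))
        with pytest.raises(PortraitError, match="MG-QOL15"):
            composite_score(p, CompositeWeights(0.5, 0.5, 0.0))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            CompositeWeights(0.5, 0.5, 0.2)
        with pytest.raises(ValueError):
            CompositeWeights(-0.1, 0.6, 0.5)


class TestEmpiricalMarginals:
    def test_matches_direct_counting(self):
        recs = [
            ("P1", 0, "MG-ADL", "eyelid_drop", None, 0),
            ("P2", 0, "MG-ADL", "eyelid_drop", None, 0),
            ("P3", 0, "MG-ADL", "eyelid_drop", None, 3),
        ]
        m = empirical_marginals(ScoreTable.from_records(recs), ("MG-ADL",))
        assert np.allclose(m[ItemRef("MG-ADL", "eyelid_drop")], [2 / 3, 0, 0, 1 / 3])
        # never-observed items are uniform
        assert np.allclose(m[ItemRef("MG-ADL", "talking")], 0.25)
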