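import math

import numpy as np
import pytest

from freelist.harmonize import harmonize
from freelist.salience import (
    cumulative_taxa,
    domain_membership,
    frequency_and_rank,
    list_lengths,
    salience_table,
    singleton_share,
    smiths_s,
)
from freelist.types import ParameterError, QuestionDomain

from conftest import make_freelist, random_freelists


class TestSmithsS:
    def test_hand_computed_example(self):
        """(n=4, r=3) -> 0.5; (n=2, r=1) -> 1.0; absent -> 0; mean = 0.5."""
        lists = [
            make_freelist("P1", ["a", "b", "T", "c"]),
            make_freelist("P2", ["T", "d"]),
            make_freelist("P3", ["e"]),
        ]
        assert smiths_s(lists, "T") == pytest.approx(0.5, abs=1e-15)

    def test_always_first_mention_gives_one(self):
        lists = [make_freelist(f"P{i}", ["T", "x"]) for i in range(5)]
        assert smiths_s(lists, "T") == 1.0

    def test_unlisted_taxon_gives_zero(self):
        lists = [make_freelist("P1", ["a"])]
        assert smiths_s(lists, "nope") == 0.0

    def test_empty_lists_count_in_denominator(self):
        lists = [make_freelist("P1", ["T"]), make_freelist("P2", [])]
        assert smiths_s(lists, "T") == pytest.approx(0.5)


class TestFrequencyAndRank:
    def test_hand_count(self):
        lists = [
            make_freelist("P1", ["T"]),
            make_freelist("P2", ["a", "b", "T"]),
            make_freelist("P3", ["a"]),
            make_freelist("P4", []),
        ]
        n, freq, mean_rank = frequency_and_rank(lists, "T")
        assert (n, freq, mean_rank) == (2, 0.5, 2.0)

    def test_unlisted_taxon_has_missing_mean_rank(self):
        lists = [make_freelist("P1", ["a"])]
        n, freq, mean_rank = frequency_and_rank(lists, "T")
        assert (n, freq) == (0, 0.0)
        assert math.isnan(mean_rank)


def test_salience_invariants_on_random_fixtures():
    """0 <= S <= rel_freq <= 1 and the per-participant mass identity
    sum_taxa S = (1/N) sum_i (n_i + 1) / 2 over non-empty lists."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        lists = random_freelists(rng, int(rng.integers(2, 15)))
        table = salience_table(lists)
        assert ((table["smiths_s"] >= 0) & (table["smiths_s"] <= table["rel_freq"])).all()
        assert (table["rel_freq"] <= 1).all()
        expected_mass = sum((fl.n + 1) / 2 for fl in lists if fl.n) / len(lists)
        assert table["smiths_s"].sum() == pytest.approx(expected_mass, abs=1e-12)


class TestDomainMembership:
    def test_overlap_rule_removes_higher_taxon_with_member_in_domain(self, bird_catalog):
        lists = (
            [make_freelist(f"A{i}", ["Corvus"]) for i in range(3)]
            + [make_freelist(f"B{i}", ["Rook"]) for i in range(1)]
            + [make_freelist(f"C{i}", ["Blackbird"]) for i in range(6)]
        )
        lists = [harmonize(fl, bird_catalog) for fl in lists]
        table = salience_table(lists)
        with_higher = domain_membership(table, 0.05, True, bird_catalog)
        without = domain_membership(table, 0.05, False, bird_catalog)
        assert "Corvus" in with_higher.members
        assert "Corvus" not in without.members
        assert "Corvus frugilegus" in without.members

    def test_threshold_one_keeps_only_universally_listed(self):
        lists = [make_freelist("P1", ["a", "b"]), make_freelist("P2", ["a"])]
        from freelist.types import TaxonCatalog

        result = domain_membership(salience_table(lists), 1.0, True, TaxonCatalog([]))
        assert result.members == frozenset({"a"})

    def test_threshold_outside_unit_interval_rejected(self):
        from freelist.types import TaxonCatalog

        table = salience_table([make_freelist("P1", ["a"])])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                domain_membership(table, bad, True, TaxonCatalog([]))

    def test_domain_size_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        lists = random_freelists(rng, 30)
        table = salience_table(lists)
        from freelist.types import TaxonCatalog

        sizes = [
            len(domain_membership(table, t, True, TaxonCatalog([])).members)
            for t in np.linspace(0.01, 1.0, 25)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCumulativeAndLengths:
    def test_union_of_disjoint_lists(self, bird_catalog):
        lists = [
            make_freelist("P1", ["Turdus merula", "Alauda arvensis"]),
            make_freelist("P2", ["Corvus"]),
        ]
        got = cumulative_taxa(lists, "raw", False)
        assert got == {"Turdus merula", "Alauda arvensis", "Corvus"}

    def test_overlap_exclusion_drops_ancestor_from_union(self, bird_catalog):
        lists = [
            make_freelist("P1", ["Corvus"]),
            make_freelist("P2", ["Corvus frugilegus"]),
        ]
        got = cumulative_taxa(lists, "raw", True, bird_catalog)
        assert got == {"Corvus frugilegus"}

    def test_exclusion_result_is_subset_of_raw_union(self, bird_catalog):
        rng = np.random.default_rng(3)
        pool = ["Corvus", "Corvus frugilegus", "Corvus cornix", "Turdus merula"]
        lists = [
            make_freelist(
                f"P{i}", rng.choice(pool, size=int(rng.integers(1, 5)), replace=False)
            )
            for i in range(10)
        ]
        with_excl = cumulative_taxa(lists, "raw", True, bird_catalog)
        without = cumulative_taxa(lists, "raw", False)
        assert with_excl <= without

    def test_valid_filter_and_credit_rule_lengths(self, bird_catalog):
        harmonized = harmonize(
            make_freelist("P1", ["Turdus merula", "Rook"]), bird_catalog
        )
        # Corvus was inserted: raw length counts it (credit rule)
        raw = list_lengths([harmonized], "raw")
        assert raw["length"].tolist() == [3]
        farm = list_lengths([harmonized], "farmland_bird")
        assert farm["length"].tolist() == [1]

    def test_valid_never_exceeds_raw(self, plant_catalog):
        rng = np.random.default_rng(5)
        pool = ["Löwenzahn", "Kornblume", "Tulpe", "Arrhenatherum elatius"]
        lists = [
            harmonize(
                make_freelist(
                    f"P{i}",
                    rng.choice(pool, size=int(rng.integers(0, 5)), replace=False),
                    QuestionDomain.PLANT,
                ),
                plant_catalog,
            )
            for i in range(20)
        ]
        raw = list_lengths(lists, "raw")["length"]
        valid = list_lengths(lists, "valid")["length"]
        assert (valid <= raw).all()

    def test_empty_list_has_length_zero(self):
        assert list_lengths([make_freelist("P1", [])], "raw")["length"].tolist() == [0]


class TestSingletonShare:
    def test_all_singletons(self, bird_catalog):
        lists = [make_freelist("P1", ["Turdus merula"]), make_freelist("P2", ["Alauda arvensis"])]
        assert singleton_share(lists, "raw", False) == 1.0

    def test_no_singletons(self, bird_catalog):
        lists = [make_freelist("P1", ["Turdus merula"]), make_freelist("P2", ["Turdus merula"])]
        assert singleton_share(lists, "raw", False) == 0.0

    def test_hand_counted_share(self):
        lists = [
            make_freelist("P1", ["a", "b", "c", "d"]),
            make_freelist("P2", ["a", "b", "c", "e"]),
        ]
        # a, b, c listed twice; d, e once -> 2 of 5
        assert singleton_share(lists, "raw", False) == pytest.approx(0.4)

    def test_empty_cumulative_set_is_missing(self):
        assert math.isnan(singleton_share([make_freelist("P1", [])], "raw", False))
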