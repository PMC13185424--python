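import numpy as np
import pytest

from freelist.compare import (
    AgeSplit,
    group_salience,
    indicator_frequency_by_age,
    participant_contributions,
    salience_randomization_test,
    salience_randomization_tests,
)
from freelist.types import Gender, ParameterError, ParticipantRecord

from conftest import make_freelist, random_freelists, random_participants


def _participants_with_ages(ages):
    return [
        ParticipantRecord(f"R{i:03d}", Gender.FEMALE, age, 3, 3)
        for i, age in enumerate(ages)
    ]


class TestGroupSalience:
    def test_default_split_is_classes_123_vs_456(self):
        split = AgeSplit()
        for age, expected in [(1, 0), (3, 0), (4, 1), (6, 1)]:
            p = ParticipantRecord("x", Gender.MALE, age, 3, 3)
            assert split.group_of(p) == expected

    def test_identical_freelists_give_identical_tables(self):
        lists = [make_freelist(f"R{i:03d}", ["a", "b"]) for i in range(4)]
        parts = _participants_with_ages([1, 2, 5, 6])
        young, old = group_salience(lists, parts)
        for col in ("rel_freq", "smiths_s", "mean_rank"):
            assert young[col].tolist() == old[col].tolist()

    def test_taxon_listed_only_by_older_has_zero_young_salience(self):
        lists = [
            make_freelist("R000", ["a"]),
            make_freelist("R001", ["b"]),
        ]
        parts = _participants_with_ages([2, 5])
        young, old = group_salience(lists, parts)
        assert young.set_index("taxon").loc["b", "smiths_s"] == 0.0
        assert old.set_index("taxon").loc["b", "smiths_s"] == 1.0

    def test_empty_group_rejected(self):
        lists = [make_freelist("R000", ["a"])]
        parts = _participants_with_ages([2])
        with pytest.raises(ParameterError):
            group_salience(lists, parts)


class TestRandomizationTest:
    def test_constant_contributions_give_p_one_and_zero_diff(self):
        lists = [make_freelist(f"R{i:03d}", ["T"]) for i in range(6)]
        parts = _participants_with_ages([1, 2, 3, 4, 5, 6])
        res = salience_randomization_test(lists, parts, "T", n_perm=200, seed=0)
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_same_seed_reproduces_p_exactly(self):
        rng = np.random.default_rng(1)
        lists = random_freelists(rng, 12)
        parts = _participants_with_ages([1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6])
        taxon = "TX00"
        a = salience_randomization_test(lists, parts, taxon, n_perm=500, seed=9)
        b = salience_randomization_test(lists, parts, taxon, n_perm=500, seed=9)
        assert a == b
        assert a.p_value >= 1 / 501

    def test_swapping_groups_negates_diff_and_keeps_p(self):
        rng = np.random.default_rng(2)
        lists = random_freelists(rng, 10, allow_empty=False)
        parts = _participants_with_ages([1, 1, 1, 2, 3, 4, 5, 5, 6, 6])
        swapped = AgeSplit(young_classes=frozenset({4, 5, 6}), labels=("old", "young"))
        taxon = "TX01"
        a = salience_randomization_test(lists, parts, taxon, n_perm=400, seed=3)
        b = salience_randomization_test(lists, parts, taxon, split=swapped, n_perm=400, seed=3)
        assert a.observed_diff == pytest.approx(-b.observed_diff, abs=1e-15)
        assert a.p_value == b.p_value

    def test_montecarlo_converges_to_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        lists = random_freelists(rng, 8, allow_empty=False)
        parts = _participants_with_ages([1, 2, 3, 3, 4, 5, 6, 6])
        taxon = "TX02"
        exact = salience_randomization_test(lists, parts, taxon, exact=True)
        assert exact.method == "exhaustive"
        mc = salience_randomization_test(lists, parts, taxon, n_perm=20_000, seed=5)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20_000)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1e-4

    def test_invalid_parameters_rejected(self):
        lists = [make_freelist("R000", ["a"]), make_freelist("R001", ["a"])]
        with pytest.raises(ParameterError):
            salience_randomization_test(
                lists, _participants_with_ages([1, 5]), "a", n_perm=0
            )
        with pytest.raises(ParameterError):
            salience_randomization_test(
                lists, _participants_with_ages([1, 2]), "a", n_perm=10
            )

    def test_batch_runner_reports_stars_and_adjustment(self):
        rng = np.random.default_rng(6)
        lists = random_freelists(rng, 14, allow_empty=False)
        parts = random_participants(rng, 14)
        df = salience_randomization_tests(
            lists, parts, ["TX00", "TX01"], n_perm=200, seed=1, p_adjust="holm"
        )
        assert set(df.columns) >= {"taxon", "observed_diff", "p_value", "stars", "p_adjusted"}
        assert (df["p_adjusted"] >= df["p_value"] - 1e-15).all()


class TestIndicatorFrequencyByAge:
    def test_hand_counted_cell(self):
        # class 4 has 5 participants, 2 of whom list T
        ages = [4] * 5 + [1] * 3
        parts = _participants_with_ages(ages)
        lists = [
            make_freelist("R000", ["T"]),
            make_freelist("R001", ["T", "x"]),
            make_freelist("R002", ["x"]),
            make_freelist("R005", ["T"]),
        ]
        with pytest.warns(UserWarning):  # some age classes are empty
            table = indicator_frequency_by_age(lists, parts, ["T"])
        cell = table.set_index(["taxon", "age_class"]).loc[("T", 4)]
        assert cell["n_listers"] == 2
        assert cell["n_in_class"] == 5
        assert cell["rel_freq"] == pytest.approx(0.4)
        assert table["n_in_class"].groupby(table["age_class"]).first().sum() == len(parts)

    def test_unlisted_taxon_has_all_zero_rows(self):
        parts = _participants_with_ages([1, 2, 3, 4, 5, 6])
        lists = [make_freelist("R000", ["x"])]
        table = indicator_frequency_by_age(lists, parts, ["never"])
        assert (table["n_listers"] == 0).all()


def test_contributions_vector_aligns_with_participants():
    lists = [make_freelist("R001", ["T", "x"])]
    parts = _participants_with_ages([1, 5])  # R000 has no freelist
    c = participant_contributions(lists, parts, "T")
    assert c.tolist() == [0.0, 1.0]
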