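import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freelist.harmonize import annotate, canonicalize, harmonize, insert_higher_order
from freelist.types import (
    AnnotationError,
    IndicatorClass,
    Provenance,
    QuestionDomain,
)

from conftest import make_freelist


class TestCanonicalize:
    def test_synonyms_resolve_and_duplicates_drop_keeping_first(self, plant_catalog):
        fl = make_freelist(
            "P1", ["Speckblume", "Kornblume", "Löwenzahn"], QuestionDomain.PLANT
        )
        out = canonicalize(fl, plant_catalog)
        assert out.labels() == ("Taraxacum sect. Ruderalia", "Centaurea cyanus")
        assert [i.rank for i in out.items] == [1, 2]

    def test_already_canonical_list_unchanged(self, plant_catalog):
        fl = make_freelist(
            "P1", ["Centaurea cyanus", "Taraxacum sect. Ruderalia"], QuestionDomain.PLANT
        )
        assert canonicalize(fl, plant_catalog) == fl

    def test_empty_list_stays_empty(self, plant_catalog):
        fl = make_freelist("P1", [], QuestionDomain.PLANT)
        assert canonicalize(fl, plant_catalog).n == 0

    def test_unresolvable_label_names_the_label(self, plant_catalog):
        fl = make_freelist("P1", ["Quercus"], QuestionDomain.PLANT)
        with pytest.raises(AnnotationError, match="Quercus"):
            canonicalize(fl, plant_catalog)


class TestInsertHigherOrder:
    def test_missing_genus_inserted_just_before_first_member(self, bird_catalog):
        fl = make_freelist("P1", ["Turdus merula", "Corvus frugilegus"])
        out = insert_higher_order(fl, bird_catalog)
        assert out.labels() == ("Turdus merula", "Corvus", "Corvus frugilegus")
        assert [i.provenance for i in out.items] == [
            Provenance.LISTED,
            Provenance.INSERTED,
            Provenance.LISTED,
        ]
        assert [i.rank for i in out.items] == [1, 2, 3]

    def test_noop_when_higher_taxon_already_listed(self, bird_catalog):
        fl = make_freelist("P1", ["Corvus", "Corvus frugilegus"])
        assert insert_higher_order(fl, bird_catalog) == fl

    def test_one_insertion_serves_both_member_species(self, bird_catalog):
        fl = make_freelist("P1", ["Corvus cornix", "Corvus frugilegus"])
        out = insert_higher_order(fl, bird_catalog)
        assert out.labels() == ("Corvus", "Corvus cornix", "Corvus frugilegus")
        assert out.items[0].provenance is Provenance.INSERTED

    def test_credit_rule_gives_species_lister_both_credits(self, bird_catalog):
        """Listing Rook earns the crow credit plus the species credit."""
        rook_only = harmonize(make_freelist("P1", ["Rook"]), bird_catalog)
        crows_only = harmonize(make_freelist("P2", ["Crows"]), bird_catalog)
        assert rook_only.n == 2
        assert crows_only.n == 1

    def test_idempotent_and_order_preserving_on_random_lists(self, bird_catalog):
        rng = np.random.default_rng(42)
        pool = ["Corvus", "Corvus frugilegus", "Corvus cornix", "Turdus merula",
                "Alauda arvensis"]
        for _ in range(300):
            n = int(rng.integers(0, len(pool) + 1))
            labels = list(rng.choice(pool, size=n, replace=False))
            fl = make_freelist("P1", labels)
            once = insert_higher_order(fl, bird_catalog)
            assert insert_higher_order(once, bird_catalog) == once
            listed = [i.label for i in once.items if i.provenance is Provenance.LISTED]
            assert listed == labels
            missing_ancestors = {
                anc.canonical_name
                for lbl in labels
                for anc in [bird_catalog.parent(lbl)]
                if anc is not None and anc.canonical_name not in labels
            }
            assert once.n == fl.n + len(missing_ancestors)


class TestAnnotate:
    def test_validity_and_indicator_class_copied(self, plant_catalog):
        fl = make_freelist(
            "P1", ["Centaurea cyanus", "Tulipa gesneriana"], QuestionDomain.PLANT
        )
        out = annotate(fl, plant_catalog)
        cornflower, tulip = out.items
        assert cornflower.valid
        assert cornflower.indicator_class is IndicatorClass.ARABLE_PLANT
        assert not tulip.valid
        assert tulip.indicator_class is IndicatorClass.NONE

    def test_inserted_items_are_annotated_like_listed_ones(self, bird_catalog):
        out = harmonize(make_freelist("P1", ["Rook"]), bird_catalog)
        inserted = out.items[0]
        assert inserted.label == "Corvus"
        assert inserted.provenance is Provenance.INSERTED
        assert inserted.valid


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.sampled_from(
    ["Crows", "Rook", "Hooded crow", "Blackbird", "Skylark",
     "Corvus", "Corvus frugilegus"]), max_size=7))
def test_harmonize_never_shrinks_and_never_reorders(bird_catalog, labels):
    # dedupe raw labels so the list is constructible with distinct mentions
    seen, raw = set(), []
    for lbl in labels:
        if lbl not in seen:
            seen.add(lbl)
            raw.append(lbl)
    fl = make_freelist("P1", raw)
    out = harmonize(fl, bird_catalog)
    canonical = canonicalize(fl, bird_catalog)
    assert out.n >= canonical.n
    listed = [i.label for i in out.items if i.provenance is Provenance.LISTED]
    assert listed == list(canonical.labels())
    assert len(set(out.labels())) == out.n  # no canonical taxon twice
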