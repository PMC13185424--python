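"""Freelist preparation: canonicalization, higher-order taxon insertion, annotation.

Interviewees mix taxonomic levels: one person says "Rook", another just
"crows".  To make lists comparable, a missing higher-order taxon whose
member species was listed is *inserted* just before the first-listed member,
so that a participant naming a species receives credit both for the species
and for the enclosing higher-order taxon, while a participant naming only
the higher-order taxon receives a single credit.

Only the catalog's declared parent is inserted — one level, never the whole
chain: the insertion mirrors the name people actually use for the group
(e.g. "crows"), not every Linnaean rank above the species.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import (
    AnnotationError,
    Dataset,
    Freelist,
    FreelistItem,
    IndicatorClass,
    IntegrityError,
    Provenance,
    QuestionDomain,
    TaxonCatalog,
    TaxonLevel,
)


@dataclass(frozen=True)
class AnnotatedItem:
    label: str                       # canonical taxon name
    rank: int
    provenance: Provenance
    valid: bool
    indicator_class: IndicatorClass
    level: TaxonLevel

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise IntegrityError(f"rank must be >= 1, got {self.rank}")


@dataclass(frozen=True)
class AnnotatedFreelist:
    """A harmonized freelist whose items carry catalog annotations."""

    participant_id: str
    question_domain: QuestionDomain
    items: tuple[AnnotatedItem, ...] = ()

    def __post_init__(self) -> None:
        for i, item in enumerate(self.items, start=1):
            if item.rank != i:
                raise IntegrityError(
                    f"annotated freelist {self.participant_id}: ranks not consecutive"
                )

    @property
    def n(self) -> int:
        return len(self.items)

    def labels(self) -> tuple[str, ...]:
        return tuple(item.label for item in self.items)


def canonicalize(fl: Freelist, catalog: TaxonCatalog) -> Freelist:
    """Replace item labels by canonical taxon names and drop later duplicates.

    When two mentions resolve to the same canonical taxon (vernacular
    synonyms), the earliest mention is kept — freelist rank encodes
    accessibility from memory — and subsequent ranks close the gap.
    """
    items: list[FreelistItem] = []
    seen: set[str] = set()
    for item in fl.items:
        entry = catalog.resolve(item.label)
        if entry is None:
            raise AnnotationError(
                f"participant {fl.participant_id!r}: label {item.label!r} "
                f"not resolvable against the catalog"
            )
        if entry.canonical_name in seen:
            continue
        seen.add(entry.canonical_name)
        items.append(
            FreelistItem(entry.canonical_name, len(items) + 1, item.provenance)
        )
    return Freelist(fl.participant_id, fl.question_domain, tuple(items))


def insert_higher_order(fl: Freelist, catalog: TaxonCatalog) -> Freelist:
    """Insert each missing higher-order taxon just before its first-listed member.

    For every catalog parent H with at least one listed descendant but H
    itself absent from the list, H is added immediately before the
    first-listed descendant, flagged ``inserted``, and ranks are renumbered.
    Insertions never trigger further insertions (no chaining), and the
    relative order of originally listed items is preserved.  Idempotent.
    """
    present = set(fl.labels())
    items: list[FreelistItem] = []
    inserted: set[str] = set()
    for item in fl.items:
        entry = catalog.resolve(item.label)
        if entry is None:
            raise AnnotationError(
                f"participant {fl.participant_id!r}: label {item.label!r} "
                f"not resolvable against the catalog"
            )
        parent = catalog.parent(entry.canonical_name)
        if (
            parent is not None
            and item.provenance is Provenance.LISTED
            and parent.canonical_name not in present
            and parent.canonical_name not in inserted
        ):
            items.append(
                FreelistItem(parent.canonical_name, len(items) + 1, Provenance.INSERTED)
            )
            inserted.add(parent.canonical_name)
        items.append(FreelistItem(item.label, len(items) + 1, item.provenance))
    return Freelist(fl.participant_id, fl.question_domain, tuple(items))


def annotate(fl: Freelist, catalog: TaxonCatalog) -> AnnotatedFreelist:
    """Copy validity, indicator class, and level from the catalog onto each item.

    Order and ranks are unchanged; inserted items are annotated like listed
    ones, so they count toward list lengths (the credit rule).
    """
    items = []
    for item in fl.items:
        entry = catalog.resolve(item.label)
        if entry is None:
            raise AnnotationError(
                f"participant {fl.participant_id!r}: label {item.label!r} "
                f"not resolvable against the catalog"
            )
        items.append(
            AnnotatedItem(
                label=entry.canonical_name,
                rank=item.rank,
                provenance=item.provenance,
                valid=entry.valid,
                indicator_class=entry.indicator_class,
                level=entry.level,
            )
        )
    return AnnotatedFreelist(fl.participant_id, fl.question_domain, tuple(items))


def harmonize(fl: Freelist, catalog: TaxonCatalog) -> AnnotatedFreelist:
    """Full preparation pipeline: canonicalize, insert higher-order taxa, annotate."""
    return annotate(insert_higher_order(canonicalize(fl, catalog), catalog), catalog)


def harmonize_dataset(ds: Dataset) -> list[AnnotatedFreelist]:
    return [harmonize(fl, ds.catalog) for fl in ds.freelists]
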