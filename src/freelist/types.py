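"""Core data types for freelist cultural-domain analysis.

A *freelist* is one participant's ordered list of item mentions for one
interview question (here: wild herbaceous plants or farmland birds).  Rank 1
is the first item that came to mind; rank order is taken as a proxy for
cognitive accessibility.  A *taxon catalog* maps the vernacular labels people
use onto canonical taxa, records each taxon's level (species up to order),
its next higher-order parent taxon where the catalog declares one, whether it
is a *valid* answer (a taxon genuinely occurring wild in the open agricultural
landscape), its *indicator class* (grassland plant, arable plant, farmland
bird, or none), and an expert rating of its regional frequency on a 0-3
scale (0 absent, 1 rare, 2 occasional, 3 common).
"""

from __future__ import annotations

import enum
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional


class FreelistError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FreelistError):
    """A file does not conform to the expected CSV layout."""


class IntegrityError(FreelistError):
    """Data violate a structural invariant (rank gaps, cycles, duplicates)."""


class CatalogError(FreelistError):
    """A taxon catalog reference cannot be resolved (dangling parent)."""


class AnnotationError(FreelistError):
    """A freelist item cannot be resolved against the catalog."""


class ParameterError(FreelistError, ValueError):
    """An analysis parameter is outside its admissible range."""


class FitError(FreelistError):
    """A model fit failed to converge."""


class QuestionDomain(str, enum.Enum):
    PLANT = "plant"
    BIRD = "bird"


class Provenance(str, enum.Enum):
    LISTED = "listed"      # mentioned by the participant
    INSERTED = "inserted"  # added by the higher-order-taxon credit rule


class TaxonLevel(str, enum.Enum):
    SPECIES = "species"
    SECTION = "section"
    AGGREGATE = "aggregate"
    GENUS = "genus"
    FAMILY = "family"
    ORDER = "order"


#: coarse ordering used to check that a parent sits above its child
LEVEL_ORDER: dict[TaxonLevel, int] = {
    TaxonLevel.SPECIES: 0,
    TaxonLevel.SECTION: 1,
    TaxonLevel.AGGREGATE: 1,
    TaxonLevel.GENUS: 2,
    TaxonLevel.FAMILY: 3,
    TaxonLevel.ORDER: 4,
}


class IndicatorClass(str, enum.Enum):
    GRASSLAND_PLANT = "grassland_plant"
    ARABLE_PLANT = "arable_plant"
    FARMLAND_BIRD = "farmland_bird"
    NONE = "none"


class Gender(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


#: age classes 1..6 = 18-25, 26-35, 36-45, 46-55, 56-65, >65
AGE_CLASS_LABELS = ("18-25", "26-35", "36-45", "46-55", "56-65", ">65")
N_AGE_CLASSES = 6
EDUCATION_RANGE = (1, 6)
INCOME_RANGE = (1, 6)


def normalize_label(label: str) -> str:
    """Normalize a hand-transcribed item label for matching.

    Unicode NFKC normalization, whitespace trimming and case folding;
    interview transcripts are inconsistent in exactly these ways.
    """
    return unicodedata.normalize("NFKC", label).strip().casefold()


@dataclass(frozen=True)
class FreelistItem:
    label: str
    rank: int
    provenance: Provenance = Provenance.LISTED

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise IntegrityError(f"rank must be >= 1, got {self.rank}")


@dataclass(frozen=True)
class Freelist:
    """One participant's ordered mentions for one question domain.

    Ranks must be consecutive 1..n; n = 0 (nothing listed) is allowed.
    """

    participant_id: str
    question_domain: QuestionDomain
    items: tuple[FreelistItem, ...] = ()

    def __post_init__(self) -> None:
        for i, item in enumerate(self.items, start=1):
            if item.rank != i:
                raise IntegrityError(
                    f"freelist {self.participant_id}/{self.question_domain.value}: "
                    f"expected rank {i}, got {item.rank} (ranks must be consecutive 1..n)"
                )

    @property
    def n(self) -> int:
        return len(self.items)

    def labels(self) -> tuple[str, ...]:
        return tuple(item.label for item in self.items)


@dataclass(frozen=True)
class TaxonEntry:
    canonical_name: str
    level: TaxonLevel
    parent: Optional[str] = None  # canonical name of the next higher-order taxon
    valid: bool = True
    indicator_class: IndicatorClass = IndicatorClass.NONE
    regional_frequency: int = 0

    def __post_init__(self) -> None:
        if self.regional_frequency not in (0, 1, 2, 3):
            raise IntegrityError(
                f"{self.canonical_name}: regional_frequency must be in 0..3, "
                f"got {self.regional_frequency}"
            )


class TaxonCatalog:
    """Resolves item labels to canonical taxa and holds the parent hierarchy.

    Several vernacular labels may map to one canonical taxon (synonyms);
    matching is case-insensitive after Unicode normalization and trimming.
    """

    def __init__(
        self,
        entries: Iterable[TaxonEntry],
        synonyms: Mapping[str, str] | None = None,
    ) -> None:
        self._entries: dict[str, TaxonEntry] = {}
        for entry in entries:
            if entry.canonical_name in self._entries:
                raise IntegrityError(f"duplicate catalog entry {entry.canonical_name!r}")
            self._entries[entry.canonical_name] = entry

        self._synonyms: dict[str, str] = {}
        for name in self._entries:
            self._synonyms[normalize_label(name)] = name
        if synonyms:
            for label, canonical in synonyms.items():
                if canonical not in self._entries:
                    raise CatalogError(
                        f"synonym {label!r} points at unknown taxon {canonical!r}"
                    )
                key = normalize_label(label)
                existing = self._synonyms.get(key)
                if existing is not None and existing != canonical:
                    raise IntegrityError(
                        f"label {label!r} maps to both {existing!r} and {canonical!r}"
                    )
                self._synonyms[key] = canonical

        self._check_parents()

    def _check_parents(self) -> None:
        for entry in self._entries.values():
            if entry.parent is None:
                continue
            parent = self._entries.get(entry.parent)
            if parent is None:
                raise CatalogError(
                    f"{entry.canonical_name}: parent {entry.parent!r} not in catalog"
                )
            if (
                entry.level == TaxonLevel.SPECIES
                and LEVEL_ORDER[parent.level] <= LEVEL_ORDER[TaxonLevel.SPECIES]
            ):
                raise IntegrityError(
                    f"{entry.canonical_name}: parent {entry.parent!r} is not "
                    f"above species level"
                )
        # cycle check by walking each parent chain
        for name in self._entries:
            seen = {name}
            current = self._entries[name].parent
            while current is not None:
                if current in seen:
                    raise IntegrityError(f"cyclic parent chain through {current!r}")
                seen.add(current)
                current = self._entries[current].parent

    # -- lookup ----------------------------------------------------------
    def resolve(self, label: str) -> Optional[TaxonEntry]:
        """Return the catalog entry for a (possibly vernacular) label, or None."""
        canonical = self._synonyms.get(normalize_label(label))
        return None if canonical is None else self._entries[canonical]

    def entry(self, canonical_name: str) -> TaxonEntry:
        try:
            return self._entries[canonical_name]
        except KeyError:
            raise CatalogError(f"unknown taxon {canonical_name!r}") from None

    def parent(self, canonical_name: str) -> Optional[TaxonEntry]:
        parent_name = self.entry(canonical_name).parent
        return None if parent_name is None else self._entries[parent_name]

    def ancestors(self, canonical_name: str) -> Iterator[TaxonEntry]:
        """Yield the parent chain of a taxon, nearest first."""
        current = self.entry(canonical_name).parent
        while current is not None:
            entry = self._entries[current]
            yield entry
            current = entry.parent

    def synonyms_of(self, canonical_name: str) -> tuple[str, ...]:
        self.entry(canonical_name)
        return tuple(
            label for label, name in self._synonyms.items() if name == canonical_name
        )

    @property
    def synonym_map(self) -> Mapping[str, str]:
        return dict(self._synonyms)

    def __contains__(self, canonical_name: object) -> bool:
        return canonical_name in self._entries

    def __getitem__(self, canonical_name: str) -> TaxonEntry:
        return self.entry(canonical_name)

    def __iter__(self) -> Iterator[TaxonEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._entries)


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    gender: Gender
    age_class: int                    # 1..6, see AGE_CLASS_LABELS
    education: int                    # ordinal 1..6
    income: Optional[int] = None      # ordinal 1..6, may be missing

    def __post_init__(self) -> None:
        if not 1 <= self.age_class <= N_AGE_CLASSES:
            raise IntegrityError(
                f"{self.participant_id}: age_class {self.age_class} outside 1..{N_AGE_CLASSES}"
            )
        lo, hi = EDUCATION_RANGE
        if not lo <= self.education <= hi:
            raise IntegrityError(
                f"{self.participant_id}: education {self.education} outside {lo}..{hi}"
            )
        lo, hi = INCOME_RANGE
        if self.income is not None and not lo <= self.income <= hi:
            raise IntegrityError(
                f"{self.participant_id}: income {self.income} outside {lo}..{hi}"
            )


@dataclass
class Dataset:
    """A complete survey: freelists, participant demographics, taxon catalog."""

    freelists: list[Freelist] = field(default_factory=list)
    participants: list[ParticipantRecord] = field(default_factory=list)
    catalog: TaxonCatalog = field(default_factory=lambda: TaxonCatalog([]))

    @property
    def participant_map(self) -> dict[str, ParticipantRecord]:
        return {p.participant_id: p for p in self.participants}

    def freelists_for(self, domain: QuestionDomain) -> list[Freelist]:
        return [fl for fl in self.freelists if fl.question_domain == domain]
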