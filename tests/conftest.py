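import numpy as np
import pytest

from freelist.types import (
    Freelist,
    FreelistItem,
    Gender,
    IndicatorClass,
    ParticipantRecord,
    Provenance,
    QuestionDomain,
    TaxonCatalog,
    TaxonEntry,
    TaxonLevel,
)


def make_freelist(
    pid: str, labels, domain: QuestionDomain = QuestionDomain.BIRD
) -> Freelist:
    return Freelist(
        pid,
        domain,
        tuple(FreelistItem(lbl, i + 1) for i, lbl in enumerate(labels)),
    )


@pytest.fixture(scope="session")
def bird_catalog() -> TaxonCatalog:
    """Crows and friends: a genus with two member species plus an unrelated
    species, with English vernacular synonyms."""
    entries = [
        TaxonEntry("Corvus", TaxonLevel.GENUS, valid=True),
        TaxonEntry(
            "Corvus frugilegus", TaxonLevel.SPECIES, parent="Corvus",
            valid=True, indicator_class=IndicatorClass.FARMLAND_BIRD,
            regional_frequency=3,
        ),
        TaxonEntry("Corvus cornix", TaxonLevel.SPECIES, parent="Corvus", valid=True),
        TaxonEntry("Turdus merula", TaxonLevel.SPECIES, valid=True),
        TaxonEntry(
            "Alauda arvensis", TaxonLevel.SPECIES, valid=True,
            indicator_class=IndicatorClass.FARMLAND_BIRD, regional_frequency=3,
        ),
    ]
    synonyms = {
        "Crows": "Corvus",
        "Rook": "Corvus frugilegus",
        "Hooded crow": "Corvus cornix",
        "Blackbird": "Turdus merula",
        "Skylark": "Alauda arvensis",
    }
    return TaxonCatalog(entries, synonyms)


@pytest.fixture(scope="session")
def plant_catalog() -> TaxonCatalog:
    """Dandelion (three vernacular names), cornflower, and a garden exotic."""
    entries = [
        TaxonEntry("Taraxacum sect. Ruderalia", TaxonLevel.SECTION, valid=True,
                   regional_frequency=3),
        TaxonEntry("Centaurea cyanus", TaxonLevel.SPECIES, valid=True,
                   indicator_class=IndicatorClass.ARABLE_PLANT,
                   regional_frequency=3),
        TaxonEntry("Arrhenatherum elatius", TaxonLevel.SPECIES, valid=True,
                   indicator_class=IndicatorClass.GRASSLAND_PLANT,
                   regional_frequency=2),
        TaxonEntry("Tulipa gesneriana", TaxonLevel.SPECIES, valid=False),
    ]
    synonyms = {
        "Löwenzahn": "Taraxacum sect. Ruderalia",
        "Speckblume": "Taraxacum sect. Ruderalia",
        "Hundeblume": "Taraxacum sect. Ruderalia",
        "Kornblume": "Centaurea cyanus",
        "Tulpe": "Tulipa gesneriana",
    }
    return TaxonCatalog(entries, synonyms)


def random_freelists(
    rng: np.random.Generator,
    n_participants: int,
    pool_size: int = 12,
    max_len: int = 8,
    allow_empty: bool = True,
    domain: QuestionDomain = QuestionDomain.PLANT,
) -> list[Freelist]:
    """Random already-canonical freelists over a synthetic label pool."""
    pool = [f"TX{i:02d}" for i in range(pool_size)]
    lists = []
    for i in range(n_participants):
        lo = 0 if allow_empty else 1
        n = int(rng.integers(lo, min(max_len, pool_size) + 1))
        labels = rng.choice(pool, size=n, replace=False)
        lists.append(make_freelist(f"R{i:03d}", labels, domain))
    return lists


def random_participants(
    rng: np.random.Generator, n: int, prefix: str = "R"
) -> list[ParticipantRecord]:
    return [
        ParticipantRecord(
            participant_id=f"{prefix}{i:03d}",
            gender=Gender.FEMALE if rng.random() < 0.5 else Gender.MALE,
            age_class=int(rng.integers(1, 7)),
            education=int(rng.integers(1, 7)),
            income=int(rng.integers(1, 7)),
        )
        for i in range(n)
    ]
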