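"""Cultural-domain statistics on harmonized freelists.

Smith's S for a taxon averages, over *all* N informants asked the question,
the per-informant contribution

    c_i = (n_i - r_i + 1) / n_i   if informant i listed the taxon at rank r_i
                                  in a list of length n_i,
    c_i = 0                       otherwise (including empty lists),

so a first-mentioned taxon contributes 1 and a last-mentioned taxon 1/n_i.
The *cultural domain* is the set of taxa listed by at least a threshold
share of informants (5% here; 20% marks "general knowledge").  When
higher-order taxa overlap their members (both "crows" and "Rook" above the
threshold), the higher-order taxon can be excluded to avoid double counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .harmonize import AnnotatedFreelist, AnnotatedItem
from .types import (
    Freelist,
    IndicatorClass,
    ParameterError,
    TaxonCatalog,
)

AnyFreelist = Union[Freelist, AnnotatedFreelist]

#: named item filters for list lengths / cumulative counts
FILTERS: dict[str, Callable[[AnnotatedItem], bool]] = {
    "raw": lambda item: True,
    "valid": lambda item: item.valid,
    "grassland_plant": lambda item: item.indicator_class is IndicatorClass.GRASSLAND_PLANT,
    "arable_plant": lambda item: item.indicator_class is IndicatorClass.ARABLE_PLANT,
    "farmland_bird": lambda item: item.indicator_class is IndicatorClass.FARMLAND_BIRD,
    "plant_indicator": lambda item: item.indicator_class
    in (IndicatorClass.GRASSLAND_PLANT, IndicatorClass.ARABLE_PLANT),
    "indicator": lambda item: item.indicator_class is not IndicatorClass.NONE,
}


def _filter_fn(name: str) -> Callable[[AnnotatedItem], bool]:
    try:
        return FILTERS[name]
    except KeyError:
        raise ParameterError(
            f"unknown filter {name!r}; choose from {sorted(FILTERS)}"
        ) from None


def _require_annotated(freelists: Sequence[AnyFreelist], filter: str) -> None:
    if filter != "raw" and any(not isinstance(fl, AnnotatedFreelist) for fl in freelists):
        raise ParameterError(f"filter {filter!r} requires annotated freelists")


def participant_salience(fl: AnyFreelist, taxon: str) -> float:
    """One informant's Smith's-S contribution c_i for a taxon (0 if absent)."""
    for item in fl.items:
        if item.label == taxon:
            return (fl.n - item.rank + 1) / fl.n
    return 0.0


def smiths_s(freelists: Sequence[AnyFreelist], taxon: str) -> float:
    """Smith's salience index: mean of c_i over all informants (see module doc)."""
    if not freelists:
        raise ParameterError("smiths_s needs at least one freelist")
    return sum(participant_salience(fl, taxon) for fl in freelists) / len(freelists)


def frequency_and_rank(
    freelists: Sequence[AnyFreelist], taxon: str
) -> tuple[int, float, float]:
    """(number of listers, relative frequency, mean rank among listers).

    Mean rank is NaN when nobody listed the taxon.
    """
    if not freelists:
        raise ParameterError("frequency_and_rank needs at least one freelist")
    ranks = [
        item.rank for fl in freelists for item in fl.items if item.label == taxon
    ]
    n_listed = len(ranks)
    rel_freq = n_listed / len(freelists)
    mean_rank = float(np.mean(ranks)) if ranks else math.nan
    return n_listed, rel_freq, mean_rank


def salience_table(
    freelists: Sequence[AnyFreelist],
    taxa: Iterable[str] | None = None,
    group: str = "all",
) -> pd.DataFrame:
    """Per-taxon salience table: n_listed, rel_freq, mean_rank, smiths_s, group.

    ``taxa`` defaults to the union of taxa appearing in the lists, ordered by
    decreasing Smith's S.
    """
    if not freelists:
        raise ParameterError("salience_table needs at least one freelist")
    if taxa is None:
        taxa = sorted({item.label for fl in freelists for item in fl.items})
    rows = []
    for taxon in taxa:
        n_listed, rel_freq, mean_rank = frequency_and_rank(freelists, taxon)
        rows.append(
            {
                "taxon": taxon,
                "n_listed": n_listed,
                "rel_freq": rel_freq,
                "mean_rank": mean_rank,
                "smiths_s": smiths_s(freelists, taxon),
                "group": group,
            }
        )
    df = pd.DataFrame(
        rows, columns=["taxon", "n_listed", "rel_freq", "mean_rank", "smiths_s", "group"]
    )
    return df.sort_values("smiths_s", ascending=False, kind="stable").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class DomainResult:
    threshold: float
    include_overlapping_higher: bool
    members: frozenset[str]


def _drop_overlapping_higher(
    members: set[str], catalog: TaxonCatalog
) -> set[str]:
    """Remove taxa that are ancestors of another member (overlap exclusion)."""
    overlapping: set[str] = set()
    for taxon in members:
        if taxon not in catalog:
            continue
        for ancestor in catalog.ancestors(taxon):
            if ancestor.canonical_name in members:
                overlapping.add(ancestor.canonical_name)
    return members - overlapping


def domain_membership(
    table: pd.DataFrame,
    threshold: float,
    include_overlapping_higher: bool,
    catalog: TaxonCatalog,
) -> DomainResult:
    """Taxa whose relative frequency reaches the threshold (>=, exact fraction).

    With ``include_overlapping_higher=False``, higher-order members that have
    a descendant member are removed so knowledge is not double-counted.
    """
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    members = set(table.loc[table["rel_freq"] >= threshold, "taxon"])
    if not include_overlapping_higher:
        members = _drop_overlapping_higher(members, catalog)
    return DomainResult(threshold, include_overlapping_higher, frozenset(members))


def cumulative_taxa(
    freelists: Sequence[AnyFreelist],
    filter: str = "raw",
    exclude_overlapping_higher: bool = True,
    catalog: TaxonCatalog | None = None,
) -> frozenset[str]:
    """Union of distinct taxa listed by anybody, after the item filter.

    With exclusion on (the default, as when compiling a cumulative knowledge
    list), any higher-order taxon that has a descendant in the union is
    dropped; this needs a catalog.
    """
    _require_annotated(freelists, filter)
    keep = _filter_fn(filter)
    union = {
        item.label
        for fl in freelists
        for item in fl.items
        if filter == "raw" or keep(item)  # raw works on plain Freelists too
    }
    if exclude_overlapping_higher:
        if catalog is None:
            raise ParameterError("overlap exclusion requires a catalog")
        union = _drop_overlapping_higher(union, catalog)
    return frozenset(union)


def list_lengths(
    freelists: Sequence[AnyFreelist], filter: str = "raw"
) -> pd.DataFrame:
    """One count per (participant, question domain) after the item filter.

    Inserted higher-order taxa count like listed items (credit rule).
    """
    _require_annotated(freelists, filter)
    keep = _filter_fn(filter)
    rows = [
        {
            "participant_id": fl.participant_id,
            "question_domain": fl.question_domain.value,
            "length": sum(1 for item in fl.items if filter == "raw" or keep(item)),
        }
        for fl in freelists
    ]
    return pd.DataFrame(rows, columns=["participant_id", "question_domain", "length"])


def singleton_share(
    freelists: Sequence[AnyFreelist],
    filter: str = "raw",
    exclude_overlapping_higher: bool = True,
    catalog: TaxonCatalog | None = None,
) -> float:
    """Share of cumulative taxa listed by exactly one participant (NaN if the
    cumulative set is empty)."""
    taxa = cumulative_taxa(freelists, filter, exclude_overlapping_higher, catalog)
    if not taxa:
        return math.nan
    singletons = sum(
        1 for taxon in taxa if frequency_and_rank(freelists, taxon)[0] == 1
    )
    return singletons / len(taxa)
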