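"""CSV readers and writers plus whole-dataset validation.

Three comma-separated UTF-8 formats with headers:

* freelists:      ``participant_id,question_domain,rank,item_label[,provenance]``
* taxon catalog:  ``item_label,canonical_name,level,parent,valid,indicator_class,regional_frequency``
* demographics:   ``participant_id,gender,age_class,education,income``

One catalog row per label; multiple labels (vernacular synonyms) may map to
the same canonical taxon, in which case the taxon's attributes are taken from
the first row and later rows must agree.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    AnnotationError,
    CatalogError,
    Dataset,
    FormatError,
    Freelist,
    FreelistItem,
    Gender,
    IndicatorClass,
    IntegrityError,
    ParticipantRecord,
    Provenance,
    QuestionDomain,
    TaxonCatalog,
    TaxonEntry,
    TaxonLevel,
)

FREELIST_COLUMNS = ["participant_id", "question_domain", "rank", "item_label"]
TAXONOMY_COLUMNS = [
    "item_label",
    "canonical_name",
    "level",
    "parent",
    "valid",
    "indicator_class",
    "regional_frequency",
]
PARTICIPANT_COLUMNS = ["participant_id", "gender", "age_class", "education", "income"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_freelists(
    path: str | Path, catalog: TaxonCatalog | None = None
) -> list[Freelist]:
    """Read a long-format freelist CSV into one :class:`Freelist` per
    (participant, question domain) pair.

    Ranks are validated (consecutive 1..n, no duplicates).  If a catalog is
    given, item labels that do not resolve are reported with a warning but
    kept, so nothing is silently dropped.
    """
    df = _read_csv(path, FREELIST_COLUMNS)
    has_prov = "provenance" in df.columns
    freelists: list[Freelist] = []
    unknown: list[str] = []

    for (pid, domain_str), group in df.groupby(
        ["participant_id", "question_domain"], sort=False
    ):
        try:
            domain = QuestionDomain(domain_str)
        except ValueError:
            raise FormatError(f"{path}: unknown question_domain {domain_str!r}") from None
        try:
            ranks = group["rank"].astype(int)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer rank for {pid!r}") from exc
        if ranks.duplicated().any():
            raise IntegrityError(f"{path}: duplicate rank for ({pid!r}, {domain_str})")
        group = group.assign(rank=ranks).sort_values("rank")
        if list(group["rank"]) != list(range(1, len(group) + 1)):
            raise IntegrityError(
                f"{path}: ranks for ({pid!r}, {domain_str}) are not consecutive 1..n"
            )
        items = []
        for _, row in group.iterrows():
            prov = Provenance(row["provenance"]) if has_prov and row.get("provenance") else Provenance.LISTED
            items.append(FreelistItem(row["item_label"], int(row["rank"]), prov))
            if catalog is not None and catalog.resolve(row["item_label"]) is None:
                unknown.append(row["item_label"])
        freelists.append(Freelist(str(pid), domain, tuple(items)))

    if unknown:
        warnings.warn(
            f"{len(unknown)} item label(s) not resolvable against the catalog: "
            f"{sorted(set(unknown))[:10]}",
            stacklevel=2,
        )
    return freelists


def write_freelists(freelists: Iterable[Freelist], path: str | Path) -> None:
    rows = [
        {
            "participant_id": fl.participant_id,
            "question_domain": fl.question_domain.value,
            "rank": item.rank,
            "item_label": item.label,
            "provenance": item.provenance.value,
        }
        for fl in freelists
        for item in fl.items
    ]
    pd.DataFrame(rows, columns=FREELIST_COLUMNS + ["provenance"]).to_csv(
        path, index=False, encoding="utf-8"
    )


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise FormatError(f"{context}: cannot parse boolean {value!r}")


def read_taxonomy(path: str | Path) -> TaxonCatalog:
    """Read a taxon catalog CSV into a :class:`TaxonCatalog`.

    Raises :class:`CatalogError` on dangling parent references and
    :class:`IntegrityError` on cyclic parent chains or rows that redefine a
    canonical taxon with conflicting attributes.
    """
    df = _read_csv(path, TAXONOMY_COLUMNS)
    entries: dict[str, TaxonEntry] = {}
    synonyms: dict[str, str] = {}
    for _, row in df.iterrows():
        canonical = row["canonical_name"].strip()
        try:
            entry = TaxonEntry(
                canonical_name=canonical,
                level=TaxonLevel(row["level"].strip().lower()),
                parent=row["parent"].strip() or None,
                valid=_parse_bool(row["valid"], canonical),
                indicator_class=IndicatorClass(row["indicator_class"].strip() or "none"),
                regional_frequency=int(row["regional_frequency"] or 0),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad row for {canonical!r}: {exc}") from exc
        if canonical in entries:
            if entries[canonical] != entry:
                raise IntegrityError(
                    f"{path}: conflicting attribute rows for {canonical!r}"
                )
        else:
            entries[canonical] = entry
        synonyms[row["item_label"]] = canonical
    return TaxonCatalog(entries.values(), synonyms)


def write_taxonomy(catalog: TaxonCatalog, path: str | Path) -> None:
    rows = []
    for entry in catalog:
        labels = catalog.synonyms_of(entry.canonical_name)
        # emit the canonical name itself plus every distinct synonym label
        emitted = set()
        for label in (entry.canonical_name, *labels):
            key = label.strip().casefold()
            if key in emitted:
                continue
            emitted.add(key)
            rows.append(
                {
                    "item_label": label,
                    "canonical_name": entry.canonical_name,
                    "level": entry.level.value,
                    "parent": entry.parent or "",
                    "valid": str(entry.valid).lower(),
                    "indicator_class": entry.indicator_class.value,
                    "regional_frequency": entry.regional_frequency,
                }
            )
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    df = _read_csv(path, PARTICIPANT_COLUMNS)
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise IntegrityError(f"{path}: duplicate participant_id {dupes[:5]}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                ParticipantRecord(
                    participant_id=str(row["participant_id"]),
                    gender=Gender(row["gender"].strip().lower()),
                    age_class=int(row["age_class"]),
                    education=int(row["education"]),
                    income=int(row["income"]) if row["income"].strip() else None,
                )
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: bad row for participant {row['participant_id']!r}: {exc}"
            ) from exc
    return records


def write_participants(
    participants: Iterable[ParticipantRecord], path: str | Path
) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "gender": p.gender.value,
            "age_class": p.age_class,
            "education": p.education,
            "income": "" if p.income is None else p.income,
        }
        for p in participants
    ]
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_dataset(
    freelists_path: str | Path,
    taxonomy_path: str | Path,
    participants_path: str | Path,
) -> Dataset:
    """Assemble a full dataset from the three CSVs.

    A participant who listed nothing has no rows in the long-format freelist
    CSV, yet they count in every per-participant denominator (Smith's S,
    relative frequency).  Since the demographics roster names everyone who
    was asked, an empty freelist is restored here for each (participant,
    question domain) pair without rows, for every domain present in the file.
    """
    catalog = read_taxonomy(taxonomy_path)
    freelists = read_freelists(freelists_path, catalog)
    participants = read_participants(participants_path)
    domains = {fl.question_domain for fl in freelists}
    present = {(fl.participant_id, fl.question_domain) for fl in freelists}
    for p in participants:
        for domain in sorted(domains, key=lambda d: d.value):
            if (p.participant_id, domain) not in present:
                freelists.append(Freelist(p.participant_id, domain, ()))
    return Dataset(freelists=freelists, participants=participants, catalog=catalog)


# -- validation ----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Finding:
    kind: str        # orphan_participant | unresolved_item | duplicate_taxon
    subject: str
    message: str


@dataclasses.dataclass
class ValidationReport:
    findings: list[Finding] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"ok": self.ok, "findings": [dataclasses.asdict(f) for f in self.findings]},
            indent=2,
            ensure_ascii=False,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report-only consistency check: orphan freelists, unresolvable items,
    canonical taxa mentioned twice in one list.  Never modifies the dataset."""
    report = ValidationReport()
    known = {p.participant_id for p in ds.participants}
    for fl in ds.freelists:
        if fl.participant_id not in known:
            report.findings.append(
                Finding(
                    "orphan_participant",
                    fl.participant_id,
                    f"freelist for {fl.participant_id!r} has no demographics record",
                )
            )
        seen: dict[str, str] = {}
        for item in fl.items:
            entry = ds.catalog.resolve(item.label)
            if entry is None:
                report.findings.append(
                    Finding(
                        "unresolved_item",
                        item.label,
                        f"label {item.label!r} (participant {fl.participant_id!r}) "
                        f"not in catalog",
                    )
                )
                continue
            if entry.canonical_name in seen:
                report.findings.append(
                    Finding(
                        "duplicate_taxon",
                        entry.canonical_name,
                        f"participant {fl.participant_id!r} mentions "
                        f"{entry.canonical_name!r} more than once "
                        f"({seen[entry.canonical_name]!r}, {item.label!r})",
                    )
                )
            seen.setdefault(entry.canonical_name, item.label)
    return report
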