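"""Synthetic freelist survey generator.

Emulates the statistical structure of a town-square species-knowledge
survey: 463 participants, two question domains (plants, birds), heavy-tailed
taxon popularity (Zipf weights, hence many singletons in the cumulative
list), list lengths 0-35 following a negative-binomial regression on
demographics, and an age-dependent boost of indicator-taxon salience so
that older participants list characteristic farmland species more readily.

Items are drawn without replacement by sequential weighted sampling
(Plackett-Luce, implemented with the Gumbel top-k trick), so rank order
stochastically follows taxon weight — salient items come to mind first,
which is what makes Smith's S meaningful on the synthetic lists.

Labels are systematic (``P-SP001``, ``B-GEN01``...), not imitation
vernacular names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .types import (
    Dataset,
    Freelist,
    FreelistItem,
    Gender,
    IndicatorClass,
    ParameterError,
    ParticipantRecord,
    QuestionDomain,
    TaxonCatalog,
    TaxonEntry,
    TaxonLevel,
)


@dataclass(frozen=True)
class DomainConfig:
    """Taxon pool and list-length law for one question domain.

    The list-length model is NB(mu_i, theta) with

        log mu_i = beta0 + beta_age*(age_i - 3.5) + beta_age2*(age_i - 3.5)^2
                   + beta_edu*(edu_i - 3) + beta_gender*[male_i]

    (age and education as ordinal class codes).  ``gamma`` multiplies
    indicator-taxon weights by exp(gamma * (age - 3.5)), emulating higher
    indicator salience among older participants; gamma = 0 is the null.
    """

    domain: QuestionDomain
    n_species: int = 300
    n_genera: int = 14
    p_parent: float = 0.45          # share of species with a catalog parent genus
    zipf_exponent: float = 1.4
    beta0: float = 1.35
    beta_age: float = 0.12
    beta_age2: float = -0.03
    beta_edu: float = 0.08
    beta_gender: float = 0.0        # positive = males list more
    dispersion: float = 3.0         # NB size theta; variance mu + mu^2/theta
    valid_share: float = 0.85
    indicator_share: float = 0.30   # share of valid species flagged as indicators
    indicator_classes: tuple[IndicatorClass, ...] = (
        IndicatorClass.GRASSLAND_PLANT,
        IndicatorClass.ARABLE_PLANT,
    )
    gamma: float = 0.15
    n_synonym_taxa: int = 3         # taxa given an extra vernacular label

    @property
    def pool_size(self) -> int:
        return self.n_species + self.n_genera


def default_domains() -> tuple[DomainConfig, DomainConfig]:
    plants = DomainConfig(QuestionDomain.PLANT)
    birds = DomainConfig(
        QuestionDomain.BIRD,
        n_species=200,
        n_genera=18,
        p_parent=0.55,
        zipf_exponent=1.6,
        beta0=1.85,
        beta_gender=0.12,
        indicator_classes=(IndicatorClass.FARMLAND_BIRD,),
    )
    return plants, birds


@dataclass(frozen=True)
class SynthConfig:
    """Whole-survey configuration; the defaults mirror the study conditions."""

    n_participants: int = 463
    domains: tuple[DomainConfig, ...] = field(default_factory=default_domains)
    age_probs: tuple[float, ...] = (0.10, 0.12, 0.15, 0.19, 0.19, 0.25)
    p_female: float = 0.607
    education_probs: tuple[float, ...] = (0.06, 0.16, 0.28, 0.24, 0.16, 0.10)
    income_probs: tuple[float, ...] = (0.10, 0.18, 0.24, 0.22, 0.16, 0.10)
    p_income_missing: float = 0.013
    seed: int = 0

    def validate(self) -> None:
        for probs in (self.age_probs, self.education_probs, self.income_probs):
            if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
                raise ParameterError("marginal probabilities must be >= 0 and sum to 1")
        if not 0 <= self.p_female <= 1 or not 0 <= self.p_income_missing <= 1:
            raise ParameterError("probabilities must lie in [0, 1]")
        if self.n_participants < 1:
            raise ParameterError("need at least one participant")
        for dc in self.domains:
            if dc.dispersion <= 0:
                raise ParameterError(f"{dc.domain.value}: dispersion must be > 0")
            if dc.n_species < 1 or dc.n_genera < 0:
                raise ParameterError(f"{dc.domain.value}: empty taxon pool")
            if not 0 <= dc.p_parent <= 1:
                raise ParameterError(f"{dc.domain.value}: p_parent outside [0, 1]")


def _domain_prefix(domain: QuestionDomain) -> str:
    return "P" if domain is QuestionDomain.PLANT else "B"


def _build_pool(
    dc: DomainConfig, rng: np.random.Generator
) -> tuple[list[TaxonEntry], dict[str, str], np.ndarray, list[str]]:
    """Catalog entries, synonym labels, base Zipf weights, and pool names."""
    prefix = _domain_prefix(dc.domain)
    genus_names = [f"{prefix}-GEN{g + 1:02d}" for g in range(dc.n_genera)]
    species_names = [f"{prefix}-SP{s + 1:03d}" for s in range(dc.n_species)]

    entries: list[TaxonEntry] = []
    for name in genus_names:
        entries.append(
            TaxonEntry(name, TaxonLevel.GENUS, parent=None, valid=True,
                       indicator_class=IndicatorClass.NONE,
                       regional_frequency=int(rng.integers(1, 4)))
        )
    species_entries: list[TaxonEntry] = []
    for name in species_names:
        parent = (
            genus_names[int(rng.integers(dc.n_genera))]
            if dc.n_genera > 0 and rng.random() < dc.p_parent
            else None
        )
        valid = bool(rng.random() < dc.valid_share)
        indicator = (
            dc.indicator_classes[int(rng.integers(len(dc.indicator_classes)))]
            if valid and rng.random() < dc.indicator_share
            else IndicatorClass.NONE
        )
        freq = (
            int(rng.integers(2, 4))
            if indicator is not IndicatorClass.NONE
            else int(rng.integers(0, 4))
        )
        species_entries.append(
            TaxonEntry(name, TaxonLevel.SPECIES, parent=parent, valid=valid,
                       indicator_class=indicator, regional_frequency=freq)
        )
    entries.extend(species_entries)

    pool = genus_names + species_names
    # Zipf popularity over a random ordering, so genera mix into all tiers
    order = rng.permutation(len(pool))
    ranks = np.empty(len(pool), dtype=int)
    ranks[order] = np.arange(1, len(pool) + 1)
    weights = ranks.astype(float) ** (-dc.zipf_exponent)

    synonyms: dict[str, str] = {}
    for name in rng.choice(species_names, size=min(dc.n_synonym_taxa, len(species_names)), replace=False):
        synonyms[f"{name}-ALT"] = str(name)
    return entries, synonyms, weights, pool


def _draw_demographics(
    cfg: SynthConfig, rng: np.random.Generator
) -> list[ParticipantRecord]:
    n = cfg.n_participants
    ages = rng.choice(np.arange(1, 7), size=n, p=cfg.age_probs)
    genders = np.where(rng.random(n) < cfg.p_female, "female", "male")
    edus = rng.choice(np.arange(1, 7), size=n, p=cfg.education_probs)
    incomes = rng.choice(np.arange(1, 7), size=n, p=cfg.income_probs)
    missing = rng.random(n) < cfg.p_income_missing
    return [
        ParticipantRecord(
            participant_id=f"ID{i + 1:04d}",
            gender=Gender(genders[i]),
            age_class=int(ages[i]),
            education=int(edus[i]),
            income=None if missing[i] else int(incomes[i]),
        )
        for i in range(n)
    ]


def expected_log_mu(dc: DomainConfig, p: ParticipantRecord) -> float:
    a = p.age_class - 3.5
    return (
        dc.beta0
        + dc.beta_age * a
        + dc.beta_age2 * a * a
        + dc.beta_edu * (p.education - 3)
        + dc.beta_gender * (1.0 if p.gender is Gender.MALE else 0.0)
    )


def generate(config: SynthConfig) -> tuple[Dataset, dict[str, Any]]:
    """Generate a full synthetic survey plus its ground truth.

    Per participant and domain a list length is drawn from the NB model
    (truncated at the pool size), then that many items are sampled without
    replacement with probability proportional to taxon weight times the
    age-dependent indicator multiplier; sampling order becomes rank.
    Deterministic given the config (which includes the seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants = _draw_demographics(config, rng)

    all_entries: list[TaxonEntry] = []
    all_synonyms: dict[str, str] = {}
    freelists: list[Freelist] = []
    truth: dict[str, Any] = {"seed": config.seed, "domains": {}}

    for dc in config.domains:
        entries, synonyms, weights, pool = _build_pool(dc, rng)
        all_entries.extend(entries)
        all_synonyms.update(synonyms)
        indicator_mask = np.array(
            [e.indicator_class is not IndicatorClass.NONE for e in entries]
        )
        # entries order = genus_names + species_names = pool order
        name_to_labels: dict[str, list[str]] = {name: [name] for name in pool}
        for alt, canonical in synonyms.items():
            name_to_labels[canonical].append(alt)

        log_w_base = np.log(weights)
        # one weight vector per age class (indicator boost scales with age)
        log_w_by_age = {
            a: log_w_base + np.where(indicator_mask, dc.gamma * (a - 3.5), 0.0)
            for a in range(1, 7)
        }

        mus = np.array([np.exp(expected_log_mu(dc, p)) for p in participants])
        theta = dc.dispersion
        lengths = rng.negative_binomial(theta, theta / (theta + mus))
        lengths = np.minimum(lengths, dc.pool_size)  # truncate at the pool

        for p, n_items in zip(participants, lengths):
            if n_items == 0:
                freelists.append(Freelist(p.participant_id, dc.domain, ()))
                continue
            gumbel = rng.gumbel(size=dc.pool_size)
            keys = log_w_by_age[p.age_class] + gumbel
            top = np.argpartition(-keys, n_items - 1)[:n_items]
            top = top[np.argsort(-keys[top])]
            items = []
            for rank, idx in enumerate(top, start=1):
                labels = name_to_labels[pool[idx]]
                label = labels[int(rng.integers(len(labels)))] if len(labels) > 1 else labels[0]
                items.append(FreelistItem(label, rank))
            freelists.append(Freelist(p.participant_id, dc.domain, tuple(items)))

        truth["domains"][dc.domain.value] = {
            "coefficients": {
                "beta0": dc.beta0,
                "beta_age": dc.beta_age,
                "beta_age2": dc.beta_age2,
                "beta_edu": dc.beta_edu,
                "beta_gender": dc.beta_gender,
            },
            "dispersion": dc.dispersion,
            "gamma": dc.gamma,
            "zipf_exponent": dc.zipf_exponent,
            "weights": {name: float(w) for name, w in zip(pool, weights)},
            "indicator_taxa": sorted(
                e.canonical_name for e in entries
                if e.indicator_class is not IndicatorClass.NONE
            ),
        }

    catalog = TaxonCatalog(all_entries, all_synonyms)
    dataset = Dataset(freelists=freelists, participants=participants, catalog=catalog)
    return dataset, truth


def write_truth(truth: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2), encoding="utf-8")


def config_to_dict(config: SynthConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


# -- end-to-end recovery checks -----------------------------------------


def recovery_suite(
    config: SynthConfig,
    n_perm: int = 2000,
    alpha_level: float = 0.05,
) -> dict[str, Any]:
    """Generate data from a config with known effects and check that the
    pipeline recovers them.

    Checks, per domain: (i) the NB list-length coefficients lie inside their
    95% CIs; (ii) AIC effect-type selection for age picks the generating
    type (linear vs smooth); (iii) with gamma > 0 the most salient boosted
    indicator taxon shows a significant old-vs-young salience difference in
    the expected direction.  Returns a report with pass/fail per check.
    """
    from .compare import AgeSplit, salience_randomization_test
    from .harmonize import harmonize_dataset
    from .models import EffectSpec, EffectType, fit_nb, select_effect_type
    from .salience import salience_table

    ds, truth = generate(config)
    harmonized = harmonize_dataset(ds)
    frame = participant_frame(ds)
    checks: list[dict[str, Any]] = []

    for dc in config.domains:
        dom = dc.domain.value
        raw = {
            fl.participant_id: fl.n for fl in ds.freelists_for(dc.domain)
        }
        data = frame.assign(length=[raw[p.participant_id] for p in ds.participants])
        data["age_c"] = data["age"] - 3.5
        data["edu_c"] = data["education"] - 3

        gen_type = EffectType.LINEAR if dc.beta_age2 == 0 else EffectType.SMOOTH
        age_term = EffectSpec("age_c", gen_type).terms()
        terms = age_term + EffectSpec("edu_c", EffectType.LINEAR).terms()
        fit = fit_nb(data, "length", terms, term_tests=False)
        ci = fit.conf_int()
        if gen_type is EffectType.LINEAR:
            ok_age = ci.loc["age_c", "lower"] <= dc.beta_age <= ci.loc["age_c", "upper"]
            checks.append(
                {"name": f"{dom}:age_coefficient_in_ci", "passed": bool(ok_age),
                 "detail": f"true={dc.beta_age}, ci=({ci.loc['age_c', 'lower']:.3f}, "
                           f"{ci.loc['age_c', 'upper']:.3f})"}
            )
        ok_edu = ci.loc["edu_c", "lower"] <= dc.beta_edu <= ci.loc["edu_c", "upper"]
        checks.append(
            {"name": f"{dom}:education_coefficient_in_ci", "passed": bool(ok_edu),
             "detail": f"true={dc.beta_edu}, ci=({ci.loc['edu_c', 'lower']:.3f}, "
                       f"{ci.loc['edu_c', 'upper']:.3f})"}
        )

        selected = select_effect_type(data, "length", "age_c", include_gender=False)
        checks.append(
            {"name": f"{dom}:age_effect_type_selected", "passed": selected.effect_type is gen_type,
             "detail": f"selected {selected.effect_type.value}, generating {gen_type.value}"}
        )

        if dc.gamma > 0:
            lists = [fl for fl in harmonized if fl.question_domain is dc.domain]
            table = salience_table(lists)
            boosted = truth["domains"][dom]["indicator_taxa"]
            top = table[table["taxon"].isin(boosted)].head(1)
            if not top.empty:
                taxon = top["taxon"].iloc[0]
                res = salience_randomization_test(
                    lists, ds.participants, taxon, AgeSplit(),
                    n_perm=n_perm, seed=config.seed + 1,
                )
                checks.append(
                    {"name": f"{dom}:boosted_taxon_older_salience",
                     "passed": bool(res.p_value < alpha_level and res.observed_diff > 0),
                     "detail": f"taxon={taxon}, diff={res.observed_diff:.4f}, "
                               f"p={res.p_value:.4f}"}
                )

    return {"n_checks": len(checks), "n_passed": sum(c["passed"] for c in checks),
            "checks": checks}


def participant_frame(ds: Dataset) -> "pd.DataFrame":
    """Demographics as a model-ready DataFrame (age/education/income as
    ordinal codes, income NaN when missing)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in ds.participants],
            "gender": [p.gender.value for p in ds.participants],
            "age": [p.age_class for p in ds.participants],
            "education": [p.education for p in ds.participants],
            "income": [np.nan if p.income is None else p.income for p in ds.participants],
        }
    )
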