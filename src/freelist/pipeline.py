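"""End-to-end pipeline: data in (or synthesized), full report bundle out.

Stages: read/generate -> validate -> harmonize -> cultural-domain statistics
-> age-group salience comparison -> list-length models -> binomial mixed
model of indicator frequency by age.  Every stage writes its table under the
output directory; all randomness flows through the single seed in the
config, so identical config implies an identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .compare import (
    AgeSplit,
    group_salience,
    indicator_frequency_by_age,
    salience_randomization_tests,
)
from .harmonize import harmonize_dataset
from .io import read_dataset, validate_dataset, write_freelists
from .models import (
    EffectSpec,
    backward_select,
    fit_binomial_glmm,
    merge_terms,
    model_table,
    select_effect_type,
)
from .salience import (
    cumulative_taxa,
    domain_membership,
    list_lengths,
    salience_table,
    singleton_share,
)
from .synth import SynthConfig, generate, participant_frame, write_truth
from .types import (
    Dataset,
    FreelistError,
    IndicatorClass,
    ParameterError,
    QuestionDomain,
)

log = logging.getLogger("freelist")

#: list-length responses per domain: filter name keyed by response label
DOMAIN_RESPONSES: dict[QuestionDomain, dict[str, str]] = {
    QuestionDomain.PLANT: {"raw": "raw", "valid": "valid", "indicator": "plant_indicator"},
    QuestionDomain.BIRD: {"raw": "raw", "valid": "valid", "indicator": "farmland_bird"},
}


@dataclass
class RunConfig:
    freelists: str | None = None
    taxonomy: str | None = None
    participants: str | None = None
    synth: bool = False
    synth_config: SynthConfig | None = None
    domain_threshold: float = 0.05
    general_threshold: float = 0.20
    age_split: AgeSplit = field(default_factory=AgeSplit)
    n_perm: int = 10_000
    seed: int = 0
    outdir: str = "results/run"
    make_plots: bool = True

    def validate(self) -> None:
        for t in (self.domain_threshold, self.general_threshold):
            if not 0 < t <= 1:
                raise ParameterError(f"threshold {t} outside (0, 1]")
        if not self.synth:
            missing = [
                name
                for name, path in [
                    ("freelists", self.freelists),
                    ("taxonomy", self.taxonomy),
                    ("participants", self.participants),
                ]
                if path is None or not Path(path).exists()
            ]
            if missing:
                raise ParameterError(f"missing input path(s): {missing}")


def _load(cfg: RunConfig, outdir: Path) -> Dataset:
    if cfg.synth:
        synth_cfg = cfg.synth_config or SynthConfig(seed=cfg.seed)
        if synth_cfg.seed != cfg.seed:
            synth_cfg = dataclasses.replace(synth_cfg, seed=cfg.seed)
        ds, truth = generate(synth_cfg)
        data_dir = outdir / "data"
        data_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_participants, write_taxonomy

        write_freelists(ds.freelists, data_dir / "freelists.csv")
        write_taxonomy(ds.catalog, data_dir / "taxonomy.csv")
        write_participants(ds.participants, data_dir / "participants.csv")
        write_truth(truth, data_dir / "truth.json")
        return ds
    assert cfg.freelists and cfg.taxonomy and cfg.participants
    return read_dataset(cfg.freelists, cfg.taxonomy, cfg.participants)


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage and write the artifact bundle; returns a result map."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}

    stage = "load"
    try:
        ds = _load(cfg, outdir)
        log.info("loaded %d freelists, %d participants, %d catalog entries",
                 len(ds.freelists), len(ds.participants), len(ds.catalog))

        stage = "validate"
        report = validate_dataset(ds)
        report.to_json(outdir / "validation.json")
        if not report.ok:
            log.warning("validation produced %d finding(s)", len(report.findings))

        stage = "harmonize"
        harmonized = harmonize_dataset(ds)
        write_freelists(
            [hf for hf in _as_freelists(harmonized)], outdir / "harmonized.csv"
        )

        frame = participant_frame(ds)
        summary_rows = []
        for domain in QuestionDomain:
            lists = [fl for fl in harmonized if fl.question_domain is domain]
            if not lists:
                continue
            tag = domain.value

            stage = f"salience:{tag}"
            table = salience_table(lists)
            _tsv(table, outdir / f"salience_{tag}.tsv")

            domain_sets = {}
            for label, threshold in [
                ("domain", cfg.domain_threshold),
                ("general", cfg.general_threshold),
            ]:
                for overlap in (True, False):
                    res = domain_membership(table, threshold, overlap, ds.catalog)
                    key = f"{label}{'_with_higher' if overlap else ''}"
                    domain_sets[key] = sorted(res.members)
            (outdir / f"domain_{tag}.json").write_text(
                json.dumps(domain_sets, indent=2), encoding="utf-8"
            )

            cumulative = cumulative_taxa(lists, "raw", True, ds.catalog)
            singles = singleton_share(lists, "raw", True, ds.catalog)
            lengths = {
                resp: list_lengths(lists, filt)["length"]
                for resp, filt in DOMAIN_RESPONSES[domain].items()
            }
            summary_rows.append(
                {
                    "question_domain": tag,
                    "n_lists": len(lists),
                    "cumulative_taxa": len(cumulative),
                    "singleton_share": singles,
                    "n_domain": len(domain_sets["domain"]),
                    "n_domain_with_higher": len(domain_sets["domain_with_higher"]),
                    "n_general": len(domain_sets["general"]),
                    "mean_length_raw": float(lengths["raw"].mean()),
                    "mean_length_valid": float(lengths["valid"].mean()),
                    "mean_length_indicator": float(lengths["indicator"].mean()),
                }
            )

            stage = f"compare:{tag}"
            young, old = group_salience(lists, ds.participants, cfg.age_split)
            _tsv(pd.concat([young, old]), outdir / f"salience_by_group_{tag}.tsv")
            domain_taxa = domain_sets["domain_with_higher"]
            tests = salience_randomization_tests(
                lists, ds.participants, domain_taxa, cfg.age_split,
                n_perm=cfg.n_perm, seed=cfg.seed,
            )
            _tsv(tests, outdir / f"randtests_{tag}.tsv")
            results[f"randtests_{tag}"] = tests

            stage = f"age_frequency:{tag}"
            indicator_domain = [
                t
                for t in domain_taxa
                if t in ds.catalog
                and ds.catalog[t].indicator_class is not IndicatorClass.NONE
            ]
            glmm_summary: dict[str, Any] = {"n_indicator_taxa": len(indicator_domain)}
            freq_table = None
            if indicator_domain:
                freq_table = indicator_frequency_by_age(
                    lists, ds.participants, indicator_domain
                )
                _tsv(freq_table, outdir / f"age_frequency_{tag}.tsv")
            fitted = None
            if len(indicator_domain) >= 2:
                glmm = fit_binomial_glmm(freq_table)
                fitted = glmm.fitted
                glmm_summary.update(
                    lr_stat=round(glmm.lr_stat, 2), lr_df=glmm.lr_df,
                    lr_p=glmm.lr_p, sigma=round(glmm.sigma, 4),
                    converged=glmm.converged,
                )
                results[f"glmm_{tag}"] = glmm
            else:
                log.warning("%s: fewer than 2 indicator taxa in the domain; "
                            "mixed model skipped", tag)
            (outdir / f"glmm_{tag}.json").write_text(
                json.dumps(glmm_summary, indent=2), encoding="utf-8"
            )

            stage = f"models:{tag}"
            model_rows = []
            for resp_label, filt in DOMAIN_RESPONSES[domain].items():
                lengths_df = list_lengths(lists, filt)
                data = frame.merge(
                    lengths_df.rename(columns={"length": "y"}), on="participant_id"
                )
                specs = [
                    select_effect_type(data, "y", pred) for pred in
                    ("age", "education", "income")
                ]
                terms = merge_terms(specs, include_gender=True)
                final = backward_select(data, "y", terms)
                model_rows.append(model_table(final, f"{tag}.{resp_label}"))
                results[f"model_{tag}_{resp_label}"] = final
            models_df = pd.concat(model_rows, ignore_index=True)
            _tsv(models_df, outdir / f"models_{tag}.tsv")

            if cfg.make_plots:
                stage = f"plots:{tag}"
                from .plots import age_frequency_lines, salience_diff_bars, salience_scatter

                figdir = outdir / "figures"
                figdir.mkdir(exist_ok=True)
                salience_scatter(
                    table[table["taxon"].isin(domain_taxa)],
                    figdir / f"salience_{tag}.png",
                    title=f"{tag}: cultural-domain taxa",
                )
                salience_diff_bars(
                    tests, figdir / f"salience_diff_{tag}.png",
                    title=f"{tag}: older vs younger salience",
                )
                if freq_table is not None:
                    age_frequency_lines(
                        freq_table, figdir / f"age_frequency_{tag}.png",
                        fitted=fitted, title=f"{tag}: indicator frequency by age",
                    )

        summary = pd.DataFrame(summary_rows)
        _tsv(summary, outdir / "summary.tsv")
        results["summary"] = summary

        run_log = {
            "seed": cfg.seed,
            "n_perm": cfg.n_perm,
            "domain_threshold": cfg.domain_threshold,
            "general_threshold": cfg.general_threshold,
            "package_version": __version__,
            "python": platform.python_version(),
            "synth": cfg.synth,
        }
        (outdir / "run.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")
        return results
    except FreelistError:
        log.exception("pipeline stage %r failed", stage)
        raise


def _as_freelists(harmonized):
    """Adapt annotated freelists to the writer's plain-freelist interface."""
    from .types import Freelist, FreelistItem

    for hf in harmonized:
        yield Freelist(
            hf.participant_id,
            hf.question_domain,
            tuple(
                FreelistItem(item.label, item.rank, item.provenance)
                for item in hf.items
            ),
        )
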