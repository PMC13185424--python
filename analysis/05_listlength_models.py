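#!/usr/bin/env python
"""List-length regression ledger.

For each question domain and response (raw, valid, indicator list length):
pick each demographic predictor's effect type by AIC on univariate NB fits,
combine them with the gender main effect, prune by backward elimination
(likelihood-ratio chi-square, 5% level), and tabulate the surviving terms
with their chi-square, p, deviance explained, and n.
"""

import argparse
from pathlib import Path

import pandas as pd

from freelist.harmonize import harmonize_dataset
from freelist.io import read_dataset
from freelist.models import backward_select, merge_terms, model_table, select_effect_type
from freelist.pipeline import DOMAIN_RESPONSES
from freelist.salience import list_lengths
from freelist.synth import participant_frame
from freelist.types import QuestionDomain


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    ds = read_dataset(
        args.datadir / "freelists.csv",
        args.datadir / "taxonomy.csv",
        args.datadir / "participants.csv",
    )
    harmonized = harmonize_dataset(ds)
    frame = participant_frame(ds)
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for domain in QuestionDomain:
        lists = [fl for fl in harmonized if fl.question_domain is domain]
        for resp_label, filt in DOMAIN_RESPONSES[domain].items():
            lengths = list_lengths(lists, filt).rename(columns={"length": "y"})
            data = frame.merge(lengths, on="participant_id")
            specs = [
                select_effect_type(data, "y", pred)
                for pred in ("age", "education", "income")
            ]
            chosen = ", ".join(f"{s.predictor}:{s.effect_type.value}" for s in specs)
            final = backward_select(data, "y", merge_terms(specs, include_gender=True))
            name = f"{domain.value}.{resp_label}"
            kept = ", ".join(t.name for t in final.terms) or "(intercept only)"
            print(f"{name}: effect types [{chosen}] -> kept [{kept}], "
                  f"dev.expl {final.deviance_explained:.1f}%, n={final.n}")
            rows.append(model_table(final, name))

    ledger = pd.concat(rows, ignore_index=True)
    ledger.to_csv(args.outdir / "listlength_models.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir / 'listlength_models.tsv'}")


if __name__ == "__main__":
    main()
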