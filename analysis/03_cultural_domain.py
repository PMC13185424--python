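#!/usr/bin/env python
"""Cultural-domain statistics: cumulative knowledge, salience, domain sizes.

Per question domain: cumulative taxon count and singleton share, Smith's S
salience table, cultural-domain membership at the 5% frequency threshold
and general knowledge at 20%, plus a mean-rank vs frequency scatter.
"""

import argparse
import json
from pathlib import Path

from freelist.harmonize import harmonize_dataset
from freelist.io import read_dataset
from freelist.plots import salience_scatter
from freelist.salience import (
    cumulative_taxa,
    domain_membership,
    list_lengths,
    salience_table,
    singleton_share,
)
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
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "figures").mkdir(exist_ok=True)

    for domain in QuestionDomain:
        lists = [fl for fl in harmonized if fl.question_domain is domain]
        tag = domain.value
        cumulative = cumulative_taxa(lists, "raw", True, ds.catalog)
        singles = singleton_share(lists, "raw", True, ds.catalog)
        table = salience_table(lists)
        table.to_csv(args.outdir / f"salience_{tag}.tsv", sep="\t", index=False)

        domain_set = domain_membership(table, 0.05, False, ds.catalog)
        domain_higher = domain_membership(table, 0.05, True, ds.catalog)
        general = domain_membership(table, 0.20, False, ds.catalog)
        (args.outdir / f"domain_{tag}.json").write_text(
            json.dumps(
                {
                    "domain": sorted(domain_set.members),
                    "domain_with_higher": sorted(domain_higher.members),
                    "general": sorted(general.members),
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        mean_raw = list_lengths(lists, "raw")["length"].mean()
        print(
            f"{tag}: {len(cumulative)} cumulative taxa "
            f"({100 * singles:.0f}% singletons); mean list length {mean_raw:.1f}; "
            f"cultural domain {len(domain_set.members)} taxa "
            f"({len(domain_higher.members)} counting overlapping higher-order); "
            f"general knowledge {len(general.members)} taxa"
        )
        salience_scatter(
            table[table["taxon"].isin(domain_higher.members)],
            args.outdir / "figures" / f"salience_{tag}.png",
            title=f"{tag}: cultural-domain taxa",
        )


if __name__ == "__main__":
    main()
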