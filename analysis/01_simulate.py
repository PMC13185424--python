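#!/usr/bin/env python
"""Generate the synthetic survey the downstream analyses run on.

Emulates a two-town street-intercept survey: 463 participants freelist the
wild plants and the birds of their surrounding agricultural landscape.
Writes the three canonical CSVs plus the generator's ground truth under
results/data/.
"""

import argparse
from pathlib import Path

from freelist.io import write_freelists, write_participants, write_taxonomy
from freelist.synth import SynthConfig, generate, write_truth
from freelist.types import QuestionDomain


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    cfg = SynthConfig(seed=args.seed)
    ds, truth = generate(cfg)

    args.outdir.mkdir(parents=True, exist_ok=True)
    write_freelists(ds.freelists, args.outdir / "freelists.csv")
    write_taxonomy(ds.catalog, args.outdir / "taxonomy.csv")
    write_participants(ds.participants, args.outdir / "participants.csv")
    write_truth(truth, args.outdir / "truth.json")

    print(f"seed {args.seed}: {len(ds.participants)} participants, "
          f"{len(ds.catalog)} catalog entries")
    for domain in QuestionDomain:
        lists = ds.freelists_for(domain)
        lengths = [fl.n for fl in lists]
        print(f"  {domain.value}: {len(lists)} freelists, raw lengths "
              f"{min(lengths)}-{max(lengths)}, mean {sum(lengths)/len(lengths):.1f}")
    print(f"wrote CSVs and ground truth to {args.outdir}")


if __name__ == "__main__":
    main()
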