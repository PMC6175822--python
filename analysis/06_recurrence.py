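#!/usr/bin/env python
"""Genes recurrently deregulated across trisomies and monosomies.

Restricts to aneuploidies with >= 100 DE genes, computes per-gene fractions
of eligible contrasts in which the gene is up / down / unchanged, selects
genes changing in >= 60% of a class, and intersects the classes into the
pan-aneuploidy up- and down-regulated sets.

Writes results/recurrence.tsv, results/genes_*.txt and
results/recurrence_summary.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ploidyseq import (
    common_across_classes,
    eligible_aneuploidies,
    frequently_deregulated,
    recurrence_fractions,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--de-dir", type=Path, default=Path("scratch/de"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-de", type=int, default=100)
    ap.add_argument("--threshold", type=float, default=0.60)
    args = ap.parse_args()

    contrasts = {
        p.stem.replace("_", " "): pd.read_csv(p, sep="\t", index_col=0)
        for p in sorted(args.de_dir.glob("*.tsv"))
    }
    eligible = eligible_aneuploidies(contrasts, min_de=args.min_de)
    table = recurrence_fractions(contrasts, eligible)
    table.to_csv(args.results / "recurrence.tsv", sep="\t")
    sets = frequently_deregulated(table, threshold=args.threshold)
    common = common_across_classes(sets)

    for name, genes in {**sets, **common}.items():
        (args.results / f"genes_{name}.txt").write_text(
            "\n".join(sorted(genes)) + ("\n" if genes else "")
        )
    summary = {
        "n_eligible": {c: len(v) for c, v in eligible.items()},
        "set_sizes": {k: len(v) for k, v in {**sets, **common}.items()},
        "common_up": sorted(common["common_up"]),
        "common_down": sorted(common["common_down"]),
    }
    with open(args.results / "recurrence_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(
        f"eligible: {len(eligible['trisomy'])} trisomies, "
        f"{len(eligible['monosomy'])} monosomies (>= {args.min_de} DE genes)"
    )
    print(
        f"recurrently deregulated in >= {args.threshold:.0%} of both classes: "
        f"{len(common['common_up'])} up, {len(common['common_down'])} down"
    )
    print("common up:", ", ".join(sorted(common["common_up"])))
    print("common down:", ", ".join(sorted(common["common_down"])))


if __name__ == "__main__":
    main()
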