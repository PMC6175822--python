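#!/usr/bin/env python
"""Chromosome-normalized dosage summaries across aneuploidies.

Builds the up- and down-direction bubble matrices (DE counts normalized by
chromosome gene content and per-aneuploidy DE totals), ranks aneuploidies
by total DE genes, and quantifies the dosage diagonal: the fraction of
trisomies whose gained chromosome carries the row-maximal up-signal, and of
monosomies whose lost chromosome carries the row-maximal down-signal.

Writes results/bubble_*.tsv, results/aneuploidy_ranking.tsv and
results/diagonal_dominance.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ploidyseq import bubble_matrix, diagonal_dominance, rank_aneuploidies
from ploidyseq.recurrence import contrast_class
from ploidyseq.simulate import parse_karyotype_label


def load_contrasts(de_dir: Path) -> dict[str, pd.DataFrame]:
    out = {}
    for path in sorted(de_dir.glob("*.tsv")):
        label = path.stem.replace("_", " ")
        out[label] = pd.read_csv(path, sep="\t", index_col=0)
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--de-dir", type=Path, default=Path("scratch/de"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    annotation = pd.read_csv(args.cohort_dir / "annotation.tsv", sep="\t")
    annotation["chrom"] = annotation["chrom"].astype(str)
    contrasts = load_contrasts(args.de_dir)

    ranking = rank_aneuploidies(contrasts)
    ranking.to_csv(args.results / "aneuploidy_ranking.tsv", sep="\t", index=False)

    label_chrom = {}
    for label in contrasts:
        copy_map, _ = parse_karyotype_label(label)
        if len(copy_map) == 1:
            label_chrom[label] = next(iter(copy_map))

    dominance = {}
    for direction, cls in (("up", "trisomy"), ("down", "monosomy")):
        subset = {
            lab: t for lab, t in contrasts.items()
            if contrast_class(lab) == cls and lab in label_chrom
        }
        matrix = bubble_matrix(subset, annotation, direction)
        matrix.to_csv(args.results / f"bubble_{cls}_{direction}.tsv", sep="\t")
        dominance[f"{cls}_{direction}"] = diagonal_dominance(matrix, label_chrom)
        # the opposite direction is the negative control: no diagonal
        control = bubble_matrix(
            subset, annotation, "down" if direction == "up" else "up"
        )
        dominance[f"{cls}_{'down' if direction == 'up' else 'up'}_control"] = (
            diagonal_dominance(control, label_chrom)
        )

    with open(args.results / "diagonal_dominance.json", "w") as fh:
        json.dump(dominance, fh, indent=2)
    print("top of the ranking:")
    print(ranking.head(5).to_string(index=False))
    print("diagonal dominance (own-chromosome row maxima):")
    print(json.dumps(dominance, indent=2))


if __name__ == "__main__":
    main()
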