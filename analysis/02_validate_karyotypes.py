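#!/usr/bin/env python
"""Validate each embryo's karyotype from its RNA-seq variants.

For every embryo: read its VCF, keep high-confidence variants (depth >= 50,
quality >= 500), build per-chromosome allele-fraction densities, call each
chromosome haploid/diploid/triploid from the peak template, combine the X
call with Y-transcript presence into a sex call, and compare with the
screening label.  Mosaic embryos surface as indeterminate chromosomes and
are excluded from everything downstream.

Writes results/validation.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ploidyseq import (
    call_karyotype,
    classify_ploidy,
    compute_fpkm,
    detect_y_expression,
    detect_vaf_peaks,
    filter_high_confidence,
    group_vafs_by_chromosome,
    read_vcf,
    validate_against_label,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = pd.read_csv(args.cohort_dir / "counts.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(args.cohort_dir / "annotation.tsv", sep="\t")
    annotation["chrom"] = annotation["chrom"].astype(str)
    metadata = pd.read_csv(args.cohort_dir / "metadata.tsv", sep="\t")
    fpkm = compute_fpkm(counts, annotation)
    autosomes = tuple(c for c in pd.unique(annotation["chrom"]) if c not in ("X", "Y"))

    rows = []
    for rec in metadata.itertuples(index=False):
        variants = filter_high_confidence(
            read_vcf(args.cohort_dir / "vcf" / f"{rec.sample_id}.vcf")
        )
        calls = {}
        for vafset in group_vafs_by_chromosome(variants):
            if vafset.chrom == "Y":
                continue
            calls[vafset.chrom] = classify_ploidy(detect_vaf_peaks(vafset))
        y_expr = detect_y_expression(fpkm, annotation, rec.sample_id)
        kcall = call_karyotype(calls, y_expressed=y_expr, autosomes=autosomes)
        status = validate_against_label(kcall, rec.label)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "label": rec.label,
                "truly_mosaic": rec.mosaic,
                "sex_call": kcall.sex_call,
                "status": status,
            }
        )

    out = pd.DataFrame(rows)
    args.results.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.results / "validation.tsv", sep="\t", index=False)
    n_val = int((out["status"] == "validated").sum())
    print(f"validated {n_val}/{len(out)} embryos")
    print(out["status"].value_counts().to_string())
    caught = out.loc[out["truly_mosaic"], "status"].eq(
        "excluded_mosaic_or_indeterminate"
    )
    print(f"mosaics excluded: {int(caught.sum())}/{len(caught)}")


if __name__ == "__main__":
    main()
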