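#!/usr/bin/env python
"""Simulate the study-like embryo cohort.

Generates a cohort shaped like the real one — a handful of euploid
blastocysts of both sexes, every autosomal trisomy and monosomy in
duplicate, XO and XXX, plus two mosaic embryos whose screening labels claim
pure trisomies — and writes the raw artifacts (count matrix, one VCF per
embryo, annotation and metadata TSVs) under --cohort-dir, with a small
design summary under --results.
"""

import argparse
from pathlib import Path

import pandas as pd

from ploidyseq import SimConfig, simulate_cohort, study_like_design
from ploidyseq.simulate import write_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--cohort-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = SimConfig(seed=args.seed)
    design = study_like_design(config)
    cohort = simulate_cohort(config, design)
    write_cohort(cohort, args.cohort_dir)

    args.results.mkdir(parents=True, exist_ok=True)
    summary = (
        cohort.metadata.groupby(["label", "mosaic"]).size().rename("n_embryos")
    )
    summary.to_csv(args.results / "cohort_design.tsv", sep="\t")
    print(
        f"simulated {cohort.counts.shape[1]} embryos x "
        f"{cohort.counts.shape[0]} genes -> {args.cohort_dir}"
    )
    print(f"{int(cohort.metadata['mosaic'].sum())} mosaic embryos planted")


if __name__ == "__main__":
    main()
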