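"""FPKM quantification and expressed-core summaries.

FPKM(g, s) = counts(g, s) x 10^9 / (length_bp(g) x total_counts(s)), with
the per-million denominator taken from the count-matrix column sums so the
quantification is self-contained.  A gene is called expressed at FPKM >= 10
(inclusive); the expressed core of a sample set is the intersection of
per-sample expressed sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fpkm",
    "expressed_core",
    "chromosome_expression_fraction",
    "detect_y_expression",
]


def _check_annotation(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    ann = annotation.set_index("gene_id")
    missing = counts.index.difference(ann.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} genes missing from annotation, e.g. "
            + ", ".join(map(str, missing[:5]))
        )
    return ann.loc[counts.index]


def compute_fpkm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``counts`` is genes x samples (index gene_id); ``annotation`` must cover
    every counted gene and supply length_bp >= 1.  Columns are invariant
    under global scaling of the sample's counts; rows scale inversely with
    gene length.
    """
    ann = _check_annotation(counts, annotation)
    lengths = ann["length_bp"].to_numpy(dtype=float)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = counts.columns[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    fpkm = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def expressed_core(
    fpkm: pd.DataFrame,
    sample_ids: Sequence[str],
    threshold: float = 10.0,
) -> tuple[set[str], float]:
    """Expressed core of a sample set and its overlap fraction.

    Per sample, expressed = {g : FPKM >= threshold} (inclusive cutoff); the
    core is the intersection over samples and the overlap fraction is
    |core| / |union| (0, with a warning, if the union is empty).
    """
    if len(sample_ids) < 2:
        raise ValueError("expressed_core needs at least two samples")
    sub = fpkm[list(sample_ids)]
    expressed = sub >= threshold
    core_mask = expressed.all(axis=1)
    union_mask = expressed.any(axis=1)
    core = set(sub.index[core_mask])
    n_union = int(union_mask.sum())
    if n_union == 0:
        logger.warning("no gene expressed in any sample; overlap set to 0")
        return core, 0.0
    return core, len(core) / n_union


def chromosome_expression_fraction(
    expressed: Iterable[str], annotation: pd.DataFrame
) -> pd.Series:
    """Fraction of each chromosome's annotated genes that are expressed.

    Chromosomes with zero annotated genes are omitted.  On euploid data no
    chromosome should stand far off the rest — expression is spread roughly
    evenly once gene content is normalized out.
    """
    expressed = set(expressed)
    unknown = expressed - set(annotation["gene_id"])
    if unknown:
        raise ValueError(f"{len(unknown)} expressed genes not in annotation")
    ann = annotation.assign(expressed=annotation["gene_id"].isin(expressed))
    grouped = ann.groupby("chrom", sort=False)["expressed"].agg(["sum", "count"])
    grouped = grouped[grouped["count"] > 0]
    return grouped["sum"] / grouped["count"]


def detect_y_expression(
    fpkm: pd.DataFrame,
    annotation: pd.DataFrame,
    sample: str,
    threshold: float = 10.0,
    min_genes: int = 1,
) -> bool:
    """True iff >= ``min_genes`` Y-chromosome genes reach FPKM >= threshold
    in the sample (male embryos express Y transcripts at the blastocyst
    stage; an annotation without Y genes yields False)."""
    y_genes = annotation.loc[annotation["chrom"] == "Y", "gene_id"]
    y_genes = fpkm.index.intersection(y_genes)
    if len(y_genes) == 0:
        return False
    return int((fpkm.loc[y_genes, sample] >= threshold).sum()) >= min_genes
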