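"""Chromosome-by-aneuploidy summaries of differential expression.

The central object is the normalized "bubble" matrix: for each aneuploidy
(row) and chromosome (column), the count of significantly up- (or down-)
regulated genes on that chromosome divided by both the chromosome's
annotated gene count and the aneuploidy's total number of DE genes.  On a
dosage-driven cohort the up-direction matrix of trisomies (and the
down-direction matrix of monosomies) is diagonal-dominant: the gained/lost
chromosome carries the strongest normalized signal of its own row.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "de_counts_by_chromosome",
    "bubble_matrix",
    "rank_aneuploidies",
    "diagonal_dominance",
]


def _gene_chrom(annotation: pd.DataFrame) -> pd.Series:
    return annotation.set_index("gene_id")["chrom"]


def _direction_mask(results: pd.DataFrame, direction: str) -> pd.Series:
    if direction == "up":
        return results["significant"] & (results["log2fc"] > 0)
    if direction == "down":
        return results["significant"] & (results["log2fc"] < 0)
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def de_counts_by_chromosome(
    results: pd.DataFrame, annotation: pd.DataFrame, direction: str
) -> pd.Series:
    """Significant up- or down-regulated gene counts per chromosome.

    Every DE gene must be annotated; chromosomes without DE genes report 0.
    Up and down partition the significant set (log2fc = 0 cannot reach
    significance).
    """
    chrom_of = _gene_chrom(annotation)
    genes = results.index[_direction_mask(results, direction)]
    missing = genes.difference(chrom_of.index)
    if len(missing):
        raise ValueError(f"{len(missing)} DE genes missing from annotation")
    chroms = pd.unique(annotation["chrom"])
    counts = chrom_of.loc[genes].value_counts()
    return counts.reindex(chroms, fill_value=0).astype(int)


def bubble_matrix(
    contrasts: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    direction: str,
) -> pd.DataFrame:
    """Normalized DE-count matrix, aneuploidies x chromosomes.

    value(a, c) = count(a, c) / (genes_on(c) x totalDE(a)), where totalDE is
    the aneuploidy's total significant-gene count in either direction; rows
    with totalDE = 0 are all-zero.
    """
    genes_on = annotation["chrom"].value_counts()
    rows = {}
    for label, res in contrasts.items():
        counts = de_counts_by_chromosome(res, annotation, direction)
        total = int(res["significant"].sum())
        if total == 0:
            rows[label] = counts.astype(float) * 0.0
        else:
            rows[label] = counts / (genes_on.reindex(counts.index) * total)
    return pd.DataFrame(rows).T


def rank_aneuploidies(contrasts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Aneuploidies ordered by total DE genes (descending; ties broken by
    label lexicographically)."""
    totals = {
        label: int(res["significant"].sum()) for label, res in contrasts.items()
    }
    out = pd.DataFrame(
        sorted(totals.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["label", "total_de"],
    )
    return out


def diagonal_dominance(
    matrix: pd.DataFrame, label_to_chrom: Mapping[str, str]
) -> float:
    """Fraction of aneuploidies whose own chromosome attains its row maximum.

    All-zero rows are excluded from both numerator and denominator; a tie
    for the row maximum that includes the own chromosome counts as dominant.
    Raises if a row label has no chromosome mapping.
    """
    n_dom = 0
    n_rows = 0
    for label, row in matrix.iterrows():
        if label not in label_to_chrom:
            raise KeyError(f"no chromosome mapped for aneuploidy {label!r}")
        chrom = str(label_to_chrom[label])
        if chrom not in matrix.columns:
            raise KeyError(f"chromosome {chrom!r} not a column of the matrix")
        values = row.to_numpy(dtype=float)
        if not np.any(values > 0):
            continue
        n_rows += 1
        if row[chrom] >= values.max():
            n_dom += 1
    return n_dom / n_rows if n_rows else 0.0
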