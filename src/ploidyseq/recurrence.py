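"""Recurrently deregulated genes across aneuploidies.

Within each class (trisomies, monosomies), only contrasts with at least 100
differentially expressed genes are eligible.  For every gene the fraction
of eligible contrasts in which it is up-regulated, down-regulated or
unchanged is computed, genes changing in the same direction in at least 60%
of a class are selected, and the trisomy/monosomy selections are
intersected to yield the genes deregulated across aneuploidy classes.
"Deregulated" means significant (padj < alpha) with the sign of the log2
fold change — no extra fold-change floor.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import parse_karyotype_label

logger = logging.getLogger(__name__)

__all__ = [
    "contrast_class",
    "eligible_aneuploidies",
    "recurrence_fractions",
    "frequently_deregulated",
    "common_across_classes",
]

CLASSES = ("trisomy", "monosomy")


def contrast_class(label: str) -> str | None:
    """Class of an aneuploidy label: 'trisomy' (gain, incl. XXX), 'monosomy'
    (loss, incl. XO), or None for anything else."""
    try:
        copy_map, sex = parse_karyotype_label(label)
    except ValueError:
        low = label.strip().lower()
        if low.startswith("trisomy"):
            return "trisomy"
        if low.startswith("monosomy"):
            return "monosomy"
        return None
    gains = [cn for cn in copy_map.values() if cn == 3]
    losses = [cn for cn in copy_map.values() if cn == 1]
    if gains or sex == "XXX":
        return "trisomy"
    if losses or sex == "XO":
        return "monosomy"
    return None


def eligible_aneuploidies(
    contrasts: Mapping[str, pd.DataFrame], min_de: int = 100
) -> dict[str, list[str]]:
    """Contrast labels with >= ``min_de`` DE genes (inclusive), per class."""
    out: dict[str, list[str]] = {c: [] for c in CLASSES}
    for label, res in contrasts.items():
        cls = contrast_class(label)
        if cls is None:
            logger.warning("contrast %r is neither trisomy nor monosomy; skipped", label)
            continue
        if int(res["significant"].sum()) >= min_de:
            out[cls].append(label)
    return out


def _direction(res: pd.DataFrame, genes: pd.Index) -> pd.Series:
    """Per-gene direction in one contrast: +1 up, -1 down, 0 unchanged.
    Genes absent from the contrast's table count as unchanged."""
    d = pd.Series(0, index=genes, dtype=int)
    present = genes.intersection(res.index)
    if len(present) < len(genes):
        logger.warning(
            "%d genes absent from a contrast table; counted unchanged",
            len(genes) - len(present),
        )
    sub = res.loc[present]
    sig = sub["significant"]
    d.loc[present[sig & (sub["log2fc"] > 0)]] = 1
    d.loc[present[sig & (sub["log2fc"] < 0)]] = -1
    return d


def recurrence_fractions(
    contrasts: Mapping[str, pd.DataFrame],
    eligible: Mapping[str, list[str]],
) -> pd.DataFrame:
    """Per-gene recurrence fractions over the eligible contrasts of each
    class.

    Returns a table indexed by gene with columns
    ``{class}_{up,down,unchanged}`` (fractions summing to 1 per gene and
    class) plus ``n_eligible_{class}``.  Classes without eligible contrasts
    are omitted.
    """
    genes = pd.Index([])
    for labels in eligible.values():
        for label in labels:
            genes = genes.union(contrasts[label].index)
    out = pd.DataFrame(index=genes)
    for cls in CLASSES:
        labels = list(eligible.get(cls, []))
        if not labels:
            continue
        up = pd.Series(0.0, index=genes)
        down = pd.Series(0.0, index=genes)
        for label in labels:
            d = _direction(contrasts[label], genes)
            up += (d == 1).astype(float)
            down += (d == -1).astype(float)
        n = len(labels)
        out[f"{cls}_up"] = up / n
        out[f"{cls}_down"] = down / n
        out[f"{cls}_unchanged"] = 1.0 - out[f"{cls}_up"] - out[f"{cls}_down"]
        out[f"n_eligible_{cls}"] = n
    return out


def frequently_deregulated(
    table: pd.DataFrame, threshold: float = 0.60
) -> dict[str, set[str]]:
    """Genes deregulated in >= ``threshold`` (inclusive) of a class's
    eligible contrasts, split by class and direction."""
    sets: dict[str, set[str]] = {}
    for cls in CLASSES:
        for direction in ("up", "down"):
            col = f"{cls}_{direction}"
            if col in table.columns:
                sets[col] = set(table.index[table[col] >= threshold])
            else:
                sets[col] = set()
    return sets


def common_across_classes(sets: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Genes recurrently deregulated in both classes, per direction."""
    return {
        "common_up": set(sets.get("trisomy_up", set())) & set(sets.get("monosomy_up", set())),
        "common_down": set(sets.get("trisomy_down", set())) & set(sets.get("monosomy_down", set())),
    }
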