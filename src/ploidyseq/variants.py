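"""VCF reading, high-confidence filtering and per-chromosome allele fractions.

The karyotype-validation pathway works on called variants only: each VCF
record is reduced to (chrom, pos, depth, alt depth, quality), filtered to
high-confidence calls (depth >= 50 and quality >= 500 by default, both
inclusive), and collapsed to per-chromosome variant-allele-fraction (VAF)
collections whose density peaks carry the chromosome copy-number signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "VAFSet",
    "read_vcf",
    "filter_high_confidence",
    "group_vafs_by_chromosome",
    "vaf_table",
]


@dataclass(frozen=True)
class Variant:
    """One biallelic variant call. Coordinates are 1-based as in VCF."""

    chrom: str
    pos: int
    depth: int
    alt_depth: int
    quality: float

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.alt_depth > self.depth:
            raise ValueError(f"alt_depth {self.alt_depth} exceeds depth {self.depth}")

    @property
    def vaf(self) -> float:
        """Alt-read fraction; depth is the DP denominator, not ref+alt."""
        return self.alt_depth / self.depth


@dataclass
class VAFSet:
    """All allele fractions observed on one chromosome."""

    chrom: str
    vafs: np.ndarray

    def __post_init__(self) -> None:
        self.vafs = np.asarray(self.vafs, dtype=float)
        if self.vafs.size and (self.vafs.min() < 0 or self.vafs.max() > 1):
            raise ValueError("allele fractions must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.vafs.size)


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1


def read_vcf(path: str | Path, include_indels: bool = False) -> list[Variant]:
    """Read a VCF (v4.x) into a list of :class:`Variant`.

    One variant per biallelic record; multi-allelic records are skipped (the
    peak model assumes biallelic fractions), as are records lacking DP/AD —
    both with a logged warning.  Depth comes from FORMAT/DP of the first
    sample (INFO/DP as fallback), alt depth from FORMAT/AD.  Indels are
    skipped unless ``include_indels``.
    """
    out: list[Variant] = []
    n_multi = n_missing = n_indel = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            if not include_indels and not _is_snv(rec.ref or "", alts[0]):
                n_indel += 1
                continue
            depth = None
            alt_depth = None
            if rec.samples:
                sample = rec.samples[0]
                depth = sample.get("DP")
                ad = sample.get("AD")
                if ad is not None and len(ad) >= 2 and ad[1] is not None:
                    alt_depth = int(ad[1])
                    if depth is None:
                        depth = int(sum(a for a in ad if a is not None))
            if depth is None:
                depth = rec.info.get("DP")
            if depth is None or alt_depth is None:
                n_missing += 1
                continue
            depth = int(depth)
            ad_total = None
            if rec.samples:
                ad = rec.samples[0].get("AD")
                if ad is not None and all(a is not None for a in ad):
                    ad_total = int(sum(ad))
            if ad_total and depth and abs(ad_total - depth) / depth > 0.20:
                logger.warning(
                    "%s:%d AD sum %d deviates >20%% from DP %d",
                    rec.chrom, rec.pos, ad_total, depth,
                )
            out.append(
                Variant(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    depth=depth,
                    alt_depth=min(alt_depth, depth),
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                )
            )
    if n_multi:
        logger.warning("skipped %d multi-allelic records", n_multi)
    if n_missing:
        logger.warning("skipped %d records lacking DP/AD", n_missing)
    if n_indel:
        logger.debug("skipped %d indel records", n_indel)
    return out


def filter_high_confidence(
    variants: Iterable[Variant],
    min_depth: int = 50,
    min_quality: float = 500.0,
) -> list[Variant]:
    """Keep high-confidence variants: depth >= ``min_depth`` and quality >=
    ``min_quality`` (both inclusive); input order preserved."""
    if min_depth < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        v for v in variants if v.depth >= min_depth and v.quality >= min_quality
    ]


def group_vafs_by_chromosome(variants: Sequence[Variant]) -> list[VAFSet]:
    """Collect VAF = alt_depth/depth per chromosome, in order of first
    appearance.  Zero-depth variants are excluded with a warning; chromosomes
    absent from the input yield no set."""
    by_chrom: dict[str, list[float]] = {}
    n_zero = 0
    for v in variants:
        if v.depth == 0:
            n_zero += 1
            continue
        by_chrom.setdefault(v.chrom, []).append(v.vaf)
    if n_zero:
        logger.warning("excluded %d zero-depth variants from VAF sets", n_zero)
    return [VAFSet(chrom=c, vafs=np.array(vs)) for c, vs in by_chrom.items()]


def vaf_table(variants: Sequence[Variant]):
    """Optional flat export: one row per variant with its VAF (depth>0)."""
    import pandas as pd

    rows = [
        (v.chrom, v.pos, v.depth, v.alt_depth, v.quality, v.vaf)
        for v in variants
        if v.depth > 0
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "depth", "alt_depth", "quality", "vaf"]
    )
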