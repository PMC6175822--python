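"""Shared fixtures and helpers: everything is generated in-process from the
synthetic cohort module, so the suite needs no data files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ploidyseq import (
    KaryotypeSpec,
    SimConfig,
    classify_ploidy,
    detect_vaf_peaks,
    filter_high_confidence,
    group_vafs_by_chromosome,
    simulate_cohort,
    simulate_variants,
)
from ploidyseq.variants import Variant


def variants_from_frame(df: pd.DataFrame) -> list[Variant]:
    """Variant objects from a simulated variant table."""
    return [
        Variant(r.chrom, int(r.pos), int(r.depth), int(r.alt_depth), float(r.quality))
        for r in df.itertuples(index=False)
    ]


def ploidy_calls(config: SimConfig, spec: KaryotypeSpec, rep: int = 0):
    """Full variant -> filter -> VAF -> peaks -> ploidy path per chromosome."""
    frame = simulate_variants(config, spec, rep=rep)
    variants = filter_high_confidence(variants_from_frame(frame))
    return {
        s.chrom: classify_ploidy(detect_vaf_peaks(s))
        for s in group_vafs_by_chromosome(variants)
    }


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        genes_per_chromosome=60,
        y_genes=12,
        variants_per_chromosome=200,
        n_pan_up=0,
        n_pan_down=0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    design = [
        (KaryotypeSpec.euploid("XX"), 3),
        (KaryotypeSpec.trisomy("3"), 2),
        (KaryotypeSpec.monosomy("5"), 2),
    ]
    return simulate_cohort(small_config, design)
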