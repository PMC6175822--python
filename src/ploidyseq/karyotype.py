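"""Ploidy calling from per-chromosome allele-fraction peaks.

A chromosome present in k copies yields allele-fraction peaks at
{j/k : j = 1..k}: one peak near 1 for haploid, peaks near 1/2 and 1 for
diploid, and a peak near 2/3 (plus a low peak and one near 1) for triploid.
Peaks are found on a kernel-smoothed density of the VAFs with boundary
reflection at 0 and 1; classification matches the detected peaks against
closed template windows, with "indeterminate" as the sink for anything else
— which is exactly how mosaic chromosomes (peaks off every template, e.g.
0.4/0.6 for a 50/50 diploid/trisomic mixture) get flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .simulate import SEX_X_COPY, parse_karyotype_label
from .variants import VAFSet

__all__ = [
    "PeakSet",
    "PloidyCall",
    "KaryotypeCall",
    "detect_vaf_peaks",
    "classify_ploidy",
    "call_karyotype",
    "validate_against_label",
    "WINDOWS",
]

#: Closed template windows on the allele-fraction axis.
#:   hom      — the near-1 peak every ploidy shares;
#:   dip_het  — the diploid heterozygous peak near 1/2;
#:   trip_mid — the triploid discriminator near 2/3 (2/3 +/- 0.05);
#:   trip_low — the low triploid peak, wide enough for 1/3 or 1/2.
WINDOWS: dict[str, tuple[float, float]] = {
    "hom": (0.85, 1.0),
    "dip_het": (0.45, 0.55),
    "trip_mid": (2.0 / 3.0 - 0.05, 2.0 / 3.0 + 0.05),
    "trip_low": (0.28, 0.58),
}


def _in(window: tuple[float, float], x: float) -> bool:
    lo, hi = window
    return lo <= x <= hi  # closed: a peak exactly on an edge belongs


@dataclass
class PeakSet:
    """Detected density peaks of one chromosome's VAF distribution."""

    chrom: str
    locations: np.ndarray  # strictly increasing, in [0, 1]
    heights: np.ndarray
    n_variants: int

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.locations.size != self.heights.size:
            raise ValueError("locations and heights must have equal length")
        if self.locations.size > 1 and not np.all(np.diff(self.locations) > 0):
            raise ValueError("peak locations must be strictly increasing")


@dataclass
class PloidyCall:
    chrom: str
    ploidy: int | str  # 1, 2, 3 or "indeterminate"
    peaks: PeakSet | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.ploidy == "indeterminate" and not self.reason:
            raise ValueError("indeterminate calls must carry a reason")

    @property
    def determinate(self) -> bool:
        return self.ploidy in (1, 2, 3)


@dataclass
class KaryotypeCall:
    calls: Mapping[str, PloidyCall]
    sex_call: str  # XX, XY, XO, XXX or unknown
    status: str = ""  # set by validate_against_label

    def autosome_copy_map(self) -> dict[str, int | str]:
        return {
            c: call.ploidy
            for c, call in self.calls.items()
            if c not in ("X", "Y")
        }


def detect_vaf_peaks(
    vafset: VAFSet,
    bandwidth: float = 0.04,
    min_prominence_fraction: float = 0.1,
    grid_size: int = 1024,
) -> PeakSet:
    """Detect density peaks of a chromosome's allele fractions.

    The density is a histogram on [0, 1] smoothed with a Gaussian kernel of
    standard deviation ``bandwidth`` under edge reflection at both
    boundaries, so peaks sitting exactly at 1 (haploid chromosomes) are not
    attenuated.  Local maxima with prominence below
    ``min_prominence_fraction`` of the global maximum are discarded.
    """
    if vafset.n < 1:
        raise ValueError("cannot detect peaks on an empty VAF set")
    hist, edges = np.histogram(vafset.vafs, bins=grid_size, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma = bandwidth * grid_size
    density = gaussian_filter1d(hist.astype(float), sigma=sigma, mode="reflect")
    # pad symmetrically so boundary maxima are interior points for find_peaks
    pad = min(grid_size - 1, int(np.ceil(4 * sigma)) + 1)
    padded = np.pad(density, pad, mode="symmetric")
    prominence = min_prominence_fraction * padded.max()
    idx, _ = find_peaks(padded, prominence=max(prominence, 1e-12))
    idx = idx - pad
    keep = sorted({int(np.clip(i, 0, grid_size - 1)) for i in idx})
    locs = centers[keep]
    heights = density[keep]
    return PeakSet(
        chrom=vafset.chrom,
        locations=locs,
        heights=heights,
        n_variants=vafset.n,
    )


def classify_ploidy(peaks: PeakSet, min_variants: int = 50) -> PloidyCall:
    """Classify a chromosome's ploidy from its VAF peaks.

    Template matching on closed windows (see :data:`WINDOWS`): triploid
    requires a peak in the 2/3 window plus one near 1; diploid a peak near
    1/2 and one near 1 with nothing in the 2/3 window; haploid a single
    near-1 signature (no peak below 0.85).  Every detected peak must fall in
    a window of the chosen template; chromosomes with fewer than
    ``min_variants`` variants, or any unassigned peak, are indeterminate.
    """
    chrom = peaks.chrom
    if peaks.n_variants < min_variants:
        return PloidyCall(
            chrom, "indeterminate", peaks,
            reason=f"only {peaks.n_variants} variants (< {min_variants})",
        )
    locs = list(peaks.locations)
    if not locs:
        return PloidyCall(chrom, "indeterminate", peaks, reason="no peaks detected")
    has_hom = any(_in(WINDOWS["hom"], x) for x in locs)
    has_mid = any(_in(WINDOWS["trip_mid"], x) for x in locs)
    has_het = any(_in(WINDOWS["dip_het"], x) for x in locs)
    if not has_hom:
        return PloidyCall(chrom, "indeterminate", peaks, reason="no peak near 1")
    if has_mid:
        ok = all(
            _in(WINDOWS["trip_low"], x) or _in(WINDOWS["trip_mid"], x)
            or _in(WINDOWS["hom"], x)
            for x in locs
        )
        if ok:
            return PloidyCall(chrom, 3, peaks)
        return PloidyCall(
            chrom, "indeterminate", peaks,
            reason="2/3 peak present but extra peaks off the triploid template",
        )
    if has_het:
        ok = all(
            _in(WINDOWS["dip_het"], x) or _in(WINDOWS["hom"], x) for x in locs
        )
        if ok:
            return PloidyCall(chrom, 2, peaks)
        return PloidyCall(
            chrom, "indeterminate", peaks,
            reason="peaks off the diploid template (possible mosaic)",
        )
    if all(_in(WINDOWS["hom"], x) for x in locs):
        return PloidyCall(chrom, 1, peaks)
    return PloidyCall(
        chrom, "indeterminate", peaks,
        reason="peaks outside every ploidy template (possible mosaic)",
    )


#: (X ploidy, Y expression) -> sex call
_SEX_TABLE = {(2, False): "XX", (1, True): "XY", (1, False): "XO", (3, False): "XXX"}


def call_karyotype(
    calls: Mapping[str, PloidyCall],
    y_expressed: bool,
    autosomes: tuple[str, ...] | None = None,
) -> KaryotypeCall:
    """Assemble per-chromosome calls into an embryo karyotype.

    The sex call combines the X ploidy call with Y-transcript presence
    (males express Y transcripts already at the blastocyst stage): (2, no Y)
    = XX, (1, Y) = XY, (1, no Y) = XO, (3, no Y) = XXX; anything else is
    unknown.  Chromosomes missing from ``calls`` become indeterminate.
    """
    if autosomes is None:
        autosomes = tuple(str(i) for i in range(1, 23))
    full: dict[str, PloidyCall] = {}
    for chrom in (*autosomes, "X"):
        if chrom in calls:
            full[chrom] = calls[chrom]
        else:
            full[chrom] = PloidyCall(
                chrom, "indeterminate", None, reason="chromosome missing from input"
            )
    x = full["X"].ploidy
    sex = _SEX_TABLE.get((x, bool(y_expressed)), "unknown") if x != "indeterminate" else "unknown"
    return KaryotypeCall(calls=full, sex_call=sex)


def validate_against_label(karyotype: KaryotypeCall, label: str) -> str:
    """Compare a karyotype call with the embryo's screening (PGS) label.

    Returns ``validated`` when every chromosome's call matches the label's
    implied copy map and none is indeterminate; any indeterminate chromosome
    yields ``excluded_mosaic_or_indeterminate``; a determinate but
    conflicting call yields ``mismatch``.  The result is also stored on
    ``karyotype.status``.
    """
    copy_map, sex = parse_karyotype_label(label)
    if any(not c.determinate for c in karyotype.calls.values()):
        status = "excluded_mosaic_or_indeterminate"
    else:
        ok = all(
            call.ploidy == copy_map.get(chrom, 2)
            for chrom, call in karyotype.calls.items()
            if chrom != "X"
        )
        if sex is None:
            # label asserts no sex: any normal sex complement is consistent
            ok = ok and karyotype.sex_call in ("XX", "XY")
        else:
            ok = ok and karyotype.sex_call == sex
        status = "validated" if ok else "mismatch"
    karyotype.status = status
    return status
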