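"""Peak detection, ploidy classification, karyotype assembly and label
validation."""

import numpy as np
import pytest

from conftest import ploidy_calls, variants_from_frame
from ploidyseq import (
    KaryotypeSpec,
    SimConfig,
    call_karyotype,
    classify_ploidy,
    detect_vaf_peaks,
    filter_high_confidence,
    group_vafs_by_chromosome,
    simulate_variants,
    validate_against_label,
)
from ploidyseq.karyotype import WINDOWS, PeakSet, PloidyCall
from ploidyseq.variants import VAFSet


def peakset(locs, n=500):
    locs = np.asarray(locs, dtype=float)
    return PeakSet("1", locs, np.ones_like(locs), n_variants=n)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def test_point_mass_single_peak_at_one():
    vafset = VAFSet("1", np.ones(200))
    peaks = detect_vaf_peaks(vafset)
    assert peaks.locations.size == 1
    assert peaks.locations[0] == pytest.approx(1.0, abs=0.01)


def test_empty_vafset_rejected():
    with pytest.raises(ValueError):
        detect_vaf_peaks(VAFSet("1", np.array([])))


def test_diploid_peaks_binomial_oracle():
    """Against a direct binomial mixture (het at 1/2, hom at 1): peaks land
    within 0.05 of the template."""
    rng = np.random.default_rng(0)
    vafs = np.concatenate(
        [rng.binomial(100, 0.5, 1000) / 100, rng.binomial(100, 1.0, 1000) / 100]
    )
    peaks = detect_vaf_peaks(VAFSet("1", vafs))
    assert peaks.locations.size == 2
    assert peaks.locations[0] == pytest.approx(0.5, abs=0.05)
    assert peaks.locations[1] == pytest.approx(1.0, abs=0.05)


def test_triploid_peaks_genotype_oracle():
    """Genotype classes {1/3, 2/3, 1} with binomial reads give three peaks,
    the middle within 0.05 of 2/3."""
    rng = np.random.default_rng(1)
    vafs = np.concatenate(
        [rng.binomial(150, p, 700) / 150 for p in (1 / 3, 2 / 3, 1.0)]
    )
    peaks = detect_vaf_peaks(VAFSet("1", vafs))
    assert peaks.locations.size == 3
    assert peaks.locations[1] == pytest.approx(2 / 3, abs=0.05)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "locs, expected",
    [
        ([1.0], 1),
        ([0.5, 1.0], 2),
        ([1 / 3, 2 / 3, 1.0], 3),
        ([0.5, 2 / 3, 1.0], 3),  # the low triploid peak may sit at 1/2
        ([0.45, 0.60, 1.0], "indeterminate"),  # mosaic-shifted middle peak
        ([0.40, 1.0], "indeterminate"),  # shifted het peak
        ([0.5], "indeterminate"),  # no peak near 1
    ],
)
def test_classification_rule_table(locs, expected):
    assert classify_ploidy(peakset(locs)).ploidy == expected


def test_window_edges_are_closed():
    lo, hi = WINDOWS["dip_het"]
    assert classify_ploidy(peakset([lo, 1.0])).ploidy == 2
    assert classify_ploidy(peakset([hi, 1.0])).ploidy == 2
    mid_lo = WINDOWS["trip_mid"][0]
    assert classify_ploidy(peakset([0.5, mid_lo, 1.0])).ploidy == 3


def test_low_support_indeterminate():
    call = classify_ploidy(peakset([0.5, 1.0], n=49))
    assert call.ploidy == "indeterminate"
    assert "49" in call.reason


def test_indeterminate_requires_reason():
    with pytest.raises(ValueError):
        PloidyCall("1", "indeterminate")


# ---------------------------------------------------------------------------
# karyotype assembly and validation
# ---------------------------------------------------------------------------

def _full_calls(x_ploidy=2, abnormal=None):
    calls = {c: PloidyCall(c, 2) for c in map(str, range(1, 23))}
    calls["X"] = PloidyCall("X", x_ploidy)
    if abnormal:
        chrom, ploidy = abnormal
        calls[chrom] = PloidyCall(chrom, ploidy)
    return calls


@pytest.mark.parametrize(
    "x_ploidy, y_expr, sex",
    [(2, False, "XX"), (1, True, "XY"), (1, False, "XO"), (3, False, "XXX"),
     (2, True, "unknown"), (3, True, "unknown")],
)
def test_sex_call_table(x_ploidy, y_expr, sex):
    k = call_karyotype(_full_calls(x_ploidy), y_expressed=y_expr)
    assert k.sex_call == sex


def test_missing_chromosome_is_indeterminate():
    calls = _full_calls()
    del calls["9"]
    k = call_karyotype(calls, y_expressed=False)
    assert k.calls["9"].ploidy == "indeterminate"
    assert validate_against_label(k, "46,XX") == "excluded_mosaic_or_indeterminate"


def test_validation_statuses():
    tri3 = call_karyotype(_full_calls(abnormal=("3", 3)), y_expressed=False)
    assert validate_against_label(tri3, "trisomy 3") == "validated"
    assert tri3.status == "validated"
    euploid = call_karyotype(_full_calls(), y_expressed=False)
    assert validate_against_label(euploid, "trisomy 3") == "mismatch"
    assert validate_against_label(euploid, "46,XX") == "validated"
    # sexless labels accept either normal sex complement
    male = call_karyotype(_full_calls(x_ploidy=1), y_expressed=True)
    assert validate_against_label(male, "46,XY") == "validated"
    assert validate_against_label(male, "46,XX") == "mismatch"
    with pytest.raises(ValueError):
        validate_against_label(euploid, "pentasomy 3")


def test_xxx_call_end_to_end():
    cfg = SimConfig(seed=9)
    calls = ploidy_calls(cfg, KaryotypeSpec(sex="XXX"))
    k = call_karyotype(calls, y_expressed=False)
    assert k.sex_call == "XXX"
    assert validate_against_label(k, "XXX") == "validated"


def test_mosaic_excluded_end_to_end():
    cfg = SimConfig(seed=10)
    mos = KaryotypeSpec.trisomy("7", mosaic_with=KaryotypeSpec.euploid("XX"))
    calls = ploidy_calls(cfg, mos)
    assert calls["7"].ploidy == "indeterminate"
    k = call_karyotype(calls, y_expressed=False)
    assert validate_against_label(k, "trisomy 7, XX") == "excluded_mosaic_or_indeterminate"


def test_classification_stable_under_subsampling():
    """Diploid calls survive uniform subsampling down to the 50-variant
    support floor in >= 95% of subsamples."""
    cfg = SimConfig(seed=12, variants_per_chromosome=500)
    frame = simulate_variants(cfg, KaryotypeSpec.euploid())
    variants = filter_high_confidence(variants_from_frame(frame))
    vafs = next(s for s in group_vafs_by_chromosome(variants) if s.chrom == "1").vafs
    rng = np.random.default_rng(0)
    same = 0
    for _ in range(40):
        sub = rng.choice(vafs, size=50, replace=False)
        call = classify_ploidy(detect_vaf_peaks(VAFSet("1", sub)))
        same += call.ploidy == 2
    assert same >= 38
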