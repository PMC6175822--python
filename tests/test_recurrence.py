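"""Recurrence fractions and cross-class gene selection, checked against
brute-force enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ploidyseq import (
    common_across_classes,
    eligible_aneuploidies,
    frequently_deregulated,
    recurrence_fractions,
)
from ploidyseq.recurrence import contrast_class


def de_table(directions: dict[str, int]):
    """DE table from a {gene: -1/0/+1} direction map."""
    genes = list(directions)
    d = np.array([directions[g] for g in genes])
    return pd.DataFrame(
        {
            "log2fc": d * 1.5,
            "padj": np.where(d != 0, 0.01, 0.8),
            "significant": d != 0,
        },
        index=genes,
    )


def big_table(n_sig: int, n_total: int = 400):
    dirs = {f"g{i}": (1 if i < n_sig else 0) for i in range(n_total)}
    return de_table(dirs)


def test_contrast_class_labels():
    assert contrast_class("trisomy 3, XX") == "trisomy"
    assert contrast_class("monosomy 14") == "monosomy"
    assert contrast_class("XXX") == "trisomy"
    assert contrast_class("XO") == "monosomy"
    assert contrast_class("46,XX") is None


def test_eligibility_inclusive_at_100():
    contrasts = {
        "trisomy 1": big_table(99),
        "trisomy 2": big_table(100),
        "monosomy 3": big_table(250),
    }
    eligible = eligible_aneuploidies(contrasts, min_de=100)
    assert eligible == {"trisomy": ["trisomy 2"], "monosomy": ["monosomy 3"]}
    none = eligible_aneuploidies({"trisomy 1": big_table(99)}, min_de=100)
    assert none["trisomy"] == [] and none["monosomy"] == []


def test_eligibility_monotone_in_min_de():
    contrasts = {f"trisomy {i}": big_table(50 * i) for i in range(1, 6)}
    sizes = [
        len(eligible_aneuploidies(contrasts, min_de=m)["trisomy"])
        for m in (50, 100, 200)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_fraction_arithmetic():
    """A gene up in 3 of 5 eligible trisomies has fraction_up 0.6."""
    contrasts = {
        f"trisomy {i}": de_table({"g": 1 if i < 3 else 0}) for i in range(5)
    }
    eligible = {"trisomy": list(contrasts)}
    table = recurrence_fractions(contrasts, eligible)
    assert table.loc["g", "trisomy_up"] == pytest.approx(0.6)
    assert table.loc["g", "trisomy_unchanged"] == pytest.approx(0.4)


def test_fractions_sum_to_one_exhaustive():
    """Brute force over every direction assignment of one gene across 4
    contrasts (3^4 cases): fractions always sum to 1 and match counting."""
    for combo in itertools.product((-1, 0, 1), repeat=4):
        contrasts = {
            f"trisomy {i}": de_table({"g": d}) for i, d in enumerate(combo)
        }
        table = recurrence_fractions(contrasts, {"trisomy": list(contrasts)})
        row = table.loc["g"]
        assert row["trisomy_up"] == pytest.approx(combo.count(1) / 4)
        assert row["trisomy_down"] == pytest.approx(combo.count(-1) / 4)
        total = row["trisomy_up"] + row["trisomy_down"] + row["trisomy_unchanged"]
        assert total == pytest.approx(1.0)


def test_missing_gene_counts_unchanged(caplog):
    contrasts = {
        "trisomy 1": de_table({"g1": 1, "g2": 1}),
        "trisomy 2": de_table({"g1": 1}),  # g2 absent
    }
    with caplog.at_level("WARNING"):
        table = recurrence_fractions(contrasts, {"trisomy": list(contrasts)})
    assert table.loc["g2", "trisomy_up"] == pytest.approx(0.5)
    assert "counted unchanged" in caplog.text


def test_selection_inclusive_at_threshold():
    table = pd.DataFrame(
        {"trisomy_up": [0.60, 0.59], "trisomy_down": [0.0, 0.0]},
        index=["hit", "miss"],
    )
    sets = frequently_deregulated(table, threshold=0.60)
    assert sets["trisomy_up"] == {"hit"}
    # raising the threshold never grows a set
    assert frequently_deregulated(table, 0.7)["trisomy_up"] <= sets["trisomy_up"]


def test_common_across_classes_intersection():
    sets = {
        "trisomy_up": {"a", "b"},
        "monosomy_up": {"b", "c"},
        "trisomy_down": {"x"},
        "monosomy_down": {"y"},
    }
    common = common_across_classes(sets)
    assert common == {"common_up": {"b"}, "common_down": set()}


def test_matches_bruteforce_enumeration():
    """Random direction tables, 6 contrasts x 50 genes: the pipeline
    selection equals direct enumeration over the direction matrix."""
    rng = np.random.default_rng(17)
    genes = [f"g{i}" for i in range(50)]
    labels = [f"trisomy {i}" for i in range(1, 4)] + [f"monosomy {i}" for i in range(1, 4)]
    for _ in range(10):
        dirs = {lab: {g: int(d) for g, d in zip(genes, rng.integers(-1, 2, 50))} for lab in labels}
        contrasts = {lab: de_table(dirs[lab]) for lab in labels}
        eligible = {"trisomy": labels[:3], "monosomy": labels[3:]}
        table = recurrence_fractions(contrasts, eligible)
        sets = frequently_deregulated(table, threshold=0.60)
        for cls, labs in eligible.items():
            for direction, want in (("up", 1), ("down", -1)):
                expected = {
                    g for g in genes
                    if sum(dirs[l][g] == want for l in labs) / len(labs) >= 0.60
                }
                assert sets[f"{cls}_{direction}"] == expected
        # a gene can never be recurrently up and down in the same class
        assert not (sets["trisomy_up"] & sets["trisomy_down"])


def test_planted_pan_aneuploidy_recovery():
    """Planted 6-up/18-down pan-aneuploidy genes are recovered exactly as
    the common trisomy/monosomy sets on a simulated cohort."""
    from ploidyseq import ContrastSpec, KaryotypeSpec, SimConfig, run_contrast, simulate_cohort
    from ploidyseq.simulate import make_annotation, pan_regulated_genes

    cfg = SimConfig(seed=51)
    ann = make_annotation(cfg)
    pan_up, pan_down = pan_regulated_genes(cfg)
    up_ids = set(ann["gene_id"].iloc[pan_up])
    down_ids = set(ann["gene_id"].iloc[pan_down])

    design = [(KaryotypeSpec.euploid("XX"), 5)]
    for c in ("1", "4", "9", "12", "16", "20"):
        design.append((KaryotypeSpec.trisomy(c), 3))
    for c in ("2", "6", "10", "14", "17", "21"):
        design.append((KaryotypeSpec.monosomy(c), 3))
    cohort = simulate_cohort(cfg, design)
    normals = cohort.metadata.loc[
        cohort.metadata["label"].str.startswith("46"), "sample_id"
    ].tolist()
    contrasts = {}
    for label, grp in cohort.metadata.groupby("label"):
        if label.startswith("46"):
            continue
        contrasts[label] = run_contrast(
            cohort.counts, ContrastSpec(label, grp["sample_id"].tolist(), normals)
        )
    eligible = eligible_aneuploidies(contrasts, min_de=100)
    assert len(eligible["trisomy"]) >= 1 and len(eligible["monosomy"]) >= 1
    table = recurrence_fractions(contrasts, eligible)
    sets = frequently_deregulated(table, threshold=0.60)
    common = common_across_classes(sets)
    assert common["common_up"] == up_ids
    assert common["common_down"] == down_ids
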