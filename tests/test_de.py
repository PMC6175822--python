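"""Size factors, BH adjustment, the NB Wald contrast and volcano classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidyseq import ContrastSpec, adjust_bh, classify_volcano, run_contrast, size_factors


def nb_counts(rng, means, n, disp):
    lam = rng.gamma(1 / disp, means[:, None] * disp, size=(means.size, n))
    return rng.poisson(lam)


def two_group_frame(rng, means_a, means_b, n=5, disp=0.05):
    k = np.hstack([nb_counts(rng, means_a, n, disp), nb_counts(rng, means_b, n, disp)])
    return pd.DataFrame(
        k,
        index=[f"g{i}" for i in range(means_a.size)],
        columns=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
    )


def spec_ab(n=5, **kw):
    return ContrastSpec(
        "aneuploid", [f"b{i}" for i in range(n)], [f"a{i}" for i in range(n)], **kw
    )


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_columns():
    df = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
    assert np.allclose(size_factors(df), 1.0)


def test_size_factors_doubled_column():
    """Column B = 2 x column A gives factors (1/sqrt(2), sqrt(2)) with the
    geometric-mean reference."""
    df = pd.DataFrame({"A": [10, 100, 55], "B": [20, 200, 110]})
    sf = size_factors(df)
    assert sf["A"] == pytest.approx(2 ** -0.5)
    assert sf["B"] == pytest.approx(2 ** 0.5)
    assert sf["B"] / sf["A"] == pytest.approx(2.0)


def test_size_factors_permutation_equivariant():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        rng.poisson(50, size=(100, 4)), columns=list("abcd")
    ) + 1
    sf = size_factors(df)
    perm = ["c", "a", "d", "b"]
    assert np.allclose(size_factors(df[perm]), sf[perm])


def test_size_factors_no_common_gene_errors():
    df = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        size_factors(df)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_stepup_by_hand():
    """p = (.01, .02, .03, .04), m = 4: p(i) m / i = 0.04 for every rank."""
    assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), 0.04)


def test_bh_degenerate():
    assert adjust_bh([0.2]) == pytest.approx([0.2])
    assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        adjust_bh([0.5, 1.5])
    with pytest.raises(ValueError):
        adjust_bh([-0.1])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
def test_bh_matches_statsmodels_and_order_invariant(pvals):
    from statsmodels.stats.multitest import multipletests

    ours = adjust_bh(pvals)
    theirs = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)
    perm = np.random.default_rng(0).permutation(len(pvals))
    assert np.allclose(np.asarray(ours)[perm], adjust_bh(np.asarray(pvals)[perm]))


# ---------------------------------------------------------------------------
# the NB Wald contrast
# ---------------------------------------------------------------------------

def test_contrast_spec_validation():
    with pytest.raises(ValueError):
        ContrastSpec("x", [], ["a"])
    with pytest.raises(ValueError):
        ContrastSpec("x", ["a"], ["a", "b"])


def test_log2fc_sign_orientation():
    """Aneuploid group mean above normal implies positive log2fc."""
    rng = np.random.default_rng(7)
    means = np.full(300, 200.0)
    up = means.copy()
    up[:150] *= 3
    df = two_group_frame(rng, means, up)
    res = run_contrast(df, spec_ab())
    assert (res["log2fc"].iloc[:150] > 0).all()


def test_null_contrast_controls_fdr():
    """Identical NB groups: BH at 0.05 yields no discoveries."""
    fp = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        means = np.exp(rng.uniform(np.log(5), np.log(2000), 1000))
        df = two_group_frame(rng, means, means, disp=0.02)
        res = run_contrast(df, spec_ab())
        fp.append(int(res["significant"].sum()))
    assert sum(fp) == 0


def test_planted_effect_power():
    rng = np.random.default_rng(42)
    means = np.exp(rng.uniform(np.log(20), np.log(2000), 1500))
    up = means.copy()
    up[:100] *= 4
    res = run_contrast(two_group_frame(rng, means, up), spec_ab())
    planted = res.iloc[:100]
    assert planted["significant"].mean() >= 0.9
    assert not (planted["significant"] & (planted["log2fc"] < 0)).any()


def test_all_zero_genes_excluded():
    df = pd.DataFrame(
        {"a0": [0, 5, 7], "a1": [0, 6, 8], "b0": [0, 5, 9], "b1": [0, 7, 6]},
        index=["dead", "g1", "g2"],
    )
    res = run_contrast(df, ContrastSpec("x", ["b0", "b1"], ["a0", "a1"]))
    assert "dead" not in res.index and len(res) == 2


def test_single_sample_group_warns(caplog):
    df = pd.DataFrame(
        {"a0": [5, 7], "a1": [6, 8], "b0": [5, 9]}, index=["g1", "g2"]
    )
    with caplog.at_level("WARNING"):
        run_contrast(df, ContrastSpec("x", ["b0"], ["a0", "a1"]))
    assert "size 1" in caplog.text


def test_own_chromosome_enrichment():
    """On a trisomy cohort without trans effects, significant up-regulation
    concentrates on the gained chromosome (odds ratio > 10)."""
    from ploidyseq.simulate import KaryotypeSpec, SimConfig, make_annotation, simulate_counts

    cfg = SimConfig(seed=31, trans_fraction=0.0, n_pan_up=0, n_pan_down=0)
    ann = make_annotation(cfg)
    eu = simulate_counts(cfg, KaryotypeSpec.euploid(), n_samples=5)
    tri = simulate_counts(cfg, KaryotypeSpec.trisomy("3"), n_samples=3)
    df = pd.DataFrame(
        np.hstack([eu, tri]), index=ann["gene_id"],
        columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(3)],
    )
    spec = ContrastSpec("trisomy 3", [f"b{i}" for i in range(3)], [f"a{i}" for i in range(5)])
    res = run_contrast(df, spec)
    up = res["significant"] & (res["log2fc"] > 0)
    on3 = ann.set_index("gene_id").loc[res.index, "chrom"] == "3"
    a = int((up & on3).sum()); b = int((~up & on3).sum())
    c = int((up & ~on3).sum()); d = int((~up & ~on3).sum())
    assert a > 0
    odds = (a * d) / max((b * c), 1)
    assert odds > 10


def test_volcano_classes():
    res = pd.DataFrame(
        {
            "padj": [0.01, 0.01, 0.2, 0.01],
            "log2fc": [3.0, 0.5, 5.0, -4.0],
            "significant": [True, True, False, True],
        },
        index=list("abcd"),
    )
    classes = classify_volcano(res, ContrastSpec("x", ["s1"], ["s2"]))
    assert classes.tolist() == ["up_strong", "significant_only", "ns", "down_strong"]


def test_wald_contrast_agrees_with_pydeseq2():
    """Independent oracle: the full DESeq2 implementation (pydeseq2) on a
    small planted-effect matrix should broadly agree — same discoveries on
    planted genes, tightly correlated fold changes."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(5)
    means = np.exp(rng.uniform(np.log(50), np.log(2000), 300))
    up = means.copy()
    up[:30] *= 4
    df = two_group_frame(rng, means, up)
    ours = run_contrast(df, spec_ab())

    meta = pd.DataFrame({"condition": ["A"] * 5 + ["B"] * 5}, index=df.columns)
    dds = DeseqDataSet(counts=df.T, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
    stats.summary()
    theirs = stats.results_df.loc[ours.index]

    r = np.corrcoef(ours["log2fc"], theirs["log2FoldChange"])[0, 1]
    assert r > 0.95
    planted = ours.index[:30]
    assert ours.loc[planted, "significant"].all()
    assert (theirs.loc[planted, "padj"] < 0.05).all()
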