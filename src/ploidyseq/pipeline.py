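"""End-to-end orchestration: simulate/load -> validate karyotypes ->
quantify -> differential expression -> dosage summaries -> recurrence.

Embryos whose RNA-based karyotype does not validate against their screening
label (mosaic or indeterminate chromosomes, or an outright mismatch) are
excluded before quantification and differential expression, exactly as the
cohort workflow demands.  A run is fully determined by its
:class:`RunConfig` (including the seed): re-running reproduces identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import ContrastSpec, classify_volcano, run_contrast
from .expression import (
    chromosome_expression_fraction,
    compute_fpkm,
    detect_y_expression,
    expressed_core,
)
from .karyotype import (
    call_karyotype,
    classify_ploidy,
    detect_vaf_peaks,
    validate_against_label,
)
from .recurrence import (
    common_across_classes,
    contrast_class,
    eligible_aneuploidies,
    frequently_deregulated,
    recurrence_fractions,
)
from .simulate import (
    KaryotypeSpec,
    SimConfig,
    parse_karyotype_label,
    simulate_cohort,
    study_like_design,
    write_cohort,
)
from .summarize import bubble_matrix, diagonal_dominance, rank_aneuploidies
from .variants import filter_high_confidence, group_vafs_by_chromosome, read_vcf

logger = logging.getLogger(__name__)

__all__ = ["Thresholds", "RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff used anywhere in the pipeline."""

    min_depth: int = 50
    min_quality: float = 500.0
    min_variants: int = 50
    kde_bandwidth: float = 0.04
    fpkm_threshold: float = 10.0
    alpha: float = 0.05
    volcano_lfc: float = 2.0
    min_de: int = 100
    recurrence_threshold: float = 0.60

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``sim`` (synthetic cohort) or ``inputs`` (paths to
    counts/annotation/metadata TSVs and a VCF directory) must be given.
    """

    outdir: Path
    sim: SimConfig | None = None
    design: list | None = None  # [(KaryotypeSpec, replicates)]
    inputs: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 42

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim config or input paths must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seed = int(raw.get("seed", 42))
        thresholds = Thresholds(**raw.get("thresholds", {}))
        sim = design = inputs = None
        if "simulate" in raw and "inputs" in raw:
            raise ValueError("exactly one of sim config or input paths must be set")
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"] or {})
            design_raw = sim_raw.pop("design", "study")
            sim = SimConfig(seed=seed, **sim_raw)
            if design_raw == "study":
                design = study_like_design(sim)
            else:
                design = []
                for item in design_raw:
                    spec = KaryotypeSpec.from_label(item["label"])
                    if item.get("mosaic_with"):
                        spec = dataclasses.replace(
                            spec,
                            mosaic_with=KaryotypeSpec.from_label(item["mosaic_with"]),
                            label="",
                        )
                    design.append((spec, int(item.get("replicates", 1))))
        elif "inputs" in raw:
            inputs = {k: Path(v) for k, v in raw["inputs"].items()}
        return cls(
            outdir=Path(raw.get("outdir", "ploidyseq_run")),
            sim=sim,
            design=design,
            inputs=inputs,
            thresholds=thresholds,
            seed=seed,
        )

    def digest(self) -> str:
        text = repr(
            (self.sim, self.design, self.inputs, self.thresholds, self.seed)
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_inputs(inputs: dict):
    counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
    annotation = pd.read_csv(inputs["annotation"], sep="\t")[
        ["gene_id", "chrom", "length_bp"]
    ]
    annotation["chrom"] = annotation["chrom"].astype(str)
    metadata = pd.read_csv(inputs["metadata"], sep="\t", dtype={"label": str})
    vcf_dir = Path(inputs["vcf_dir"])
    vcfs = {sid: vcf_dir / f"{sid}.vcf" for sid in metadata["sample_id"]}
    return counts, annotation, metadata, vcfs


def _validate_embryo(vcf_path, label, y_expressed, th: Thresholds, autosomes):
    variants = read_vcf(vcf_path)
    variants = filter_high_confidence(variants, th.min_depth, th.min_quality)
    calls = {}
    for vafset in group_vafs_by_chromosome(variants):
        if vafset.chrom == "Y":
            continue  # Y is never ploidy-called; presence comes from expression
        peaks = detect_vaf_peaks(vafset, bandwidth=th.kde_bandwidth)
        calls[vafset.chrom] = classify_ploidy(peaks, min_variants=th.min_variants)
    kcall = call_karyotype(calls, y_expressed=y_expressed, autosomes=autosomes)
    status = validate_against_label(kcall, label)
    return kcall, status


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON).

    Stage order: cohort (simulated and written, or loaded), per-embryo
    karyotype validation, expressed-core quantification on validated
    normals, per-aneuploidy NB differential expression against validated
    normals, chromosome-normalized dosage summaries, and cross-aneuploidy
    recurrence.  Non-validated embryos never reach any downstream table.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    t0 = time.time()

    def stage(msg: str) -> None:
        line = f"[{time.time() - t0:8.2f}s] {msg}"
        logger.info(msg)
        with open(log_path, "a") as fh:
            fh.write(line + "\n")

    # ----- stage 1: cohort -------------------------------------------------
    if config.sim is not None:
        design = config.design or study_like_design(config.sim)
        cohort = simulate_cohort(config.sim, design)
        write_cohort(cohort, outdir / "cohort")
        counts, annotation, metadata = cohort.counts, cohort.annotation, cohort.metadata
        vcfs = {sid: outdir / "cohort" / "vcf" / f"{sid}.vcf" for sid in counts.columns}
        stage(f"simulated cohort: {counts.shape[1]} embryos, {counts.shape[0]} genes")
    else:
        counts, annotation, metadata, vcfs = _load_inputs(config.inputs)
        stage(f"loaded cohort: {counts.shape[1]} embryos, {counts.shape[0]} genes")

    th = config.thresholds
    autosomes = tuple(
        c for c in pd.unique(annotation["chrom"]) if c not in ("X", "Y")
    )

    # ----- stage 2: karyotype validation ------------------------------------
    fpkm = compute_fpkm(counts, annotation)
    rows = []
    for rec in metadata.itertuples(index=False):
        sid, label = rec.sample_id, rec.label
        y_expr = detect_y_expression(
            fpkm, annotation, sid, threshold=th.fpkm_threshold
        )
        kcall, status = _validate_embryo(
            vcfs[sid], label, y_expr, th, autosomes
        )
        rows.append(
            {
                "sample_id": sid,
                "label": label,
                "sex_call": kcall.sex_call,
                "status": status,
                "n_indeterminate": sum(
                    not c.determinate for c in kcall.calls.values()
                ),
            }
        )
    validation = pd.DataFrame(rows)
    validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    n_validated = int((validation["status"] == "validated").sum())
    stage(
        f"karyotype validation: {n_validated}/{len(validation)} validated, "
        f"{int((validation['status'] != 'validated').sum())} excluded"
    )

    validated = validation.loc[validation["status"] == "validated"]
    normal_ids = [
        r.sample_id
        for r in validated.itertuples(index=False)
        if not parse_karyotype_label(r.label)[0]
        and parse_karyotype_label(r.label)[1] in ("XX", "XY", None)
    ]

    # ----- stage 3: expressed core on validated normals ---------------------
    core_report = {}
    if len(normal_ids) >= 2:
        core, overlap = expressed_core(fpkm, normal_ids, th.fpkm_threshold)
        fractions = chromosome_expression_fraction(core, annotation)
        fractions.rename("expressed_fraction").to_csv(
            outdir / "core_chromosome_fractions.tsv", sep="\t"
        )
        (outdir / "core_genes.txt").write_text("\n".join(sorted(core)) + "\n")
        core_report = {"core_size": len(core), "overlap_fraction": overlap}
        stage(f"expressed core: {len(core)} genes, overlap {overlap:.3f}")

    # ----- stage 4: differential expression ---------------------------------
    contrasts: dict[str, pd.DataFrame] = {}
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    normal_labels = set(
        validated.loc[validated["sample_id"].isin(normal_ids), "label"]
    )
    # contrasts are sex-aware: an all-female aneuploidy group tested against
    # male normals would call every X/Y gene differential on sex alone
    sex_of = (
        metadata.set_index("sample_id")["sex"].to_dict()
        if "sex" in metadata.columns
        else {}
    )

    def matched_normals(aneuploid_ids: list[str]) -> list[str]:
        if not sex_of:
            return normal_ids
        sexes = {sex_of.get(i) for i in aneuploid_ids}
        want = "XY" if sexes == {"XY"} else "XX"
        matched = [i for i in normal_ids if sex_of.get(i) == want]
        return matched if len(matched) >= 2 else normal_ids

    by_label = validated.groupby("label")["sample_id"].apply(list)
    for label, ids in by_label.items():
        if label in normal_labels:
            continue
        spec = ContrastSpec(
            label=label,
            aneuploid_ids=list(ids),
            normal_ids=matched_normals(list(ids)),
            alpha=th.alpha,
            volcano_lfc=th.volcano_lfc,
        )
        res = run_contrast(counts, spec)
        res["class"] = classify_volcano(res, spec)
        res.to_csv(de_dir / f"{label.replace(' ', '_').replace(',', '')}.tsv", sep="\t")
        contrasts[label] = res
    stage(f"differential expression: {len(contrasts)} contrasts")

    # ----- stage 5: dosage summaries ----------------------------------------
    summary_report = {}
    if contrasts:
        ranking = rank_aneuploidies(contrasts)
        ranking.to_csv(outdir / "aneuploidy_ranking.tsv", sep="\t", index=False)
        label_chrom = {}
        for label in contrasts:
            copy_map, _ = parse_karyotype_label(label)
            if len(copy_map) == 1:
                label_chrom[label] = next(iter(copy_map))
        dominance = {}
        for direction, cls in (("up", "trisomy"), ("down", "monosomy")):
            subset = {
                lab: res
                for lab, res in contrasts.items()
                if contrast_class(lab) == cls and lab in label_chrom
            }
            if not subset:
                continue
            matrix = bubble_matrix(subset, annotation, direction)
            matrix.to_csv(outdir / f"bubble_{cls}_{direction}.tsv", sep="\t")
            dominance[f"{cls}_{direction}"] = diagonal_dominance(
                matrix, label_chrom
            )
        summary_report = {
            "ranking_top": ranking.head(5).to_dict("records"),
            "diagonal_dominance": dominance,
        }
        stage(f"summaries: dominance {dominance}")

    # ----- stage 6: recurrence ----------------------------------------------
    recurrence_report = {}
    if contrasts:
        eligible = eligible_aneuploidies(contrasts, min_de=th.min_de)
        table = recurrence_fractions(contrasts, eligible)
        table.to_csv(outdir / "recurrence.tsv", sep="\t")
        sets = frequently_deregulated(table, threshold=th.recurrence_threshold)
        common = common_across_classes(sets)
        for name, genes in {**sets, **common}.items():
            (outdir / f"genes_{name}.txt").write_text(
                "\n".join(sorted(genes)) + ("\n" if genes else "")
            )
        recurrence_report = {
            "n_eligible": {c: len(v) for c, v in eligible.items()},
            **{k: sorted(v) for k, v in {**sets, **common}.items()},
        }
        stage(
            "recurrence: "
            f"{len(common['common_up'])} common up, "
            f"{len(common['common_down'])} common down"
        )

    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
        },
        "validation": {
            "n_embryos": int(len(validation)),
            "n_validated": n_validated,
            "n_excluded": int(len(validation) - n_validated),
            "statuses": validation["status"].value_counts().to_dict(),
        },
        "expressed_core": core_report,
        "contrast_totals": {
            lab: int(res["significant"].sum()) for lab, res in contrasts.items()
        },
        "summary": summary_report,
        "recurrence": recurrence_report,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    stage("done")
    return report
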