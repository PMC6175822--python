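"""Synthetic embryo cohort generator.

Emulates the statistical structure of a blastocyst RNA-seq cohort in which
every autosomal trisomy/monosomy plus the XO and XXX sex abnormalities occur:

* counts are negative-binomial with a cis dosage effect (x1.5 for a gained
  chromosome, x0.5 for a lost one) plus configurable trans-dysregulation and
  a small set of planted pan-aneuploidy recurrent genes;
* per-chromosome variant allele fractions follow a genotype-mixture model:
  the alternate allele is carried by 1..ploidy of the chromosome copies and
  reads are sampled binomially, so pure ploidies peak at {j/k : j=1..k};
* mosaic embryos mix two karyotypes at the cell level, which moves expected
  allele fractions of discordant chromosomes off every pure-ploidy template.

All randomness flows from ``SimConfig.seed`` through named, per-purpose
streams, so identical configurations reproduce byte-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "KaryotypeSpec",
    "Cohort",
    "make_annotation",
    "gene_baselines",
    "expected_means",
    "simulate_counts",
    "simulate_variants",
    "simulate_cohort",
    "study_like_design",
    "write_vcf",
    "write_cohort",
    "parse_karyotype_label",
]

#: X-chromosome copy number implied by each supported sex label.
SEX_X_COPY = {"XX": 2, "XY": 1, "XO": 1, "XXX": 3}

# stream tags: keep the per-purpose RNGs from ever colliding
_S_LENGTHS = 11
_S_BASELINES = 12
_S_TRANS = 13
_S_PAN = 14
_S_COUNTS = 21
_S_VARIANTS = 22


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


@dataclass(frozen=True)
class KaryotypeSpec:
    """True karyotype of one simulated embryo.

    ``copy_numbers`` maps autosome names to copies in {1, 2, 3}; autosomes
    absent from the map are disomic.  At most one autosome may deviate from 2
    (single-aneuploidy cohort design).  Sex chromosomes are set through
    ``sex``; a mosaic embryo carries a second karyotype in ``mosaic_with``,
    mixed at the cell fraction given by ``SimConfig.mosaic_fraction``.
    """

    copy_numbers: Mapping[str, int] = field(default_factory=dict)
    sex: str = "XX"
    label: str = ""
    mosaic_with: "KaryotypeSpec | None" = None
    trans_fraction: float | None = None  # per-karyotype override of SimConfig

    def __post_init__(self) -> None:
        if self.sex not in SEX_X_COPY:
            raise ValueError(f"unsupported sex label {self.sex!r}")
        aberrant = []
        for chrom, cn in self.copy_numbers.items():
            if chrom in ("X", "Y"):
                raise ValueError("sex chromosomes are set via `sex`, not copy_numbers")
            if cn not in (1, 2, 3):
                raise ValueError(f"copy number {cn} for chr{chrom} not in {{1,2,3}}")
            if cn != 2:
                aberrant.append(chrom)
        if len(aberrant) > 1:
            raise ValueError("at most one autosome may deviate from disomy")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        aberrant = [(c, n) for c, n in self.copy_numbers.items() if n != 2]
        if not aberrant:
            base = {"XX": "46,XX", "XY": "46,XY", "XO": "XO", "XXX": "XXX"}[self.sex]
        else:
            chrom, cn = aberrant[0]
            kind = "trisomy" if cn == 3 else "monosomy"
            base = f"{kind} {chrom}, {self.sex}"
        if self.mosaic_with is not None:
            return f"mosaic {base} / {self.mosaic_with.label}"
        return base

    # -- constructors ------------------------------------------------------
    @classmethod
    def euploid(cls, sex: str = "XX") -> "KaryotypeSpec":
        return cls(sex=sex)

    @classmethod
    def trisomy(cls, chrom: str, sex: str = "XX", **kw) -> "KaryotypeSpec":
        return cls(copy_numbers={str(chrom): 3}, sex=sex, **kw)

    @classmethod
    def monosomy(cls, chrom: str, sex: str = "XX", **kw) -> "KaryotypeSpec":
        return cls(copy_numbers={str(chrom): 1}, sex=sex, **kw)

    @classmethod
    def from_label(cls, label: str) -> "KaryotypeSpec":
        copy_map, sex = parse_karyotype_label(label)
        return cls(copy_numbers=copy_map, sex=sex or "XX", label=label)

    # -- queries -----------------------------------------------------------
    @property
    def is_mosaic(self) -> bool:
        return self.mosaic_with is not None

    @property
    def is_euploid(self) -> bool:
        return (
            not self.is_mosaic
            and all(cn == 2 for cn in self.copy_numbers.values())
            and self.sex in ("XX", "XY")
        )

    @property
    def has_y(self) -> bool:
        return self.sex == "XY"

    def copy_for(self, chrom: str) -> int:
        """Copy number of ``chrom`` (Y reported as 1 if present, else 0)."""
        if chrom == "X":
            return SEX_X_COPY[self.sex]
        if chrom == "Y":
            return 1 if self.has_y else 0
        return int(self.copy_numbers.get(chrom, 2))

    def aberrant_chromosomes(self) -> list[str]:
        """Chromosomes whose copy number deviates from the euploid female
        reference (autosomes != 2; X != 2; Y never counted)."""
        out = [c for c, n in self.copy_numbers.items() if n != 2]
        if SEX_X_COPY[self.sex] != 2 and self.sex != "XY":
            out.append("X")
        return out


def parse_karyotype_label(label: str) -> tuple[dict[str, int], str | None]:
    """Parse a cohort karyotype label into (autosome copy map, sex or None).

    Accepted forms: ``46,XX`` / ``46,XY``, ``XO`` / ``45,X``, ``XXX`` /
    ``47,XXX``, ``trisomy N[, sex]`` and ``monosomy N[, sex]``.  A missing sex
    (``trisomy 3``) yields ``None``, meaning "not asserted by the label".
    """
    text = label.strip()
    low = text.lower()
    if low in ("46,xx", "46, xx", "xx"):
        return {}, "XX"
    if low in ("46,xy", "46, xy", "xy"):
        return {}, "XY"
    if low in ("xo", "45,x", "45,x0", "45,xo"):
        return {}, "XO"
    if low in ("xxx", "47,xxx"):
        return {}, "XXX"
    for kind, cn in (("trisomy", 3), ("monosomy", 1)):
        if low.startswith(kind):
            rest = text[len(kind):].strip()
            # comma or whitespace may separate the optional sex suffix
            parts = [p for p in rest.replace(",", " ").split() if p]
            chrom = parts[0] if parts else ""
            if not chrom:
                raise ValueError(f"unparseable karyotype label {label!r}")
            sex = None
            if len(parts) > 1 and parts[1]:
                sex = parts[1].upper()
                if sex not in SEX_X_COPY:
                    raise ValueError(f"unsupported sex {parts[1]!r} in label {label!r}")
            if chrom in ("X", "x"):
                # sex-chromosome aneuploidy expressed as trisomy/monosomy X
                return {}, ("XXX" if cn == 3 else "XO")
            return {chrom: cn}, sex
    raise ValueError(f"unparseable karyotype label {label!r}")


def _interval(name: str, lo, hi, *, integer: bool = False, positive: bool = False):
    if not lo < hi:
        raise ValueError(f"{name} must be a non-degenerate (lo, hi) interval")
    if positive and lo <= 0:
        raise ValueError(f"{name} must be positive")
    if integer and (int(lo) != lo or int(hi) != hi):
        raise ValueError(f"{name} must have integer bounds")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Chromosomes are named "1".."22" and "X" (``n_chromosomes`` = 23 by
    default, the last one being X); chromosome Y additionally carries
    ``y_genes`` genes but, being variant-poor in RNA-seq practice, no
    variants.  ``variants_per_chromosome`` defaults to 500 — the study does
    not report the expressed-variant density achieved from RNA-seq, so this
    is an order-of-magnitude choice, not a measured value.
    """

    n_chromosomes: int = 23
    genes_per_chromosome: int | Sequence[int] = 200
    y_genes: int = 40
    gene_length_range: tuple[int, int] = (500, 10_000)
    baseline_mean_range: tuple[float, float] = (5.0, 2000.0)
    nb_dispersion: float = 0.02
    library_size_factor_range: tuple[float, float] = (0.7, 1.4)
    trans_fraction: float = 0.10
    trans_lfc_sd: float = 1.0
    n_pan_up: int = 6
    n_pan_down: int = 18
    pan_lfc: float = 2.0
    variants_per_chromosome: int = 500
    depth_range: tuple[int, int] = (50, 200)
    qual_model: Callable[[np.ndarray], np.ndarray] | None = None
    mosaic_fraction: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("need at least one autosome plus X")
        _interval("gene_length_range", *self.gene_length_range, integer=True, positive=True)
        _interval("baseline_mean_range", *self.baseline_mean_range, positive=True)
        _interval("library_size_factor_range", *self.library_size_factor_range, positive=True)
        _interval("depth_range", *self.depth_range, integer=True)
        if self.depth_range[0] < 1:
            raise ValueError("depth_range lower bound must be >= 1")
        for name in ("trans_fraction", "mosaic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.trans_lfc_sd <= 0:
            raise ValueError("trans_lfc_sd must be positive")
        if self.variants_per_chromosome < 1:
            raise ValueError("variants_per_chromosome must be >= 1")

    @property
    def chromosomes(self) -> list[str]:
        """Variant-bearing chromosomes: autosomes then X."""
        return [str(i) for i in range(1, self.n_chromosomes)] + ["X"]

    @property
    def gene_chromosomes(self) -> list[str]:
        out = list(self.chromosomes)
        if self.y_genes > 0:
            out.append("Y")
        return out

    def genes_on(self, chrom: str) -> int:
        if chrom == "Y":
            return self.y_genes
        idx = self.chromosomes.index(chrom)
        if isinstance(self.genes_per_chromosome, int):
            return self.genes_per_chromosome
        return int(self.genes_per_chromosome[idx])

    def quality_of(self, depth: np.ndarray) -> np.ndarray:
        """Per-record variant quality; monotone in depth (default 10 x depth,
        so the depth-50 and quality-500 filters align at their boundaries)."""
        if self.qual_model is not None:
            return np.asarray(self.qual_model(depth), dtype=float)
        return 10.0 * np.asarray(depth, dtype=float)


# ---------------------------------------------------------------------------
# gene-level structure (deterministic in config.seed)
# ---------------------------------------------------------------------------

def make_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation table (gene_id, chrom, length_bp), deterministic."""
    rng = np.random.default_rng([config.seed, _S_LENGTHS])
    rows = []
    lo, hi = config.gene_length_range
    for chrom in config.gene_chromosomes:
        n = config.genes_on(chrom)
        lengths = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            rows.append((f"G{chrom}_{i:04d}", chrom, int(lengths[i])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "length_bp"])


def gene_baselines(config: SimConfig) -> np.ndarray:
    """Per-gene euploid mean expression, log-uniform over the configured
    range; aligned with :func:`make_annotation` row order."""
    ann = make_annotation(config)
    rng = np.random.default_rng([config.seed, _S_BASELINES])
    lo, hi = config.baseline_mean_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ann)))


def pan_regulated_genes(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the planted pan-aneuploidy up/down genes.

    Drawn from autosomal genes in the upper half of baseline expression —
    recurrently deregulated genes are by construction detectable, and a
    2-fold knockdown of a barely-expressed gene would vanish into Poisson
    noise rather than emulate one.
    """
    n = config.n_pan_up + config.n_pan_down
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    ann = make_annotation(config)
    base = gene_baselines(config)
    autosomal = ~ann["chrom"].isin(["X", "Y"]).to_numpy()
    candidates = np.flatnonzero(autosomal & (base >= np.median(base)))
    rng = np.random.default_rng([config.seed, _S_PAN])
    chosen = rng.choice(candidates, size=n, replace=False)
    return chosen[: config.n_pan_up], chosen[config.n_pan_up:]


def _component_means(config: SimConfig, kary: KaryotypeSpec) -> np.ndarray:
    """Expected per-gene means of one pure (non-mosaic) karyotype at unit
    library size: baseline x copy/2, with trans and pan perturbations for
    aneuploid karyotypes."""
    ann = make_annotation(config)
    means = gene_baselines(config).copy()
    chroms = ann["chrom"].to_numpy()

    copy_ratio = np.ones(len(ann))
    for chrom in config.gene_chromosomes:
        cn = kary.copy_for(chrom)
        if chrom == "Y":
            copy_ratio[chroms == chrom] = 1.0 if cn else 0.0
        else:
            copy_ratio[chroms == chrom] = cn / 2.0
    means *= copy_ratio

    if not kary.is_euploid and kary.mosaic_with is None:
        pan_up, pan_down = pan_regulated_genes(config)
        means[pan_up] *= 2.0 ** config.pan_lfc
        means[pan_down] *= 2.0 ** -config.pan_lfc

        tf = config.trans_fraction if kary.trans_fraction is None else kary.trans_fraction
        if tf > 0:
            aberrant = set(kary.aberrant_chromosomes())
            off = ~np.isin(chroms, list(aberrant) + ["Y"])
            off[pan_up] = False
            off[pan_down] = False
            candidates = np.flatnonzero(off)
            k = int(round(tf * candidates.size))
            if k:
                rng = np.random.default_rng(
                    [config.seed, _S_TRANS, _label_key(kary.label)]
                )
                idx = rng.choice(candidates, size=k, replace=False)
                lfc = rng.normal(0.0, config.trans_lfc_sd, size=k)
                means[idx] *= 2.0 ** lfc
    return means


def expected_means(config: SimConfig, karyotype: KaryotypeSpec) -> np.ndarray:
    """Expected per-gene NB means at unit library size.

    Mosaic embryos mix the two component karyotypes' means at the configured
    cell fraction, matching a bulk measurement over the mixed cell
    population.
    """
    if karyotype.mosaic_with is None:
        return _component_means(config, karyotype)
    m = config.mosaic_fraction
    primary = replace(karyotype, mosaic_with=None, label=karyotype.label + "#p")
    a = _component_means(config, primary)
    b = _component_means(config, karyotype.mosaic_with)
    return (1.0 - m) * a + m * b


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimConfig,
    karyotype: KaryotypeSpec,
    n_samples: int = 1,
    start_rep: int = 0,
) -> np.ndarray:
    """Simulate a (genes x n_samples) integer count matrix for one karyotype.

    Counts are NB(mean = baseline x copy/2 x library factor x perturbation,
    dispersion = ``nb_dispersion``), drawn gamma–Poisson.  Replicates
    ``start_rep .. start_rep + n_samples - 1`` of the same karyotype under
    the same config are reproducible individually.
    """
    means = expected_means(config, karyotype)
    disp = config.nb_dispersion
    lo, hi = config.library_size_factor_range
    out = np.zeros((means.size, n_samples), dtype=np.int64)
    for j in range(n_samples):
        rng = np.random.default_rng(
            [config.seed, _S_COUNTS, _label_key(karyotype.label), start_rep + j]
        )
        libf = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        mu = means * libf
        lam = np.zeros_like(mu)
        nz = mu > 0
        lam[nz] = rng.gamma(shape=1.0 / disp, scale=mu[nz] * disp)
        out[:, j] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _alt_copies_after_cn_change(a1: np.ndarray, p1: int, p2: int, rng) -> np.ndarray:
    """Alt-copy count in the second cell line given ``a1`` alt copies of
    ``p1`` in the first, when the discordant chromosome was gained/lost one
    copy at a time (the duplicated/lost copy is the alt haplotype with
    probability a/p)."""
    a = a1.astype(float)
    p = p1
    step = 1 if p2 > p1 else -1
    while p != p2:
        hit = rng.random(a.shape) < a / p
        a = a + step * hit
        p += step
    return a


def simulate_variants(
    config: SimConfig, karyotype: KaryotypeSpec, rep: int = 0
) -> pd.DataFrame:
    """Simulate one embryo's variant table (chrom, pos, depth, alt_depth,
    quality).

    For each variant the alternate allele occupies 1..ploidy of the copies
    (uniform), reads are Binomial(depth, alt copies / ploidy), depth is
    uniform over ``depth_range`` and quality follows the config's quality
    model.  For mosaic embryos the expected allele fraction is the
    copy-weighted mixture over the two cell populations, which places peaks
    of discordant chromosomes off every pure-ploidy template.
    """
    rng = np.random.default_rng(
        [config.seed, _S_VARIANTS, _label_key(karyotype.label), rep]
    )
    m = config.mosaic_fraction if karyotype.is_mosaic else 0.0
    second = karyotype.mosaic_with
    nv = config.variants_per_chromosome
    frames = []
    for chrom in config.chromosomes:
        p1 = karyotype.copy_for(chrom)
        p2 = second.copy_for(chrom) if second is not None else p1
        for p in (p1, p2):
            if p not in (1, 2, 3):
                raise ValueError(f"ploidy {p} on chr{chrom} outside {{1,2,3}}")
        pos = np.cumsum(rng.integers(100, 5000, size=nv))
        depth = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=nv)
        a1 = rng.integers(1, p1 + 1, size=nv)
        if p2 != p1:
            a2 = _alt_copies_after_cn_change(a1, p1, p2, rng)
        else:
            a2 = a1.astype(float)
        vaf = ((1.0 - m) * a1 + m * a2) / ((1.0 - m) * p1 + m * p2)
        alt = rng.binomial(depth, vaf)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "depth": depth,
                    "alt_depth": alt,
                    "quality": config.quality_of(depth),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort assembly and file output
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    counts: pd.DataFrame        # genes x samples, index gene_id
    annotation: pd.DataFrame    # gene_id, chrom, length_bp
    metadata: pd.DataFrame      # sample_id, label, sex, mosaic
    variants: dict              # sample_id -> variant DataFrame
    specs: dict                 # sample_id -> KaryotypeSpec


def simulate_cohort(
    config: SimConfig, design: Sequence[tuple[KaryotypeSpec, int]]
) -> Cohort:
    """Simulate a full cohort from a design of (karyotype, replicates).

    Requires at least two non-mosaic euploid replicates (the normal group
    every differential contrast is drawn against).
    """
    n_euploid = sum(n for spec, n in design if spec.is_euploid)
    if n_euploid < 2:
        raise ValueError("cohort design needs >= 2 euploid replicates")
    ann = make_annotation(config)
    cols, col_names, meta_rows = [], [], []
    variants: dict[str, pd.DataFrame] = {}
    specs: dict[str, KaryotypeSpec] = {}
    rep_seen: dict[str, int] = {}
    i = 0
    for spec, n in design:
        start = rep_seen.get(spec.label, 0)
        counts = simulate_counts(config, spec, n_samples=n, start_rep=start)
        if spec.is_mosaic:
            # the screening label only sees the majority line; the mosaic
            # truth is what downstream validation is expected to catch
            claimed = KaryotypeSpec(
                copy_numbers=spec.copy_numbers, sex=spec.sex
            ).label
        else:
            claimed = spec.label
        for j in range(n):
            i += 1
            sid = f"E{i:03d}"
            cols.append(counts[:, j])
            col_names.append(sid)
            variants[sid] = simulate_variants(config, spec, rep=start + j)
            specs[sid] = spec
            meta_rows.append(
                {
                    "sample_id": sid,
                    "label": claimed,
                    "true_label": spec.label,
                    "sex": spec.sex,
                    "mosaic": spec.is_mosaic,
                }
            )
        rep_seen[spec.label] = start + n
    counts_df = pd.DataFrame(
        np.column_stack(cols), index=ann["gene_id"], columns=col_names
    )
    return Cohort(
        counts=counts_df,
        annotation=ann,
        metadata=pd.DataFrame(meta_rows),
        variants=variants,
        specs=specs,
    )


#: Trisomies compatible with live birth show the mildest transcriptome
#: disruption; used by :func:`study_like_design` to tier trans-dysregulation.
VIABLE_TRISOMIES = ("21", "18")


def study_like_design(
    config: SimConfig,
    n_normals_xx: int = 3,
    n_normals_xy: int = 2,
    replicates: int = 2,
    viable_trans_fraction: float = 0.005,
    mosaic_of: Sequence[str] = ("7", "10"),
) -> list[tuple[KaryotypeSpec, int]]:
    """A cohort design shaped like the study: a few euploid embryos of both
    sexes, every autosomal trisomy and monosomy in duplicate, XO and XXX,
    and a couple of mosaic embryos whose screening label claims a pure
    aneuploidy.

    Viable trisomies (21, 18) and the sex abnormalities get a much smaller
    trans-dysregulated fraction, mirroring the observation that viable
    aneuploidies barely move the transcriptome.
    """
    autosomes = [c for c in config.chromosomes if c != "X"]
    design: list[tuple[KaryotypeSpec, int]] = [
        (KaryotypeSpec.euploid("XX"), n_normals_xx),
        (KaryotypeSpec.euploid("XY"), n_normals_xy),
    ]
    for chrom in autosomes:
        tf = viable_trans_fraction if chrom in VIABLE_TRISOMIES else None
        design.append((KaryotypeSpec.trisomy(chrom, trans_fraction=tf), replicates))
    for chrom in autosomes:
        design.append((KaryotypeSpec.monosomy(chrom), replicates))
    design.append(
        (KaryotypeSpec(sex="XO", trans_fraction=viable_trans_fraction), replicates)
    )
    design.append(
        (KaryotypeSpec(sex="XXX", trans_fraction=viable_trans_fraction), replicates)
    )
    for chrom in mosaic_of:
        if chrom in autosomes:
            design.append(
                (
                    KaryotypeSpec.trisomy(
                        chrom, mosaic_with=KaryotypeSpec.euploid("XX")
                    ),
                    1,
                )
            )
    return design


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ploidyseq-simulate
{contigs}
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tEMBRYO
"""


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as a minimal single-sample VCF v4.2 with QUAL,
    FORMAT/DP and FORMAT/AD (ref,alt)."""
    path = Path(path)
    contigs = "\n".join(
        f"##contig=<ID={c}>" for c in pd.unique(variants["chrom"])
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for row in variants.itertuples(index=False):
            ref_d = int(row.depth) - int(row.alt_depth)
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\tA\tC\t{row.quality:g}\t"
                f"PASS\t.\tDP:AD\t{int(row.depth)}:{ref_d},{int(row.alt_depth)}\n"
            )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write counts/annotation/metadata TSVs and one VCF per embryo.

    Returns the paths written, keyed by artifact name ("counts",
    "annotation", "metadata") and sample id for the VCFs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    paths["counts"] = outdir / "counts.tsv"
    cohort.counts.to_csv(paths["counts"], sep="\t")
    paths["annotation"] = outdir / "annotation.tsv"
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.tsv"
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    for sid, var in cohort.variants.items():
        p = vcf_dir / f"{sid}.vcf"
        write_vcf(var, p)
        paths[sid] = p
    return paths
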