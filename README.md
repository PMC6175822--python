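# ploidyseq

RNA-seq karyotype validation and aneuploidy expression analysis for
pre-implantation embryo cohorts.

Bulk RNA-seq of blastocysts carries two signals at once: chromosome copy
number, readable from the per-chromosome distribution of variant allele
fractions (VAFs), and the transcriptome consequences of that copy number.
`ploidyseq` implements the full analysis chain for a cohort of embryos
labeled by pre-implantation genetic screening (PGS):

1. **Karyotype validation** — high-confidence variants (depth ≥ 50,
   quality ≥ 500) are reduced to per-chromosome VAF densities; a
   chromosome in *k* copies peaks at {j/k : j = 1..k}, so haploid ≈ {1},
   diploid ≈ {1/2, 1}, triploid ≈ {.., 2/3, 1}. Peaks off every template
   (the signature of mosaicism) make the embryo indeterminate, and
   non-validated embryos are excluded from everything downstream.
   Sex is called from X ploidy plus Y-transcript presence (XX / XY / XO /
   XXX).
2. **Expressed core** — FPKM ≥ 10 defines expression; the core is the
   intersection of expressed sets across validated normal embryos, with
   per-chromosome expressed fractions normalized by gene content.
3. **Differential expression** — each aneuploidy vs. same-sex normals
   with a negative-binomial Wald test (median-of-ratios size factors,
   moment dispersions with a cohort floor, Benjamini–Hochberg adjustment,
   padj < 0.05; volcano coloring at |log2FC| > 2).
4. **Dosage summaries** — chromosome × aneuploidy "bubble" matrices of DE
   counts normalized by chromosome gene content and per-aneuploidy DE
   totals; trisomies should up-regulate their own chromosome (the dosage
   diagonal), monosomies down-regulate theirs.
5. **Recurrence** — among aneuploidies with ≥ 100 DE genes, genes
   deregulated in the same direction in ≥ 60% of trisomies and of
   monosomies, and their cross-class intersection.

A synthetic cohort generator (NB counts with ×1.5 / ×0.5 cis dosage,
configurable trans-dysregulation, genotype-mixture VAFs with binomial read
sampling, cell-level mosaic mixtures) reproduces the statistical structure
of such a cohort, so the whole chain is testable without patient data.
See `docs/methods.md` for the model and every default.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (99 embryos: 5 normals, every autosomal trisomy and monosomy in
duplicate, XO, XXX, and two mosaics whose labels claim pure trisomies):

```bash
python analysis/01_simulate_cohort.py      # scratch/cohort/{counts,vcf,...}
python analysis/02_validate_karyotypes.py  # results/validation.tsv
python analysis/03_expressed_core.py
python analysis/04_differential_expression.py
python analysis/05_aneuploidy_summary.py
python analysis/06_recurrence.py
```

which prints, at the default seed 42:

```
validated 97/99 embryos
mosaics excluded: 2/2

expressed core: 2430 genes; core/union overlap 85.8%
per-chromosome expressed fractions: median 0.53, range 0.48-0.59
E004 expresses Y transcripts (male embryo)

          label  n_embryos  total_de  up  down
 monosomy 7, XX          2       260  83   177
monosomy 12, XX          2       255 102   153
...
trisomy 21, XX          2        27   7    20    <- viable aneuploidies
trisomy 18, XX          2        29   8    21       rank at the bottom

diagonal dominance: monosomy_down 1.0, trisomy_up 0.41
  (opposite-direction controls: 0.0 and 0.0)

eligible: 20 trisomies, 22 monosomies (>= 100 DE genes)
recurrently deregulated in >= 60% of both classes: 6 up, 18 down
```

Reading the output: both planted mosaics are caught by the VAF templates
and excluded; the expressed core covers about half of each chromosome's
genes with no chromosome over- or under-represented; viable aneuploidies
(trisomy 21/18, XXX, XO), simulated with mild trans-dysregulation, fall to
the bottom of the DE ranking; every lost chromosome dominates the
down-direction bubble matrix of its own monosomy while the controls show
no diagonal at all (at duplicate-level replication the weaker +0.58 log2
gain signal yields only a partial trisomy diagonal — with three replicates
it exceeds 0.9, see `docs/methods.md`); and the 6 + 18 planted
pan-aneuploidy genes are recovered exactly as the recurrent sets.

The same pipeline runs as one command over a YAML config (or on real
inputs: a counts TSV, gene annotation, metadata and one VCF per embryo):

```bash
ploidyseq run-all --config run.yaml
ploidyseq karyotype --vcf embryo.vcf --label "trisomy 3" --min-depth 50 --min-qual 500
```

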