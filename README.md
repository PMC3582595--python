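# cnvmir

Analysis of **copy-number-variable miRNA families (CNV-miRNAs)** and their
target genes. Some human miRNA genes sit inside copy-number-variable
regions, so their dosage differs between individuals. This package asks,
for a family-level miRNA→target regulatory network, whether CNV-labelled
families show a target-recognition preference, how much of their retention
is explained by dosage balance among co-regulating families, and whether
their targets differ from other genes in expression variability, allele
frequencies and functional annotation.

It is organised as an analysis project: the computation lives in the
`cnvmir` library (`src/`), the numbered scripts under `analysis/` are thin
narrative drivers, and all inputs are produced by a seeded synthetic-data
generator so the full pipeline runs anywhere in seconds, with no
downloads.

## The statistics at the core

**Target classification.** With bipartite edges (family *f*, gene *g*) and
a CNV label set *C*, each gene with *d* regulators of which *c* are in *C*
is *exclusive-CNV* (c = d), *exclusive-non-CNV* (c = 0) or *mixed*.
Exclusive groups are tallied by regulator count k ∈ {1,2,3,4,≥5}.

**Relabelling null.** Repeat *R* times (default 1,000): draw |C| pseudo-CNV
families uniformly without replacement, re-classify, record each
category's gene count. With fitted null moments (μ, σ) and observed count
*n*: Z = (n − μ)/σ and one-tailed p = Φ(−|Z|). The closed-form null mean
Σ_genes Π_{i<d} (|C|−i)/(M−i) (hypergeometric, M families) serves as an
independent oracle in the tests.

**Dosage balance.** For genes with exactly two exclusive-CNV regulators:
the non-independent component is m = observed − N(μ, σ); re-seeding the
network with m random genes marks f families per replicate; f/2 (two
families per co-regulating pair) over the subnetwork's family count is the
fraction of CNV families attributable to dosage balance.

**Group comparisons.** Per-gene, per-population coefficient of variation
CV_i = σ_i/M_i (sample sd over mean intensity), compared by two-tailed
Mann–Whitney U; between-population differential expression by reciprocal
OLS of population mean intensities with rank-normalised, externally
studentized residuals thresholded at the 95% t interval, and DE
proportions compared by 1-df chi-square; minor allele frequency
MAF = min(2N_AA + N_Aa, 2N_aa + N_Aa)/2N from genotype counts, compared by
two-sample t-test; per-term annotation proportions by Fisher's exact
two-tailed test; differential-expression ratios (DER) by rank-sum.

## Worked example

```sh
python analysis/01_simulate_inputs.py --seed 0   # writes results/data/
python analysis/02_classify_targets.py
python analysis/03_null_enrichment.py --seed 0
python analysis/04_dosage_balance.py --seed 0
python analysis/05_expression_variability.py
python analysis/06_population_de.py
python analysis/07_utr_maf.py
python analysis/08_der_go_enrichment.py
```

With the default world (54 families × 917 genes, 6,592 edges, 17 CNV
families labelled uniformly at random — a *null* labelling), step 02
prints:

```
917 genes partitioned: exclusive_cnv=43, mixed=683, exclusive_noncnv=191
  exclusive_cnv by k: k=1:33, k=2:5, k=3:5, k=4:0, k=5:0
```

and step 03's observed-vs-null table flags 1 of 10 categories at p < 0.05
— consistent with chance, as it should be when the CNV labels carry no
signal. Step 05 shows the planted within-population variability ordering
(group mean CVs ≈ 0.0249 → 0.0257 → 0.0277 in YRI, rank-sum p ≈ 8×10⁻¹²
for the extreme pair), step 06 finds 171/917 genes DE in at least one
population pair with group DE fractions 17.8%/18.5%/25.6%, step 07's MAF
contrasts are null (p 0.02–0.76 across eight region×population strata,
nothing planted), and step 08 recovers the planted DER ordering
0.503/0.513/0.535 (rank-sum p ≈ 1×10⁻¹⁵ for unregulated vs CNV targets).

Pass `--cnv-bias` to step 01 to label co-regulating families together and
watch the k ≥ 2 categories deviate from the null.

`cnvmir --help` exposes the same stages as subcommands
(`classify`, `nullsim`, `dosage`, `cv`, `maf`, `go-scan`, `simulate`,
`run`), and `cnvmir run --config cfg.yaml --outdir D` executes the whole
pipeline from one YAML file.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic bundle from the seed, runs every stage
of the pipeline on it (classification, relabelling null, dosage balance,
CV, DE, MAF, DER, GO), writes the full stage report to
`results/pipeline_report/`, and writes the JSON summary to `--out`.
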