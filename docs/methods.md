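# Methods

## Model and assumptions

The object of study is a bipartite regulatory network between miRNA
*families* (miRNAs sharing a seed, hence identical predicted sites) and
target genes, together with a binary label on families: located in a
copy-number-variable region or not. Genes are partitioned by the labels
of their regulators — exclusively CNV, mixed, exclusively non-CNV — and
the exclusive groups are tallied by regulator count k (1–4, pooled at ≥5).
The classification universe is exactly the network's genes: a gene with no
regulator cannot appear in an edge list and is not modelled. IDs are
compared case-sensitively after whitespace stripping.

### Edge-list filtering

TargetScan-style inputs carry a total context score (more negative =
stronger predicted repression) and a conserved-site flag. Because the
filtering convention is ambiguous in the literature — a literal reading
of "scores of −0.3 or lower were ignored" would delete the *strongest*
targets — the reader takes an explicit `keep_rule`
(`retain_at_or_below` | `retain_above`) instead of hard-coding a
direction. The default, `retain_at_or_below −0.3`, keeps the conventional
"reliable target" set. A `family_map` column, when present, collapses
per-miRNA rows to family level with deduplication.

### Relabelling null

The target-recognition preference of CNV families is scored against a
fixed-size relabelling null: per replicate, |C| families are drawn
uniformly *without replacement* and treated as pseudo-CNV; every gene is
re-classified; each (group, k) count is recorded. A normal fit
(mean, sample sd with n−1) yields Z = (observed − μ)/σ and the one-tailed
normal tail p = Φ(−|Z|), the spreadsheet NORMDIST convention used in this
literature. Two consequences are worth stating plainly:

- Complementation forces the (exclusive-CNV, k=1) and
  (exclusive-non-CNV, k=1) replicate counts to sum to the number of
  degree-1 genes, so their null sds are identical — a useful exactness
  check.
- Because p is the one-tailed area of |Z|, the null rejection rate at
  p < α is 2α, not α. Calibration tests therefore check the *Z* scores
  against N(0,1) (two-sided rejection ≈ α) and the p < α fraction against
  2α. Note that a published table of this form carries raw, uncorrected
  p-values across its ten rows.

The null mean has a hypergeometric closed form,
Σ_genes Π_{i<d}(|C|−i)/(M−i); the implementation keeps the simulation and
the closed form separate so each validates the other. Replicate counts
are retained on the result, so an empirical-quantile p (with +1
correction) is available alongside the normal-tail p. Categories whose
replicate counts never vary (e.g. |C| = M) are reported as *degenerate*
rather than given a Z.

### Dosage balance

Families co-regulating the same gene cannot change copy number
independently if dosage must stay balanced. The estimate proceeds from
the genes with exactly two exclusive-CNV regulators: the relabelling null
gives the count expected under independent labelling, and
m = observed − N(μ, σ) is the non-independent component (a location shift;
the sd is unchanged). Per replicate, m is drawn from that normal, rounded
to the nearest integer, clamped to [0, |genes|], and that many genes are
selected uniformly from **all** genes of the full network (the generative
claim is about the whole network, not the analysed subnetwork; a
`gene_universe` parameter exposes the alternative reading). The number f
of distinct families touching the selection is fitted as a normal, halved
— each co-regulating pair involves two families, and the halving applies
to mean and sd alike — and normalised by the family count of the k=2
subnetwork. The unrounded m mean is used by default; a `round_mean` flag
reproduces the presentation convention of rounding first.

On a *null* labelling the observed k=2 count sits at (or below) its null
mean, m ≈ 0, and the attributable fraction collapses toward 0 — the
default synthetic world demonstrates exactly this; the fraction is only
meaningful where the observed count exceeds its null.

### Expression variability and between-population DE

CV_i = σ_i/M_i per gene per population, computed on intensities as given
(no log transform), sample sd with n−1. Genes with M ≤ 0 are flagged
undefined and excluded from comparisons (count reported) rather than
zero-filled. Group contrasts use the two-tailed Mann–Whitney U: exact
enumeration when both groups have ≤ 20 untied observations, otherwise the
tie-corrected normal approximation.

Between-population DE works on per-gene population means: OLS of b on a
with intercept, then roles swapped. "Quartile normalization" of the
residuals is interpreted as a rank→normal-scores transform (Blom offsets,
(r − 3/8)/(n + 1/4)); after that transform the leverage structure of the
original fit no longer applies, so studentization uses the standard
internal→external t conversion at df = n−3. With the transform off, the
exact leave-one-out externally studentized residuals are used. A gene is
DE for a pair when |r̂| exceeds t_{1−α/2, n−3} in *either* direction
(union rule); the pair results union across all population pairs. Both
the transform and the df offset are switchable options. A consequence of
the rank transform: the flagged count per direction is essentially fixed
at ~α·n regardless of signal — the method identifies *which* genes are
most extreme, not *how many* are extreme — so recovery of many planted
genes requires the union over several pairs. Group DE proportions are
compared by Pearson chi-square (1 df, no continuity correction), with a
warning recommending Fisher's exact test when an expected cell is < 1.

### Variants and annotation

MAF = min(2N_AA + N_Aa, 2N_aa + N_Aa) / (2(N_AA + N_Aa + N_aa)). The
denominator is written as the full allele count so the two allele
frequencies sum to one; a printed variant of this formula omitting one
N_Aa term is treated as typographical. Intervals follow BED (0-based
half-open); SNP positions are 1-based, so position p overlaps
[start, end) iff start ≤ p−1 < end; strand is ignored. The interval join
is delegated to pyranges. MAF lists are compared per SNP (per-gene
aggregation available) with the pooled-variance t-test (Welch by flag).

GO scanning restricts both margins to annotated genes, tests each term's
2×2 with Fisher's exact two-tailed test (mass of tables no more probable
than observed, fixed margins), and flags p ≤ α with the direction of the
higher proportion. No multiple-testing correction is applied by default,
matching the raw-p convention of the source analyses; a Benjamini–
Hochberg helper is provided but off. Annotations are consumed flat — no
propagation up the GO graph. DER values (fraction of expression surveys
calling a gene differentially expressed) are consumed as a precomputed
table and compared between groups by rank-sum.

## Synthetic world

The generator emulates every input at one-tenth the scale of the analysed
human data, so the full pipeline runs in seconds:

| parameter | default | rationale |
|---|---|---|
| families × genes | 54 × 917 | 541 × 9,174 at 1/10 |
| degree distribution | truncated geometric, p = 0.138, max 30 | mean ≈ 6.9 regulators/gene ≈ 63,428/9,174 |
| CNV families | 17 | 172/10 |
| CNV labelling bias | 0 (uniform) | the null world; bias > 0 plants co-occurrence |
| populations | YRI 90, CEU 90, CHB 45, JPT 45 | the HapMap expression panel sizes |
| group CV targets | 0.0251 / 0.0258 / 0.0274 | the reported group means |
| planted DE | 46 genes (5%), shift 1.5× | ~the reported DE-fraction scale; one population each |
| MAF spectrum | uniform [0.05, 0.5] | HapMap ascertainment floor of 5% |
| GO terms | 41, base rates 0.02–0.15 | 412/10 |
| group DER means | 0.506 / 0.514 / 0.535 (Beta, conc. 40) | the reported group means |

Expression is per-gene log-normal baseline (log-mean 7, log-sd 0.5, i.e.
median ≈ 1,100 intensity units) times (1 + N(0, cv)) truncated positive;
cv ≥ 1 is rejected because truncation would distort the target. Genotypes
are multinomial Hardy–Weinberg (q², 2q(1−q), (1−q)²). A single master
seed spawns independent substreams per generator, so any one input can be
regenerated in isolation and all emitted files round-trip through the
package's readers.

What the generator does **not** emulate: probe-level noise and
normalisation artefacts, linkage disequilibrium, realistic genomic
coordinates or UTR lengths, correlated annotation structure (GO term
hierarchy), and the empirical degree correlations of real TargetScan
networks. A green test on this world establishes that the statistics are
computed correctly and calibrated under their stated nulls — not that the
biological conclusions transfer to any particular real dataset. The
real-data group sizes and survey means quoted above enter only as
generator *targets*; reproducing the published full-scale numbers
requires the original supplementary downloads and is out of desk scope.

## Numerical choices

- Sample sd (ddof = 1) throughout; normal fits report (mean, sd) pairs.
- Fisher's exact p via scipy, cross-checked in tests against a
  brute-force hypergeometric enumeration (exhaustive for table totals
  ≤ 20, seeded sample up to 60).
- Rank-sum: exact only for small untied samples, else tie-corrected
  asymptotic; identical inputs return p = 1.
- Degenerate inputs are explicit: zero-variance nulls → degenerate
  category, all-identical MAF lists → p = 1 with a warning, zero residual
  variance → empty DE set with a warning, M ≤ 0 → undefined CV.
- m (dosage balance) rounds to nearest integer, truncates at 0.
- Seeds: every stochastic routine takes one; the pipeline derives
  per-stage seeds (< 2³¹) from the master seed via SeedSequence spawning.

## Known limitations

- The relabelling null conditions only on the number of labelled
  families, not on miRNA genomic clustering or CNV length.
- The DE procedure thresholds studentized residuals gene-by-gene; it
  controls a per-gene outlier rate, not an FDR.
- The GO scan's Fisher test is conservative on discrete tables; its
  realised size sits below the nominal α (the calibration test asserts
  exactly that).
- `exclusive_subnetwork` is defined for exact k only; the pooled ≥5 bin
  has no single subnetwork.
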