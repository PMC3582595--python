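"""Minor allele frequency from genotype counts and SNP -> UTR assignment.

MAF for a biallelic SNP A/a with genotype counts (N_AA, N_Aa, N_aa):

    MAF = min(2*N_AA + N_Aa, 2*N_aa + N_Aa) / (2 * (N_AA + N_Aa + N_aa))

The denominator is the total allele count, so the two allele frequencies
sum to one.  Intervals follow the BED convention (0-based half-open);
SNP positions are 1-based (HapMap/VCF), so a SNP at position p overlaps
[start, end) when start <= p-1 < end.  Strand is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats


@dataclass(frozen=True)
class GenotypeCounts:
    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    region_tag: str  # "utr5" | "utr3"
    gene: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end: [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError("interval start must be >= 0")


@dataclass
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 1-based
    counts: dict[str, GenotypeCounts] = field(default_factory=dict)  # per population

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("SNP position is 1-based and must be >= 1")


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """MAF in [0, 0.5]; symmetric under allele relabelling."""
    n = counts.n_individuals
    if n == 0:
        raise ValueError("MAF undefined for zero individuals")
    allele1 = 2 * counts.n_AA + counts.n_Aa
    allele2 = 2 * counts.n_aa + counts.n_Aa
    return min(allele1, allele2) / (2 * n)


def overlap_snps(
    intervals: list[GenomicInterval], snps: list[SnpRecord]
) -> tuple[dict[str, list[tuple[str, str]]], list[str]]:
    """Assign SNPs to the UTR intervals containing them.

    Returns (assignments, unassigned): ``assignments`` maps snp_id to the
    list of (gene, region_tag) intervals covering it; SNPs overlapping
    nothing are listed in ``unassigned``.
    """
    if not intervals or not snps:
        return {}, [s.snp_id for s in snps]
    iv_df = pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in intervals],
            "Start": [iv.start for iv in intervals],
            "End": [iv.end for iv in intervals],
            "gene": [iv.gene for iv in intervals],
            "region_tag": [iv.region_tag for iv in intervals],
        }
    )
    snp_df = pd.DataFrame(
        {
            "Chromosome": [s.chrom for s in snps],
            "Start": [s.pos - 1 for s in snps],  # 1-based -> 0-based
            "End": [s.pos for s in snps],
            "snp_id": [s.snp_id for s in snps],
        }
    )
    joined = pr.PyRanges(snp_df).join(pr.PyRanges(iv_df)).df
    assignments: dict[str, list[tuple[str, str]]] = {}
    if len(joined):
        for row in joined.itertuples():
            assignments.setdefault(row.snp_id, []).append((row.gene, row.region_tag))
    unassigned = [s.snp_id for s in snps if s.snp_id not in assignments]
    return assignments, unassigned


def compare_maf_sets(mafs_a, mafs_b, welch: bool = False) -> float:
    """Two-sample two-tailed t-test p on two MAF lists (pooled variance by default)."""
    a = np.asarray(mafs_a, dtype=float)
    b = np.asarray(mafs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each MAF list needs >= 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all MAF values identical; p = 1", stacklevel=2)
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def read_bed_intervals(path) -> list[GenomicInterval]:
    """BED6-compatible UTR intervals; name field is 'gene|region_tag'."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str},
    )
    out = []
    for row in df.itertuples():
        gene, _, tag = row.name.partition("|")
        out.append(
            GenomicInterval(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                region_tag=tag or "utr3", gene=gene,
            )
        )
    return out


def read_snp_counts(path) -> list[SnpRecord]:
    """TSV with columns snp_id, chrom, pos, population, N_AA, N_Aa, N_aa."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos", "population", "N_AA", "N_Aa", "N_aa"}
    if not required.issubset(df.columns):
        raise ValueError(f"SNP table needs columns {sorted(required)}")
    records: dict[str, SnpRecord] = {}
    for row in df.itertuples():
        rec = records.get(row.snp_id)
        if rec is None:
            rec = records[row.snp_id] = SnpRecord(snp_id=row.snp_id, chrom=row.chrom, pos=int(row.pos))
        rec.counts[row.population] = GenotypeCounts(int(row.N_AA), int(row.N_Aa), int(row.N_aa))
    return list(records.values())


def maf_table(snps: list[SnpRecord]) -> pd.DataFrame:
    """Long table snp_id x population -> MAF."""
    rows = [
        {"snp_id": s.snp_id, "population": pop, "maf": minor_allele_frequency(c)}
        for s in snps
        for pop, c in sorted(s.counts.items())
        if c.n_individuals > 0
    ]
    return pd.DataFrame(rows, columns=["snp_id", "population", "maf"])
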