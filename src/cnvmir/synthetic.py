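"""Synthetic input generators for the whole pipeline.

Every stage of the analysis gets a no-download test bed: a bipartite
family->gene network with a configurable regulator-degree distribution,
CNV labels with tunable co-occurrence bias, per-population expression with
per-gene CV targets and planted differential-expression shifts,
Hardy-Weinberg genotypes at specified minor-allele frequencies, UTR
intervals hosting the SNPs, and GO/DER annotation tables with injectable
term enrichment.

Defaults emulate the analysed human data at one-tenth scale: 54 families x
917 genes with mean regulator degree ~6.9 (matching 63,428 edges over
9,174 targets), 17 CNV families (172/10), HapMap-sized expression panels
(YRI/CEU 90, CHB/JPT 45 samples), group CV targets 0.0251/0.0258/0.0274,
common-SNP MAFs uniform on [0.05, 0.5] (the HapMap ascertainment floor),
41 GO terms (412/10) and group DER means 0.506/0.514/0.535.

A single master seed drives independent per-generator substreams
(`numpy` SeedSequence spawning) so each input can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    EXCLUSIVE_CNV,
    EXCLUSIVE_NONCNV,
    MIXED,
    CnvAnnotation,
    RegulatoryNetwork,
    classify_targets,
)
from .expression import ExpressionMatrix
from .maf import GenomicInterval, GenotypeCounts, SnpRecord

# substream labels: hashed into the SeedSequence so generators are independent
_STREAMS = ("network", "cnv", "expression", "genotypes", "annotations", "der", "utrs", "de", "snp_pos")


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS.index(stream))))


@dataclass(frozen=True)
class DegreeSpec:
    """Truncated geometric distribution over per-gene regulator counts.

    P(d) proportional to (1-p)^(d-1) * p on d = 1..max_degree.  The default
    (p = 0.138, max 30) has mean ~6.9 regulators per gene.
    """

    p: float = 0.138
    max_degree: int = 30

    def pmf(self) -> np.ndarray:
        d = np.arange(1, self.max_degree + 1)
        w = (1 - self.p) ** (d - 1) * self.p
        return w / w.sum()


@dataclass
class SyntheticConfig:
    n_families: int = 54
    n_genes: int = 917
    degree_spec: DegreeSpec = field(default_factory=DegreeSpec)
    n_cnv: int = 17
    cnv_bias: float = 0.0
    populations: dict = field(
        default_factory=lambda: {"YRI": 90, "CEU": 90, "CHB": 45, "JPT": 45}
    )
    cv_targets: dict = field(
        default_factory=lambda: {
            EXCLUSIVE_NONCNV: 0.0251,
            MIXED: 0.0258,
            EXCLUSIVE_CNV: 0.0274,
        }
    )
    n_de: int = 46
    de_shift: float = 1.5
    maf_range: tuple = (0.05, 0.5)
    n_snps: int = 400
    n_terms: int = 41
    base_rate_range: tuple = (0.02, 0.15)
    der_means: dict = field(
        default_factory=lambda: {
            "unregulated": 0.506,
            EXCLUSIVE_NONCNV: 0.514,
            MIXED: 0.535,
            EXCLUSIVE_CNV: 0.535,
        }
    )
    n_unregulated: int = 978
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cnv > self.n_families:
            raise ValueError("n_cnv cannot exceed n_families")
        if min(self.n_families, self.n_genes, self.n_terms) <= 0:
            raise ValueError("all counts must be positive")
        if self.de_shift <= 0:
            raise ValueError("de_shift must be > 0")


def make_network(
    n_families: int, n_genes: int, degree_spec: DegreeSpec, seed: int
) -> RegulatoryNetwork:
    """Each gene draws a regulator count, then that many distinct families."""
    if degree_spec.max_degree > n_families:
        raise ValueError("degree_spec max exceeds the family pool")
    rng = _rng_for(seed, "network")
    families = [f"mirF{i:03d}" for i in range(n_families)]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    pmf = degree_spec.pmf()
    degrees = rng.choice(np.arange(1, degree_spec.max_degree + 1), size=n_genes, p=pmf)
    edges = set()
    for g, d in zip(genes, degrees):
        for fi in rng.choice(n_families, size=int(d), replace=False):
            edges.add((families[fi], g))
    return RegulatoryNetwork(
        families={f for f, _ in edges} | set(families), genes=set(genes), edges=edges
    )


def label_cnv(
    network: RegulatoryNetwork, n_cnv: int, cnv_bias: float = 0.0, seed: int = 0
) -> CnvAnnotation:
    """Label n_cnv families as CNV.

    bias 0 draws uniformly without replacement.  bias > 0 labels
    sequentially, weighting each unlabelled family by
    1 + bias * (targets shared with already-labelled families), so
    co-regulating families are preferentially co-labelled — the alternative
    world in which CNV families cluster on shared targets.
    """
    families = sorted(network.families)
    if n_cnv > len(families):
        raise ValueError("n_cnv exceeds the number of families")
    rng = _rng_for(seed, "cnv")
    if n_cnv == 0:
        return CnvAnnotation(cnv_families=set())
    if cnv_bias == 0:
        picked = rng.choice(len(families), size=n_cnv, replace=False)
        return CnvAnnotation(cnv_families={families[i] for i in picked})

    targets_of = {f: set() for f in families}
    for fam, gene in network.edges:
        targets_of[fam].add(gene)
    labelled: list[str] = [families[rng.integers(len(families))]]
    remaining = [f for f in families if f != labelled[0]]
    covered = set(targets_of[labelled[0]])
    while len(labelled) < n_cnv:
        weights = np.array(
            [1.0 + cnv_bias * len(targets_of[f] & covered) for f in remaining]
        )
        pick = rng.choice(len(remaining), p=weights / weights.sum())
        fam = remaining.pop(pick)
        labelled.append(fam)
        covered |= targets_of[fam]
    return CnvAnnotation(cnv_families=set(labelled))


def make_expression(
    genes: list[str],
    populations: dict[str, int],
    cv_of,
    seed: int = 0,
    de_genes: dict[str, str] | None = None,
    de_shift: float = 1.5,
    baseline_log_mean: float = 7.0,
    baseline_log_sd: float = 0.5,
) -> ExpressionMatrix:
    """Per-gene log-normal baselines with multiplicative Gaussian noise.

    value = baseline * (1 + N(0, cv)) truncated positive, so the realised
    per-gene CV tracks the target.  ``cv_of`` is a scalar or a gene -> cv
    map; targets must be < 1 (heavier truncation would distort them).
    ``de_genes`` maps gene -> the population whose baseline is multiplied
    by ``de_shift`` (a planted between-population expression difference).
    """
    rng = _rng_for(seed, "expression")
    genes = list(genes)
    cv = (
        np.full(len(genes), float(cv_of))
        if np.isscalar(cv_of)
        else np.array([float(cv_of[g]) for g in genes])
    )
    if (cv < 0).any() or (cv >= 1).any():
        raise ValueError("cv targets must lie in [0, 1)")
    de_genes = de_genes or {}
    baselines = rng.lognormal(baseline_log_mean, baseline_log_sd, size=len(genes))
    sample_ids, pop_labels = [], []
    for pop, n in populations.items():
        sample_ids += [f"{pop}_{i:03d}" for i in range(n)]
        pop_labels += [pop] * n
    blocks = []
    for gi, g in enumerate(genes):
        row = np.empty(len(sample_ids))
        col = 0
        for pop, n in populations.items():
            base = baselines[gi] * (de_shift if de_genes.get(g) == pop else 1.0)
            vals = base * (1.0 + rng.normal(0.0, cv[gi], size=n))
            row[col : col + n] = np.clip(vals, 1e-9, None)
            col += n
        blocks.append(row)
    values = pd.DataFrame(np.vstack(blocks), index=genes, columns=sample_ids)
    return ExpressionMatrix(
        values=values, population_of=pd.Series(pop_labels, index=sample_ids)
    )


def make_genotypes(
    n_snps: int,
    maf_range: tuple[float, float],
    n_individuals,
    seed: int = 0,
    positions: list[tuple[str, int]] | None = None,
) -> list[SnpRecord]:
    """Hardy-Weinberg genotype counts at uniformly drawn MAFs.

    Per SNP, q ~ U(maf_range); per population of n individuals, genotype
    counts are multinomial with probabilities (q^2, 2q(1-q), (1-q)^2) for
    the minor allele.  ``n_individuals`` is an int (single population
    "ALL") or a population -> size map.  ``positions`` optionally places
    the SNPs; the default is consecutive positions on chr1.
    """
    lo, hi = maf_range
    if not (0 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within [0, 0.5]")
    pops = {"ALL": int(n_individuals)} if np.isscalar(n_individuals) else dict(n_individuals)
    if min(pops.values()) < 1:
        raise ValueError("need >= 1 individual per population")
    rng = _rng_for(seed, "genotypes")
    records = []
    for i in range(n_snps):
        q = rng.uniform(lo, hi)
        chrom, pos = positions[i] if positions else ("chr1", i + 1)
        rec = SnpRecord(snp_id=f"rs{i:06d}", chrom=chrom, pos=pos)
        for pop, n in pops.items():
            counts = rng.multinomial(n, [q * q, 2 * q * (1 - q), (1 - q) ** 2])
            rec.counts[pop] = GenotypeCounts(*map(int, counts))
        records.append(rec)
    return records


def make_utrs(
    genes: list[str], seed: int = 0, utr5_len: int = 200, utr3_len: int = 1000
) -> list[GenomicInterval]:
    """Toy gene layout: each gene gets a 5'UTR and 3'UTR on one of 22 chromosomes."""
    rng = _rng_for(seed, "utrs")
    cursors = {f"chr{i}": 0 for i in range(1, 23)}
    out = []
    for g in genes:
        chrom = f"chr{rng.integers(1, 23)}"
        start = cursors[chrom] + int(rng.integers(100, 1000))
        body = int(rng.integers(2000, 20000))
        out.append(GenomicInterval(chrom, start, start + utr5_len, "utr5", g))
        out.append(
            GenomicInterval(chrom, start + utr5_len + body, start + utr5_len + body + utr3_len, "utr3", g)
        )
        cursors[chrom] = start + utr5_len + body + utr3_len
    return out


def make_annotations(
    genes: list[str],
    n_terms: int,
    seed: int = 0,
    base_rate_range: tuple[float, float] = (0.02, 0.15),
    planted: list[tuple[str, set, float, float]] | None = None,
) -> dict[str, set[str]]:
    """Independent per-term annotation with optional planted enrichment.

    Background terms annotate each gene independently at a per-term base
    rate drawn from ``base_rate_range``.  Each planted entry
    (term, gene_subset, prob_in, prob_out) annotates subset members with
    probability prob_in and everything else with prob_out.
    """
    lo, hi = base_rate_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("base rates must lie in [0, 1]")
    rng = _rng_for(seed, "annotations")
    out: dict[str, set[str]] = {g: set() for g in genes}
    for t in range(n_terms):
        rate = rng.uniform(lo, hi)
        hits = rng.random(len(genes)) < rate
        term = f"GO:{t:07d}"
        for g, h in zip(genes, hits):
            if h:
                out[g].add(term)
    for term, subset, prob_in, prob_out in planted or []:
        if not (0 <= prob_in <= 1 and 0 <= prob_out <= 1):
            raise ValueError("planted proportions must lie in [0, 1]")
        for g in genes:
            p = prob_in if g in subset else prob_out
            if rng.random() < p:
                out[g].add(term)
    return {g: terms for g, terms in out.items() if terms}


def make_der(
    groups: dict[str, set[str]],
    means: dict[str, float],
    seed: int = 0,
    concentration: float = 40.0,
) -> pd.Series:
    """Beta-distributed DER values per group with the given means."""
    rng = _rng_for(seed, "der")
    idx, vals = [], []
    for name, genes in groups.items():
        mu = means[name]
        a, b = mu * concentration, (1 - mu) * concentration
        draws = rng.beta(a, b, size=len(genes))
        idx += sorted(genes)
        vals += list(draws)
    return pd.Series(vals, index=idx, name="der")


@dataclass
class SyntheticBundle:
    """In-memory view of one generated world."""

    config: SyntheticConfig
    network: RegulatoryNetwork
    cnv: CnvAnnotation
    expression: ExpressionMatrix
    de_genes: dict[str, str]
    snps: list[SnpRecord]
    utrs: list[GenomicInterval]
    annotations: dict[str, set[str]]
    der: pd.Series


def generate_bundle(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate every pipeline input from one config and master seed."""
    config = config or SyntheticConfig()
    seed = config.seed if seed is None else seed
    network = make_network(config.n_families, config.n_genes, config.degree_spec, seed)
    cnv = label_cnv(network, config.n_cnv, config.cnv_bias, seed)
    cls = classify_targets(network, cnv)
    genes = sorted(network.genes)

    cv_of = {g: config.cv_targets[cls.group_of[g]] for g in genes}
    rng = _rng_for(seed, "de")
    pops = list(config.populations)
    de_pick = rng.choice(len(genes), size=min(config.n_de, len(genes)), replace=False)
    de_genes = {genes[i]: pops[int(rng.integers(len(pops)))] for i in de_pick}
    expression = make_expression(
        genes, config.populations, cv_of, seed=seed, de_genes=de_genes, de_shift=config.de_shift
    )

    utrs = make_utrs(genes, seed=seed)
    utr_by_gene = {}
    for iv in utrs:
        utr_by_gene.setdefault(iv.gene, []).append(iv)
    pos_rng = _rng_for(seed, "snp_pos")
    positions = []
    host_genes = [genes[i] for i in pos_rng.integers(0, len(genes), size=config.n_snps)]
    for g in host_genes:
        iv = utr_by_gene[g][int(pos_rng.integers(len(utr_by_gene[g])))]
        positions.append((iv.chrom, int(pos_rng.integers(iv.start, iv.end)) + 1))
    snps = make_genotypes(
        config.n_snps, config.maf_range, config.populations, seed=seed, positions=positions
    )

    annotations = make_annotations(genes, config.n_terms, seed=seed, base_rate_range=config.base_rate_range)

    der_groups = {name: cls.genes_in(name) for name in (EXCLUSIVE_CNV, MIXED, EXCLUSIVE_NONCNV)}
    der_groups = {k: v for k, v in der_groups.items() if v}
    der_groups["unregulated"] = {f"U{i:04d}" for i in range(config.n_unregulated)}
    der = make_der(der_groups, config.der_means, seed=seed)

    return SyntheticBundle(
        config=config,
        network=network,
        cnv=cnv,
        expression=expression,
        de_genes=de_genes,
        snps=snps,
        utrs=utrs,
        annotations=annotations,
        der=der,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write all inputs as the plain-text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "cnv": outdir / "cnv.txt",
        "expr": outdir / "expr.tsv",
        "pops": outdir / "pops.tsv",
        "snps": outdir / "snps.tsv",
        "utrs": outdir / "utrs.bed",
        "go": outdir / "go.tsv",
        "der": outdir / "der.tsv",
    }
    bundle.network.write_edge_list(paths["edges"])
    paths["cnv"].write_text("".join(f"{f}\n" for f in sorted(bundle.cnv.cnv_families)))
    bundle.expression.write(paths["expr"], paths["pops"])

    snp_rows = [
        {
            "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos, "population": pop,
            "N_AA": c.n_AA, "N_Aa": c.n_Aa, "N_aa": c.n_aa,
        }
        for s in bundle.snps
        for pop, c in sorted(s.counts.items())
    ]
    pd.DataFrame(snp_rows).to_csv(paths["snps"], sep="\t", index=False)

    with open(paths["utrs"], "w") as fh:
        for iv in bundle.utrs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}|{iv.region_tag}\t0\t+\n")

    go_rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(bundle.annotations)
        for t in sorted(bundle.annotations[g])
    ]
    pd.DataFrame(go_rows).to_csv(paths["go"], sep="\t", index=False)
    bundle.der.rename_axis("gene_id").reset_index().to_csv(paths["der"], sep="\t", index=False)

    manifest = {
        "seed": bundle.config.seed,
        "config": asdict(bundle.config),
        "files": {k: p.name for k, p in paths.items()},
        "de_genes": bundle.de_genes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {k: str(p) for k, p in paths.items()}
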