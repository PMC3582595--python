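"""Pseudo-CNV relabelling null for target-recognition preference.

Repeatedly draws a fixed-size random subset of families, pretends it is the
CNV set, re-classifies every gene, and records per-category gene counts.
A normal distribution fitted to the replicate counts yields a Z-score and a
one-tailed normal p-value for the observed count of each category (the
spreadsheet-style NORMDIST transform: p = Phi(-|z|)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import (
    EXCLUSIVE_CNV,
    EXCLUSIVE_NONCNV,
    K_CAP,
    CnvAnnotation,
    RegulatoryNetwork,
    classify_targets,
)

#: the Table-1-shaped category layout: both exclusive groups, k = 1..4 and ">=5"
DEFAULT_CATEGORIES: tuple[tuple[str, int], ...] = tuple(
    (grp, k) for grp in (EXCLUSIVE_CNV, EXCLUSIVE_NONCNV) for k in range(1, K_CAP + 1)
)


class DegenerateNullError(ValueError):
    """Replicate counts have zero spread; Z/p are undefined for the category."""


@dataclass
class NullDistribution:
    """One Table-1 row: the null fit and (optionally) the observed score."""

    category: tuple[str, int]
    replicate_counts: np.ndarray
    mean: float
    sd: float
    observed: int | None = None
    z: float | None = None
    p: float | None = None
    degenerate: bool = False

    def empirical_p(self) -> float:
        """One-tailed empirical tail probability with the +1 correction."""
        if self.observed is None:
            raise ValueError("observed count not set")
        r = np.asarray(self.replicate_counts)
        if self.observed >= self.mean:
            extreme = int(np.sum(r >= self.observed))
        else:
            extreme = int(np.sum(r <= self.observed))
        return (extreme + 1) / (len(r) + 1)


@dataclass
class _IndexedNetwork:
    """Flat arrays for fast per-replicate classification."""

    families: list[str]
    genes: list[str]
    fam_idx: np.ndarray  # family index per edge, grouped by gene
    offsets: np.ndarray  # start offset of each gene's edge block
    degree: np.ndarray  # regulator count per gene
    kbin: np.ndarray  # degree capped at K_CAP

    @classmethod
    def from_network(cls, network: RegulatoryNetwork) -> "_IndexedNetwork":
        families = sorted(network.families)
        genes = sorted(network.genes)
        fpos = {f: i for i, f in enumerate(families)}
        gpos = {g: i for i, g in enumerate(genes)}
        gi = np.fromiter((gpos[g] for _, g in network.edges), dtype=np.int64, count=len(network.edges))
        fi = np.fromiter((fpos[f] for f, _ in network.edges), dtype=np.int64, count=len(network.edges))
        order = np.argsort(gi, kind="stable")
        gi, fi = gi[order], fi[order]
        degree = np.bincount(gi, minlength=len(genes))
        offsets = np.concatenate(([0], np.cumsum(degree)[:-1]))
        return cls(
            families=families,
            genes=genes,
            fam_idx=fi,
            offsets=offsets,
            degree=degree,
            kbin=np.minimum(degree, K_CAP),
        )

    def category_counts(self, cnv_mask: np.ndarray) -> dict[tuple[str, int], int]:
        """Gene counts per (group, k) for one family labelling."""
        hits = np.add.reduceat(cnv_mask[self.fam_idx].astype(np.int64), self.offsets)
        out: dict[tuple[str, int], int] = {}
        excl_cnv = hits == self.degree
        excl_non = hits == 0
        cnv_tally = np.bincount(self.kbin[excl_cnv], minlength=K_CAP + 1)
        non_tally = np.bincount(self.kbin[excl_non], minlength=K_CAP + 1)
        for k in range(1, K_CAP + 1):
            out[(EXCLUSIVE_CNV, k)] = int(cnv_tally[k])
            out[(EXCLUSIVE_NONCNV, k)] = int(non_tally[k])
        return out


def simulate_null_distributions(
    network: RegulatoryNetwork,
    n_pseudo: int,
    reps: int,
    seed: int,
    categories: list[tuple[str, int]] | None = None,
) -> dict[tuple[str, int], NullDistribution]:
    """Fixed-size pseudo-CNV relabelling null.

    Each replicate samples ``n_pseudo`` families uniformly without
    replacement, classifies every gene against that labelling, and records
    the gene count of each requested (group, k) category.  Returns per
    category the raw replicate counts and a normal fit (mean, sample sd).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    idx = _IndexedNetwork.from_network(network)
    m = len(idx.families)
    if not 0 <= n_pseudo <= m:
        raise ValueError(f"n_pseudo must be in [0, {m}], got {n_pseudo}")
    cats = list(categories) if categories is not None else list(DEFAULT_CATEGORIES)

    rng = np.random.default_rng(seed)
    counts = {c: np.empty(reps, dtype=np.int64) for c in cats}
    mask = np.zeros(m, dtype=bool)
    for r in range(reps):
        mask[:] = False
        mask[rng.choice(m, size=n_pseudo, replace=False)] = True
        per_cat = idx.category_counts(mask)
        for c in cats:
            counts[c][r] = per_cat[c]

    out = {}
    for c in cats:
        v = counts[c]
        out[c] = NullDistribution(
            category=c,
            replicate_counts=v,
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)),
        )
    return out


def tail_probability(observed: float, mean: float, sd: float) -> tuple[float, float]:
    """Z-score and one-tailed normal tail probability p = Phi(-|z|)."""
    if sd <= 0:
        raise DegenerateNullError(f"null sd must be positive, got {sd}")
    z = (observed - mean) / sd
    p = float(stats.norm.cdf(-abs(z)))
    return z, p


def enrichment_table(
    network: RegulatoryNetwork,
    cnv: CnvAnnotation,
    reps: int = 1000,
    seed: int = 0,
    categories: list[tuple[str, int]] | None = None,
) -> list[NullDistribution]:
    """Observed-versus-null table over the standard category layout.

    n_pseudo is the number of annotated families actually present in the
    network.  Categories whose null collapses (sd = 0) are flagged
    ``degenerate`` with z/p left unset.
    """
    n_pseudo = len(cnv.cnv_families & network.families)
    nulls = simulate_null_distributions(network, n_pseudo, reps, seed, categories)
    observed_cls = classify_targets(network, cnv)
    tallies = {
        EXCLUSIVE_CNV: observed_cls.per_k_tally(EXCLUSIVE_CNV),
        EXCLUSIVE_NONCNV: observed_cls.per_k_tally(EXCLUSIVE_NONCNV),
    }
    rows = []
    for cat, nd in nulls.items():
        grp, k = cat
        nd.observed = tallies[grp][k]
        if nd.sd > 0:
            nd.z, nd.p = tail_probability(nd.observed, nd.mean, nd.sd)
        else:
            nd.degenerate = True
        rows.append(nd)
    return rows


def analytic_expected_exclusive(network: RegulatoryNetwork, n_pseudo: int, k: int) -> float:
    """Closed-form null mean of the (exclusive pseudo-CNV, k) gene count.

    A gene with d regulators is exclusive-pseudo-CNV exactly when all d fall
    in the sampled set, which happens with hypergeometric probability
    prod_{i<d} (C-i)/(M-i) for C = n_pseudo draws from M families.  Summing
    over the genes in the k bin (k = K_CAP pools degrees >= K_CAP) gives the
    expected count.  Passing n_pseudo = M - C yields the exclusive-non-CNV
    expectation by symmetry.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = len(network.families)
    if not 0 <= n_pseudo <= m:
        raise ValueError(f"n_pseudo must be in [0, {m}]")
    degree = network.gene_degree()
    total = 0.0
    for d in degree.values():
        if min(d, K_CAP) != min(k, K_CAP):
            continue
        prob = 1.0
        for i in range(d):
            prob *= max(n_pseudo - i, 0) / (m - i)
        total += prob
    return total
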