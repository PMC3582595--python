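"""GO-term 2x2 enrichment scans and differential-expression-ratio comparisons.

The enrichment scan compares, term by term, the proportion of annotated
genes between two disjoint gene sets with Fisher's exact two-tailed test.
Genes without any annotation are excluded from both margins.  The DER
(differential expression ratio: the fraction of expression surveys calling
a gene differentially expressed) is consumed as a precomputed gene table
and compared between groups with the two-tailed rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import rank_sum_p


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 layout: a = term & setA, b = term & setB, c/d = the complements."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def fisher_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p: total hypergeometric mass of tables
    (fixed margins) no more probable than the observed one."""
    if table.a + table.b + table.c + table.d == 0:
        raise ValueError("all-zero contingency table")
    return float(
        stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")[1]
    )


def go_scan(
    annotations: dict[str, set[str]],
    set_a: set[str],
    set_b: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher comparison of annotation proportions between two sets.

    Margins are the *annotated* genes of each set (genes absent from the
    annotation map are dropped).  Output: one row per term annotating at
    least one gene of either margin, with columns term, N1, N2 (annotated
    set sizes), count/proportion per set, p, significant (p <= alpha), and
    direction ("set_a"/"set_b"/"tie" for the higher proportion).
    """
    if set_a & set_b:
        raise ValueError("set_a and set_b must be disjoint")
    if not annotations:
        raise ValueError("annotation map is empty")
    ann_a = {g for g in set_a if annotations.get(g)}
    ann_b = {g for g in set_b if annotations.get(g)}
    n1, n2 = len(ann_a), len(ann_b)
    terms: set[str] = set()
    for g in ann_a | ann_b:
        terms |= annotations[g]
    rows = []
    for term in sorted(terms):
        ka = sum(1 for g in ann_a if term in annotations[g])
        kb = sum(1 for g in ann_b if term in annotations[g])
        p = fisher_two_tailed(ContingencyTable(ka, kb, n1 - ka, n2 - kb))
        pa = ka / n1 if n1 else 0.0
        pb = kb / n2 if n2 else 0.0
        rows.append(
            {
                "term": term,
                "N1": n1,
                "N2": n2,
                "count_a": ka,
                "count_b": kb,
                "proportion_a": pa,
                "proportion_b": pb,
                "p": p,
                "significant": p <= alpha,
                "direction": "set_a" if pa > pb else ("set_b" if pb > pa else "tie"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "N1", "N2", "count_a", "count_b",
            "proportion_a", "proportion_b", "p", "significant", "direction",
        ],
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (offered as an option; the scan reports raw p)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def compare_der_groups(
    der: dict[str, float] | pd.Series,
    groups: dict[str, set[str]],
) -> pd.DataFrame:
    """Pairwise rank-sum comparison of mean DER between gene groups.

    Returns one row per ordered group pair with the group mean DERs, sizes,
    and the two-tailed Mann-Whitney p.
    """
    der_s = pd.Series(der, dtype=float)
    if ((der_s < 0) | (der_s > 1)).any():
        raise ValueError("DER values must lie in [0, 1]")
    values: dict[str, np.ndarray] = {}
    for name, genes in groups.items():
        v = der_s.reindex(sorted(genes)).dropna().to_numpy()
        if len(v) == 0:
            raise ValueError(f"group {name!r} has no DER-covered gene")
        values[name] = v
    rows = []
    for na, nb in combinations(groups.keys(), 2):
        va, vb = values[na], values[nb]
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "n_a": len(va),
                "n_b": len(vb),
                "mean_a": float(np.mean(va)),
                "mean_b": float(np.mean(vb)),
                "p": rank_sum_p(va, vb),
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b", "p"])


def read_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV gene_id, term_id -> gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ValueError("annotation file needs columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.gene_id, set()).add(row.term_id)
    return out


def read_der_table(path) -> pd.Series:
    """Two-column TSV gene_id, der -> Series indexed by gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "der"}.issubset(df.columns):
        raise ValueError("DER file needs columns gene_id, der")
    return df.set_index("gene_id")["der"].astype(float)
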