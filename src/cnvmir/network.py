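"""Bipartite miRNA-family -> target-gene regulatory network.

The regulator unit is the miRNA *family* (miRNAs sharing a seed and hence
the same predicted sites).  A subset of families overlaps copy-number
variable (CNV) regions; target genes are classified by whether their
regulators are all CNV families ("exclusive_cnv"), none ("exclusive_noncnv"),
or a mixture ("mixed").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCLUSIVE_CNV = "exclusive_cnv"
MIXED = "mixed"
EXCLUSIVE_NONCNV = "exclusive_noncnv"
GROUPS = (EXCLUSIVE_CNV, MIXED, EXCLUSIVE_NONCNV)

#: per-k tallies pool everything at or above this regulator count
K_CAP = 5


class EdgeListFormatError(ValueError):
    """Malformed edge-list input (missing columns, bad values)."""


class EmptyNetworkError(ValueError):
    """All edges were removed by filtering, or the input held none."""


@dataclass(frozen=True)
class ReadStats:
    rows_read: int
    rows_kept: int
    duplicates_removed: int


@dataclass
class RegulatoryNetwork:
    """Bipartite family->gene edge set.

    ``edges`` is a set of (family, gene) pairs.  ``edge_attrs`` optionally
    carries per-edge (context_score, conserved_site) metadata; context
    scores are TargetScan-style (more negative = stronger predicted
    repression).
    """

    families: set[str]
    genes: set[str]
    edges: set[tuple[str, str]]
    edge_attrs: dict[tuple[str, str], dict] = field(default_factory=dict)
    read_stats: ReadStats | None = None

    def __post_init__(self) -> None:
        for fam, gene in self.edges:
            if fam not in self.families or gene not in self.genes:
                raise ValueError(f"edge ({fam}, {gene}) has endpoint outside node sets")
        touched = {g for _, g in self.edges}
        orphan = self.genes - touched
        if orphan:
            raise ValueError(f"{len(orphan)} genes have no incident edge, e.g. {sorted(orphan)[:3]}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def regulators_of(self, gene: str) -> set[str]:
        return {f for f, g in self.edges if g == gene}

    def gene_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {g: 0 for g in self.genes}
        for _, g in self.edges:
            deg[g] += 1
        return deg

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam, gene in sorted(self.edges):
            attrs = self.edge_attrs.get((fam, gene), {})
            rows.append(
                {
                    "family_id": fam,
                    "gene_id": gene,
                    "context_score": attrs.get("context_score", np.nan),
                    "conserved_site": attrs.get("conserved_site", np.nan),
                }
            )
        return pd.DataFrame(rows, columns=["family_id", "gene_id", "context_score", "conserved_site"])

    def write_edge_list(self, path) -> None:
        df = self.to_frame()
        # drop all-empty optional columns so round-trips stay minimal
        for col in ("context_score", "conserved_site"):
            if df.empty or df[col].isna().all():
                df = df.drop(columns=col)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CnvAnnotation:
    """Families whose members overlap CNV regions."""

    cnv_families: set[str]
    duplicates_in_input: int = 0

    def missing_from(self, network: RegulatoryNetwork) -> set[str]:
        """IDs in the annotation absent from the network (reported, never dropped)."""
        return self.cnv_families - network.families


@dataclass
class TargetClassification:
    group_of: dict[str, str]
    regulator_count: dict[str, int]
    cnv_regulator_count: dict[str, int]
    missing_cnv_families: set[str] = field(default_factory=set)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for grp in self.group_of.values():
            sizes[grp] += 1
        return sizes

    def per_k_tally(self, group: str) -> dict[int, int]:
        """Gene counts by regulator count k = 1..4, with K_CAP meaning ">=K_CAP"."""
        if group not in (EXCLUSIVE_CNV, EXCLUSIVE_NONCNV):
            raise ValueError(f"per-k tallies are defined for exclusive groups, not {group!r}")
        tally = {k: 0 for k in range(1, K_CAP + 1)}
        for gene, grp in self.group_of.items():
            if grp == group:
                tally[min(self.regulator_count[gene], K_CAP)] += 1
        return tally

    def genes_in(self, group: str, k: int | None = None) -> set[str]:
        out = set()
        for gene, grp in self.group_of.items():
            if grp != group:
                continue
            if k is None or min(self.regulator_count[gene], K_CAP) == min(k, K_CAP):
                out.add(gene)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "group": self.group_of[g],
                "regulator_count": self.regulator_count[g],
                "cnv_regulator_count": self.cnv_regulator_count[g],
            }
            for g in sorted(self.group_of)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "group", "regulator_count", "cnv_regulator_count"])


def read_edge_list(
    path,
    score_threshold: float | None = -0.3,
    keep_rule: str = "retain_at_or_below",
    require_conserved_site: bool = False,
) -> RegulatoryNetwork:
    """Load a TSV edge list into a :class:`RegulatoryNetwork`.

    Required columns: ``family_id``, ``gene_id``.  Optional: ``context_score``
    (TargetScan total context score), ``conserved_site`` (0/1), and
    ``family_map`` (miRNA->family collapse done here when present).

    ``keep_rule`` selects the filter direction because the convention is
    ambiguous in the literature: ``retain_at_or_below`` keeps scores
    <= threshold (more negative = stronger target, the conventional
    "reliable target" reading), ``retain_above`` keeps scores > threshold.
    """
    if keep_rule not in ("retain_at_or_below", "retain_above"):
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "gene_id"}
    if not required.issubset(df.columns):
        raise EdgeListFormatError(f"edge list must have columns {sorted(required)}; got {list(df.columns)}")
    rows_read = len(df)

    if "family_map" in df.columns:
        mapped = df["family_map"].fillna(df["family_id"])
        df = df.assign(family_id=mapped)

    df["family_id"] = df["family_id"].str.strip()
    df["gene_id"] = df["gene_id"].str.strip()

    if score_threshold is not None:
        if "context_score" not in df.columns:
            raise EdgeListFormatError("score_threshold given but no context_score column present")
        score = pd.to_numeric(df["context_score"], errors="coerce")
        if keep_rule == "retain_at_or_below":
            df = df[score <= score_threshold]
        else:
            df = df[score > score_threshold]
    if require_conserved_site:
        if "conserved_site" not in df.columns:
            raise EdgeListFormatError("require_conserved_site given but no conserved_site column present")
        df = df[pd.to_numeric(df["conserved_site"], errors="coerce") == 1]

    rows_kept = len(df)
    dedup = df.drop_duplicates(subset=["family_id", "gene_id"])
    duplicates = rows_kept - len(dedup)
    if dedup.empty:
        raise EmptyNetworkError("no edges remain after filtering")

    edges = set(zip(dedup["family_id"], dedup["gene_id"]))
    attrs: dict[tuple[str, str], dict] = {}
    if "context_score" in dedup.columns or "conserved_site" in dedup.columns:
        for _, row in dedup.iterrows():
            a = {}
            if "context_score" in dedup.columns and pd.notna(row["context_score"]):
                a["context_score"] = float(row["context_score"])
            if "conserved_site" in dedup.columns and pd.notna(row["conserved_site"]):
                a["conserved_site"] = bool(int(row["conserved_site"]))
            if a:
                attrs[(row["family_id"], row["gene_id"])] = a

    return RegulatoryNetwork(
        families={f for f, _ in edges},
        genes={g for _, g in edges},
        edges=edges,
        edge_attrs=attrs,
        read_stats=ReadStats(rows_read, rows_kept, duplicates),
    )


def read_cnv_families(path) -> CnvAnnotation:
    """One family ID per line; blanks ignored; duplicates collapsed with a count."""
    with open(path) as fh:
        ids = [line.strip() for line in fh]
    ids = [i for i in ids if i]
    unique = set(ids)
    dup = len(ids) - len(unique)
    if dup:
        warnings.warn(f"{dup} duplicate CNV family IDs collapsed", stacklevel=2)
    return CnvAnnotation(cnv_families=unique, duplicates_in_input=dup)


def classify_targets(network: RegulatoryNetwork, cnv: CnvAnnotation) -> TargetClassification:
    """Partition the network's genes by regulator type.

    A gene is ``exclusive_cnv`` when every regulator is a CNV family,
    ``exclusive_noncnv`` when none is, ``mixed`` otherwise.  CNV IDs absent
    from the network are reported on the result, not silently dropped.
    """
    if not network.genes:
        raise EmptyNetworkError("cannot classify an empty network")
    cnv_set = cnv.cnv_families & network.families
    reg_count: dict[str, int] = {g: 0 for g in network.genes}
    cnv_count: dict[str, int] = {g: 0 for g in network.genes}
    for fam, gene in network.edges:
        reg_count[gene] += 1
        if fam in cnv_set:
            cnv_count[gene] += 1
    group_of = {}
    for gene in network.genes:
        d, c = reg_count[gene], cnv_count[gene]
        if c == d:
            group_of[gene] = EXCLUSIVE_CNV
        elif c == 0:
            group_of[gene] = EXCLUSIVE_NONCNV
        else:
            group_of[gene] = MIXED
    return TargetClassification(
        group_of=group_of,
        regulator_count=reg_count,
        cnv_regulator_count=cnv_count,
        missing_cnv_families=cnv.missing_from(network),
    )


def exclusive_subnetwork(
    network: RegulatoryNetwork,
    cnv: CnvAnnotation,
    classification: TargetClassification,
    group: str,
    k: int,
) -> RegulatoryNetwork:
    """Induced subnetwork of genes in ``group`` with exactly ``k`` regulators.

    For the exclusive groups the edge count is forced to k x (number of
    genes) because every retained gene keeps all of its regulators.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = {
        g
        for g, grp in classification.group_of.items()
        if grp == group and classification.regulator_count[g] == k
    }
    edges = {(f, g) for f, g in network.edges if g in keep}
    return RegulatoryNetwork(
        families={f for f, _ in edges},
        genes={g for _, g in edges},
        edges=edges,
        edge_attrs={e: network.edge_attrs[e] for e in edges if e in network.edge_attrs},
    )
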