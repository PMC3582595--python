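"""End-to-end orchestration: classification -> resampling null -> dosage
balance -> CV -> between-population DE -> MAF -> DER -> GO.

Driven by one configuration mapping (or YAML file) holding input paths and
parameters.  Stages whose inputs are missing are skipped with a logged
reason; every stochastic stage receives an explicit seed derived from the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
import json

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import (
    EXCLUSIVE_CNV,
    EXCLUSIVE_NONCNV,
    GROUPS,
    MIXED,
    K_CAP,
    classify_targets,
    exclusive_subnetwork,
    read_cnv_families,
    read_edge_list,
)
from .resampling import enrichment_table
from .dosage import NormalSpec, run_dosage_balance
from .expression import ExpressionMatrix, compare_cv_groups, cv_table
from .popde import de_union, detect_de_pair, proportion_chi_square
from .maf import compare_maf_sets, maf_table, overlap_snps, read_bed_intervals, read_snp_counts
from .enrichment import compare_der_groups, go_scan, read_annotations, read_der_table

DEFAULT_PARAMS = {
    "score_threshold": None,
    "keep_rule": "retain_at_or_below",
    "require_conserved_site": False,
    "reps": 1000,
    "alpha": 0.05,
    "quartile_normalize": True,
    "seed": 0,
}

#: ordered pairs for group-level comparisons (weakest to strongest regulation by CNV families)
GROUP_PAIRS = (
    (EXCLUSIVE_NONCNV, MIXED),
    (MIXED, EXCLUSIVE_CNV),
    (EXCLUSIVE_NONCNV, EXCLUSIVE_CNV),
)


@dataclass
class PipelineReport:
    sections: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def section(self, name: str) -> pd.DataFrame:
        if name in self.skipped:
            raise KeyError(f"stage {name!r} was skipped: {self.skipped[name]}")
        return self.sections[name]


def load_config(path_or_mapping) -> dict:
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_mapping)
    cfg.setdefault("inputs", {})
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    return cfg


def _seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(2)
    return {
        "nullsim": int(children[0].generate_state(1)[0] % 2**31),
        "dosage": int(children[1].generate_state(1)[0] % 2**31),
    }


def run_full_analysis(config) -> PipelineReport:
    """Run every stage the configured inputs allow.  See module docstring."""
    cfg = load_config(config)
    inputs, params = cfg["inputs"], cfg["params"]
    seeds = _seeds(int(params["seed"]))
    report = PipelineReport(
        provenance={
            "version": __version__,
            "inputs": {k: str(v) for k, v in inputs.items()},
            "params": dict(params),
            "seeds": seeds,
        }
    )

    # --- classification ---------------------------------------------------
    if not {"edges", "cnv"} <= set(inputs):
        report.skipped["classification"] = "edges/cnv inputs not provided"
        return report
    network = read_edge_list(
        inputs["edges"],
        score_threshold=params["score_threshold"],
        keep_rule=params["keep_rule"],
        require_conserved_site=params["require_conserved_site"],
    )
    cnv = read_cnv_families(inputs["cnv"])
    cls = classify_targets(network, cnv)
    sizes = cls.group_sizes()
    rows = [
        {"group": g, "k": "all", "genes": sizes[g]} for g in GROUPS
    ]
    for grp in (EXCLUSIVE_CNV, EXCLUSIVE_NONCNV):
        for k, count in cls.per_k_tally(grp).items():
            rows.append({"group": grp, "k": f">={K_CAP}" if k == K_CAP else str(k), "genes": count})
    report.sections["classification"] = pd.DataFrame(rows)
    report.provenance["network"] = {
        "families": len(network.families),
        "genes": len(network.genes),
        "edges": network.n_edges,
        "read_stats": vars(network.read_stats) if network.read_stats else None,
        "cnv_families_in_network": len(cnv.cnv_families & network.families),
        "cnv_families_missing": sorted(cls.missing_cnv_families),
    }

    # --- resampling null (observed-vs-null table) -------------------------
    reps = int(params["reps"])
    table = enrichment_table(network, cnv, reps=reps, seed=seeds["nullsim"])
    report.sections["enrichment"] = pd.DataFrame(
        [
            {
                "group": nd.category[0],
                "k": f">={K_CAP}" if nd.category[1] == K_CAP else str(nd.category[1]),
                "null_mean": nd.mean,
                "null_sd": nd.sd,
                "observed": nd.observed,
                "z": nd.z,
                "p": nd.p,
                "degenerate": nd.degenerate,
            }
            for nd in table
        ]
    )

    # --- dosage balance (genes with exactly two exclusive-CNV regulators) -
    k2 = next(nd for nd in table if nd.category == (EXCLUSIVE_CNV, 2))
    if k2.degenerate or k2.observed == 0:
        report.skipped["dosage"] = "degenerate or empty (exclusive_cnv, k=2) category"
    else:
        sub = exclusive_subnetwork(network, cnv, cls, EXCLUSIVE_CNV, 2)
        if not sub.families:
            report.skipped["dosage"] = "no families in the k=2 exclusive-CNV subnetwork"
        else:
            db = run_dosage_balance(
                network,
                observed=k2.observed,
                null=NormalSpec(k2.mean, k2.sd),
                n_cnv_in_subnetwork=len(sub.families),
                reps=reps,
                seed=seeds["dosage"],
            )
            report.sections["dosage"] = pd.DataFrame(
                [
                    {"quantity": "observed_k2_genes", "mean": k2.observed, "sd": 0.0},
                    {"quantity": "null", "mean": k2.mean, "sd": k2.sd},
                    {"quantity": "nonindependent", "mean": db.nonindependent.mean, "sd": db.nonindependent.sd},
                    {"quantity": "marked_families", "mean": db.marked_families.mean, "sd": db.marked_families.sd},
                    {"quantity": "retained", "mean": db.retained.mean, "sd": db.retained.sd},
                    {"quantity": "attributable_fraction", "mean": db.attributable_fraction, "sd": np.nan},
                ]
            )

    group_genes = {g: cls.genes_in(g) for g in GROUPS}

    # --- expression stages ------------------------------------------------
    if not {"expr", "pops"} <= set(inputs):
        report.skipped["cv"] = report.skipped["popde"] = "expr/pops inputs not provided"
        matrix = None
    else:
        matrix = ExpressionMatrix.read(inputs["expr"], inputs["pops"])
        cv = cv_table(matrix)
        rows = []
        for pop in matrix.populations:
            for ga, gb in GROUP_PAIRS:
                try:
                    mean_a, mean_b, p = compare_cv_groups(cv, pop, group_genes[ga], group_genes[gb])
                except ValueError as err:
                    report.skipped.setdefault("cv_notes", str(err))
                    continue
                rows.append(
                    {"population": pop, "group_a": ga, "group_b": gb,
                     "mean_cv_a": mean_a, "mean_cv_b": mean_b, "p": p}
                )
        report.sections["cv"] = pd.DataFrame(rows)

        means = matrix.population_means()
        pair_results = []
        for pa, pb in combinations(matrix.populations, 2):
            pair_results.append(
                detect_de_pair(
                    means[pa], means[pb],
                    alpha=float(params["alpha"]),
                    quartile_normalize=bool(params["quartile_normalize"]),
                    pair=(pa, pb),
                )
            )
        union, per_pair = de_union(pair_results)
        de_rows = [
            {"population_a": a, "population_b": b, "n_de": n}
            for (a, b), n in per_pair.items()
        ]
        de_rows.append({"population_a": "union", "population_b": "union", "n_de": len(union)})
        report.sections["popde_pairs"] = pd.DataFrame(de_rows)

        prop_rows = []
        for ga, gb in GROUP_PAIRS:
            ta, tb = group_genes[ga], group_genes[gb]
            if not ta or not tb:
                continue
            ha, hb = len(ta & union), len(tb & union)
            prop_rows.append(
                {
                    "group_a": ga, "group_b": gb,
                    "de_fraction_a": ha / len(ta), "de_fraction_b": hb / len(tb),
                    "p": proportion_chi_square(ha, len(ta), hb, len(tb)),
                }
            )
        report.sections["popde_proportions"] = pd.DataFrame(prop_rows)

    # --- MAF --------------------------------------------------------------
    if not {"snps", "utrs"} <= set(inputs):
        report.skipped["maf"] = "snps/utrs inputs not provided"
    else:
        snps = read_snp_counts(inputs["snps"])
        intervals = read_bed_intervals(inputs["utrs"])
        assignments, unassigned = overlap_snps(intervals, snps)
        mafs = maf_table(snps)
        snp_group: dict[str, set[str]] = {}
        snp_region: dict[str, set[str]] = {}
        for snp_id, hits in assignments.items():
            for gene, tag in hits:
                if gene in cls.group_of:
                    snp_group.setdefault(snp_id, set()).add(cls.group_of[gene])
                    snp_region.setdefault(snp_id, set()).add(tag)
        rows = []
        for region in ("utr5", "utr3"):
            for pop in sorted(mafs["population"].unique()):
                sets = {}
                for grp in (EXCLUSIVE_CNV, EXCLUSIVE_NONCNV):
                    ids = {
                        s for s in snp_group
                        if grp in snp_group[s] and region in snp_region[s]
                    }
                    sets[grp] = mafs[(mafs["snp_id"].isin(ids)) & (mafs["population"] == pop)]["maf"].to_numpy()
                if len(sets[EXCLUSIVE_CNV]) >= 2 and len(sets[EXCLUSIVE_NONCNV]) >= 2:
                    p = compare_maf_sets(sets[EXCLUSIVE_CNV], sets[EXCLUSIVE_NONCNV])
                    rows.append(
                        {
                            "region": region, "population": pop,
                            "n_cnv": len(sets[EXCLUSIVE_CNV]), "n_noncnv": len(sets[EXCLUSIVE_NONCNV]),
                            "mean_maf_cnv": float(np.mean(sets[EXCLUSIVE_CNV])),
                            "mean_maf_noncnv": float(np.mean(sets[EXCLUSIVE_NONCNV])),
                            "p": p,
                        }
                    )
        report.sections["maf"] = pd.DataFrame(rows)
        report.provenance["maf"] = {"snps": len(snps), "unassigned": len(unassigned)}

    # --- DER --------------------------------------------------------------
    if "der" not in inputs:
        report.skipped["der"] = "der input not provided"
    else:
        der = read_der_table(inputs["der"])
        targets = set(cls.group_of)
        der_groups = {
            "unregulated": set(der.index) - targets,
            EXCLUSIVE_NONCNV: group_genes[EXCLUSIVE_NONCNV],
            "cnv_targets": group_genes[MIXED] | group_genes[EXCLUSIVE_CNV],
        }
        der_groups = {k: v for k, v in der_groups.items() if v & set(der.index)}
        report.sections["der"] = compare_der_groups(der, der_groups)

    # --- GO ---------------------------------------------------------------
    if "go" not in inputs:
        report.skipped["go"] = "go input not provided"
    else:
        annotations = read_annotations(inputs["go"])
        if group_genes[EXCLUSIVE_CNV] and group_genes[EXCLUSIVE_NONCNV]:
            report.sections["go"] = go_scan(
                annotations,
                group_genes[EXCLUSIVE_CNV],
                group_genes[EXCLUSIVE_NONCNV],
                alpha=float(params["alpha"]),
            )
        else:
            report.skipped["go"] = "an exclusive group is empty"

    return report


def write_report(report: PipelineReport, outdir) -> dict[str, str]:
    """One TSV per section, a manifest, and a human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in report.sections.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    manifest = {
        "provenance": report.provenance,
        "sections": sorted(report.sections),
        "skipped": report.skipped,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    lines = ["pipeline summary", "================"]
    for name in report.sections:
        lines.append(f"section {name}: {len(report.sections[name])} rows -> {name}.tsv")
    for name, why in report.skipped.items():
        lines.append(f"skipped {name}: {why}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
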