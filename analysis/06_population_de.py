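"""Between-population differential expression of the target groups.

Per population pair, regresses per-gene mean intensities reciprocally,
rank-normalises and studentizes the residuals, and flags genes outside the
95% t interval in either direction.  The union over all six pairs is the
DE gene set; its proportion is then compared across target groups with the
two-tailed chi-square test.
"""

import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from cnvmir.expression import ExpressionMatrix
from cnvmir.network import classify_targets, read_cnv_families, read_edge_list
from cnvmir.pipeline import GROUP_PAIRS
from cnvmir.popde import de_union, detect_de_pair, proportion_chi_square

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    network = read_edge_list(DATA / "edges.tsv", score_threshold=None)
    cnv = read_cnv_families(DATA / "cnv.txt")
    cls = classify_targets(network, cnv)
    matrix = ExpressionMatrix.read(DATA / "expr.tsv", DATA / "pops.tsv")
    means = matrix.population_means()

    results = [
        detect_de_pair(means[a], means[b], alpha=args.alpha, pair=(a, b))
        for a, b in combinations(matrix.populations, 2)
    ]
    union, per_pair = de_union(results)
    pairs = pd.DataFrame(
        [{"population_a": a, "population_b": b, "n_de": n} for (a, b), n in per_pair.items()]
    )
    pairs.to_csv(ROOT / "results" / "de_pairs.tsv", sep="\t", index=False)
    print(pairs.to_string(index=False))
    print(f"union: {len(union)} genes DE in at least one pair "
          f"({len(union) / len(network.genes):.1%} of targets)")

    rows = []
    for ga, gb in GROUP_PAIRS:
        ta, tb = cls.genes_in(ga), cls.genes_in(gb)
        ha, hb = len(ta & union), len(tb & union)
        rows.append({"group_a": ga, "group_b": gb,
                     "de_fraction_a": ha / len(ta), "de_fraction_b": hb / len(tb),
                     "p": proportion_chi_square(ha, len(ta), hb, len(tb))})
    props = pd.DataFrame(rows)
    props.to_csv(ROOT / "results" / "de_proportions.tsv", sep="\t", index=False)
    print(props.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
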