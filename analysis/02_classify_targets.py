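"""Classify target genes by regulator type.

Reads the edge list and CNV family list from results/data/, partitions the
genes into exclusively-CNV / mixed / exclusively-non-CNV groups, tallies the
exclusive groups by regulator count k (1..4, >=5), and writes per-gene
labels plus the summary to results/.
"""

from pathlib import Path

from cnvmir.network import (
    EXCLUSIVE_CNV,
    EXCLUSIVE_NONCNV,
    classify_targets,
    read_cnv_families,
    read_edge_list,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    network = read_edge_list(DATA / "edges.tsv", score_threshold=None)
    cnv = read_cnv_families(DATA / "cnv.txt")
    cls = classify_targets(network, cnv)

    cls.to_frame().to_csv(ROOT / "results" / "classification.tsv", sep="\t", index=False)
    sizes = cls.group_sizes()
    print(f"{len(network.genes)} genes partitioned: "
          + ", ".join(f"{g}={n}" for g, n in sizes.items()))
    for grp in (EXCLUSIVE_CNV, EXCLUSIVE_NONCNV):
        tally = cls.per_k_tally(grp)
        print(f"  {grp} by k: " + ", ".join(f"k={k}:{v}" for k, v in tally.items()))
    if cls.missing_cnv_families:
        print(f"  note: {len(cls.missing_cnv_families)} CNV IDs absent from the network")
    print("wrote results/classification.tsv")


if __name__ == "__main__":
    main()
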