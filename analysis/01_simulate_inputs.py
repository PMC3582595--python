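"""Generate the synthetic input bundle every later step consumes.

Writes edges.tsv, cnv.txt, expr.tsv, pops.tsv, snps.tsv, utrs.bed, go.tsv,
der.tsv and a manifest to results/data/.  The world is the default
one-tenth-scale configuration: 54 miRNA families x 917 target genes
(mean regulator degree ~6.9), 17 CNV-labelled families, four HapMap-sized
expression panels with group CV targets 0.0251/0.0258/0.0274, common-SNP
genotypes, and GO/DER tables with group DER means 0.506/0.514/0.535.
"""

import argparse
from pathlib import Path

from cnvmir.synthetic import SyntheticConfig, generate_bundle, write_bundle

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--cnv-bias", type=float, default=0.0,
                        help="co-occurrence bias of the CNV labelling (0 = uniform null)")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    config = SyntheticConfig(seed=args.seed, cnv_bias=args.cnv_bias)
    bundle = generate_bundle(config)
    paths = write_bundle(bundle, args.outdir)
    print(f"network: {len(bundle.network.families)} families, "
          f"{len(bundle.network.genes)} genes, {bundle.network.n_edges} edges")
    print(f"CNV families: {len(bundle.cnv.cnv_families)} (bias {args.cnv_bias})")
    print(f"wrote {len(paths)} files to {args.outdir}")


if __name__ == "__main__":
    main()
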