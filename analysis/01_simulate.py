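#!/usr/bin/env python
"""Stage 1: generate the synthetic study dataset.

Emits the in-vitro site catalog (log-normal ppm affinities), chromatin
domain mosaics (H3K9me2, H3K9me3, cLAD), genes with expression, in-vivo
peak tracks from the logistic barrier-activation model, SNPs enriched at
active motifs, the motif-implanted genome FASTA and the fragment-pileup
coverage track. Later stages reconstruct the same dataset in memory from
the seed; the files written here are the on-disk record of the run.
"""

import argparse
from pathlib import Path

from hotscan import SynthConfig, simulate_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/analysis/synthetic"))
    args = ap.parse_args()

    config = SynthConfig(seed=args.seed, write_fasta=True, coverage_depth=50)
    truth = simulate_dataset(config, args.out)

    n = len(truth.sites)
    print(f"generated {n} binding sites on "
          f"{len(config.genome)} chromosomes ({config.genome_obj.total_bp/1e6:.0f} Mb)")
    print(f"activated in vivo: {truth.activated.sum()} "
          f"({100*truth.activated.mean():.1f} %), "
          f"median affinity {truth.sites.df['score'].median():.2f} ppm")
    for name, dom in truth.domains.items():
        frac = dom.total_bp() / config.genome_obj.total_bp
        print(f"  {name}: {len(dom)} segments, {100*frac:.1f} % of genome")
    print(f"  genes: {len(truth.genes)} ({100*truth.genes.total_bp()/config.genome_obj.total_bp:.1f} %)")
    print(f"SNPs: {len(truth.snps)}; outputs in {args.out}")


if __name__ == "__main__":
    main()
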