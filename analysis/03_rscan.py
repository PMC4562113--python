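#!/usr/bin/env python
"""Stage 3: r-scan scan for hotspot-deficient regions.

Tests the in-vivo site positions against replicate draws from the full
in-vitro catalog (the background), so depletion reflects failed activation
rather than missing binding sites; called regions are then cross-referenced
against catalog site density to confirm they are truly usage-deficient.
"""

import argparse
from pathlib import Path

from hotscan import SynthConfig, simulate_dataset
from hotscan.classify import classify_sites
from hotscan.intervals import IntervalSet, write_bed
from hotscan.rscan import (RscanConfig, call_deficient_regions,
                           cross_reference_deficiency, positions_from_intervals)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-null", type=int, default=2000)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = simulate_dataset(SynthConfig(seed=args.seed))
    cls = classify_sites(truth.sites, truth.peaks["h3k4me3_a"],
                         truth.peaks["h3k4me3_b"], truth.peaks["dmc1"])
    in_vivo = IntervalSet("in_vivo", cls.sites[cls.sites["status"] == "in_vivo"])
    test = positions_from_intervals(in_vivo)
    background = positions_from_intervals(truth.sites)

    config = RscanConfig(n_null=args.n_null, seed=args.seed + 1)
    result = call_deficient_regions(test, config, background_by_chrom=background,
                                    keep_null=False)
    result.spans.to_csv(args.out / "rscan_spans.tsv", sep="\t", index=False)
    write_bed(result.regions, args.out / "deficient_regions.bed")

    n_sig = int(result.spans["significant"].sum())
    print(f"tested {len(result.spans)} extreme spans "
          f"(r <= {config.r_max}, k <= {config.k_max}, {config.n_null} null sets): "
          f"{n_sig} significant at BH-adjusted p < {config.alpha}")
    print(f"called {len(result.regions)} hotspot-deficient region(s)")

    xref = cross_reference_deficiency(result.regions, truth.sites,
                                      truth.config.genome_obj)
    xref.to_csv(args.out / "deficiency_crossref.tsv", sep="\t", index=False)
    if len(xref):
        frac = xref["truly_deficient"].mean()
        print(f"{100*frac:.0f} % of regions keep normal in-vitro site density "
              "(usage-deficient, not binding-deficient)")
    else:
        print("no regions called at the default study conditions "
              "(chromatin-driven depletion alone rarely exceeds the null)")


if __name__ == "__main__":
    main()
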