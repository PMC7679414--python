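#!/usr/bin/env python
"""Order each fungus's proteins by hierarchical clustering for heat maps.

UPGMA on Euclidean distances over the replicate-averaged profiles (missing
filled with -10 for the distance computation only); writes one ordered
matrix per fungus, optionally rendering PNGs with --plot.
"""

import argparse
from pathlib import Path

from secretomenet.cluster import heatmap_matrix, hierarchical_order, write_heatmap_tsv
from secretomenet.io import read_abundance
from secretomenet.preprocess import detection_filter
from secretomenet.simulate import read_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--averaged", type=Path, default=Path("results/averaged_abundance.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--plot", action="store_true", help="also render PNG heat maps")
    args = parser.parse_args()

    table, _ann, _cm, _truth = read_study(args.study)
    decision = detection_filter(table)
    averaged = read_abundance(args.averaged, scale="log2_normalized")

    for fungus in averaged.fungi:
        kept = sorted(decision.keep_by_fungus.get(fungus, set()))
        if len(kept) < 2:
            print(f"{fungus}: fewer than two kept proteins, skipped")
            continue
        matrix = averaged.for_fungus(fungus).values.loc[kept]
        dend = hierarchical_order(matrix)
        ordered, meta = heatmap_matrix(matrix, dend)
        path = write_heatmap_tsv(ordered, args.out / f"heatmap_{fungus}.tsv")
        print(f"{fungus}: {len(kept)} proteins ordered "
              f"(display range {meta['vmin']}..{meta['vmax']}); wrote {path}")
        if args.plot:
            from secretomenet.cluster import render_heatmap

            png = render_heatmap(ordered, args.out / f"heatmap_{fungus}.png")
            print(f"  rendered {png}")


if __name__ == "__main__":
    main()
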