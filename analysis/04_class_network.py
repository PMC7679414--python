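#!/usr/bin/env python
"""Build the enzyme-class co-expression network and filter its edges.

Per fungus: -10 imputation, |Pearson r| protein adjacency over all raw
files, collapse onto (overlapping) enzyme classes; then cross-fungus
averaging, node strength, integer discretization and the marginal
likelihood filter at alpha = 0.05.  Writes GraphML/SIF exports and prints
the hub ranking and the surviving edges.
"""

import argparse
from pathlib import Path

from secretomenet.network import export_network
from secretomenet.pipeline import build_class_network
from secretomenet.preprocess import apply_filter, detection_filter, normalize
from secretomenet.simulate import read_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results/network"))
    parser.add_argument("--beta", type=float, default=1.0,
                        help="soft-thresholding power on |Pearson r|")
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    table, annotations, class_map, _truth = read_study(args.study)
    decision = detection_filter(table)
    normalized = normalize(apply_filter(table, decision))
    averaged, discretized, filtered, strengths = build_class_network(
        normalized, annotations, class_map, decision,
        beta=args.beta, alpha=args.alpha,
    )

    occupied = [c for c in averaged.classes if averaged.sizes[averaged.index(c)] > 0]
    print(f"class network: {len(occupied)} occupied classes "
          f"(of {len(averaged.classes)} in the map)")
    ranked = sorted(strengths.items(), key=lambda kv: -kv[1])[:5]
    print("top classes by strength (hub ranking):")
    for label, s in ranked:
        print(f"  {label:28s} strength={s:.2f} size={averaged.size(label)}")

    n_edges = int((discretized.int_weights > 0).sum() // 2)
    n_kept = int((filtered.int_weights > 0).sum() // 2)
    print(f"marginal likelihood filter (alpha={args.alpha}): "
          f"{n_kept} of {n_edges} edges survive")
    for i, a in enumerate(filtered.classes):
        for j in range(i + 1, len(filtered.classes)):
            if filtered.int_weights[i, j] > 0:
                b = filtered.classes[j]
                print(f"  {a} -- {b}: C={filtered.C[i, j]:.3f} "
                      f"w={filtered.int_weights[i, j]} p={filtered.pvalues[i, j]:.2e}")

    for name, net in (("class_network", discretized),
                      ("class_network_filtered", filtered)):
        paths = export_network(net, args.out / name, strengths=strengths)
        print(f"wrote {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
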