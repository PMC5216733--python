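"""Compare the tumor and control networks: Venn partition + clock tagging.

Partitions the two edge sets into common (coherent), sign-flip,
tumor-exclusive and control-exclusive pairs, then tags clock-controller
pairs from the validated miRNA -> clock-gene target map.  The planted
control-only module around hsa-miR-139-5p should appear as control-
exclusive clock-controller pairs.
"""

import argparse
import sys
from pathlib import Path

from clocknet import TargetMap, tag_clock_controllers
from clocknet.algebra import partition_signed_pairs
from clocknet.corrnet import read_edges_tsv

sys.path.insert(0, str(Path(__file__).parent))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    if not all((args.out / n).exists() for n in ("edges_control.tsv", "edges_tumor.tsv")):
        import subprocess
        subprocess.run([sys.executable,
                        str(Path(__file__).parent / "03_correlation_networks.py"),
                        "--seed", str(args.seed), "--out", str(args.out)], check=True)

    control = read_edges_tsv(args.out / "edges_control.tsv")
    tumor = read_edges_tsv(args.out / "edges_tumor.tsv")
    part = partition_signed_pairs(tumor.edge_signs(), control.edge_signs())
    part.write_json(args.out / "partition.json")

    targets = TargetMap.validated()
    pair_tags, node_flags = tag_clock_controllers(part, targets)

    print("edge partition (Venn counts):", part.venn_counts)
    print(f"clock-controller pairs: {sum(pair_tags.values())} of {len(pair_tags)}; "
          f"clock-targeting nodes: {sum(node_flags.values())}")
    lost_clock = sorted(p for p in part.control_exclusive if pair_tags[p])
    print(f"control-exclusive clock-controller pairs (lost in tumor): {len(lost_clock)}")
    for pair in lost_clock[:6]:
        print("  lost:", " -- ".join(pair))
    print(f"wrote {args.out / 'partition.json'}")


if __name__ == "__main__":
    main()
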