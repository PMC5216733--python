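"""Paired differential expression on the simulated cohort.

Loads the fixture written by 01_simulate_cohort.py (regenerating it if
absent), runs the paired t test per feature, attaches signed fold changes
and BH FDR, applies the |FC| >= 1.5 / FDR <= 0.05 filter, and reports the
most deregulated features.  The planted candidate should surface with a
signed FC near -6.8.
"""

import argparse
import subprocess
import sys
from pathlib import Path

from clocknet import differential_expression, load_paired_set


def ensure_cohort(out: Path, seed: int) -> Path:
    fixture = out / "cohort"
    if not (fixture / "expression.tsv").exists():
        subprocess.run([sys.executable, str(Path(__file__).parent / "01_simulate_cohort.py"),
                        "--seed", str(seed), "--out", str(out)], check=True)
    return fixture


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    fixture = ensure_cohort(args.out, args.seed)
    pset = load_paired_set(fixture / "expression.tsv", fixture / "samplesheet.tsv")
    de = differential_expression(pset)
    de.to_csv(args.out / "de_table.tsv", sep="\t")

    called = de[de["direction"] != "ns"].sort_values("p")
    print(f"tested {len(de)} features over {pset.n_patients} pairs; "
          f"{(de['direction'] == 'down').sum()} down, {(de['direction'] == 'up').sum()} up "
          f"at |FC| >= 1.5, FDR <= 0.05")
    print("most deregulated features:")
    cols = ["signed_fc", "t", "p", "fdr", "direction"]
    print(called[cols].head(6).to_string(float_format=lambda v: f"{v:.4g}"))
    print(f"wrote {args.out / 'de_table.tsv'}")


if __name__ == "__main__":
    main()
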