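#!/usr/bin/env python
"""Simulate the study dataset: genome, class-labelled peaks, fragments.

Generates a background genome carrying 100 peak windows per class (G1/G2/G3)
with their planted motifs (G1: GAT-{3,4}bp-ATC tandem embedded in a WGATAR;
G2: single WGATAR; G3: GAT-6bp-GAT tandem), fragment files for the pre- and
post-expression conditions with the class-specific dyad placement, and a
uniform sonicated control. Everything downstream reads these files.
"""

import argparse
from pathlib import Path

from nucpioneer.cli import derive_seed
from nucpioneer.synthetic_data import SimConfig, simulate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    config = SimConfig(
        seed=derive_seed(args.seed, "simulate"),
        genome_length=600_000,
        n_peaks={"G1": 100, "G2": 100, "G3": 100},
        fragments_per_locus=200,
    )
    dataset = simulate_dataset(config)
    paths = write_dataset(dataset, args.out)
    print(f"simulated {len(dataset.peaks)} peaks on a {config.genome_length/1e3:.0f} kb genome")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
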