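#!/usr/bin/env python
"""Tandem GAT spacing statistics: tables, Monte Carlo null, class contrasts.

Counts same-strand (GATnGAT) and convergent opposite-strand (GATnATC) pairs
with spacers 0-10 in each 200-bp peak window, contrasts classes by
chi-squared on locus presence, tests per-spacer enrichment against random
genomic windows, and computes the Monte Carlo enrichment p-value for
GAT-pair content of peak windows versus the random-window null. On the
simulated data the G3/GG spacer histogram peaks at 6 and the G1/GA one at
3-4, matching the planted plans.
"""

import argparse
from pathlib import Path

from nucpioneer.cli import derive_seed, spacing_stage
from nucpioneer.io_tracks import read_fasta, read_peaks, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/spacing"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=1000)
    args = ap.parse_args()

    genome = read_fasta(args.sim / "genome.fa")
    peaks = read_peaks(args.sim / "peaks.tsv")
    tables = spacing_stage(
        genome, peaks, replicates=args.replicates, seed=derive_seed(args.seed, "spacing")
    )
    args.out.mkdir(parents=True, exist_ok=True)
    for name in ("spacing", "null", "null_summary", "contrasts"):
        write_table(tables[name], args.out / f"{name}.tsv")

    spacing = tables["spacing"]
    for cls, ori in [("G3", "GG"), ("G1", "GA")]:
        sub = spacing[(spacing.class_label == cls) & (spacing.orientation == ori)]
        best = sub.loc[sub["fold"].idxmax()]
        print(
            f"{cls}/{ori}: top spacer {int(best.spacer)} "
            f"(fold {best.fold:.1f} vs random windows, chi2 p = {best.p:.3g})"
        )
    s = tables["null_summary"].iloc[0]
    print(
        f"Monte Carlo enrichment: observed {int(s.observed)} pairs, "
        f"R = {int(s.R)}, empirical p = {s.empirical_p:.4g}"
    )
    print(f"wrote {args.out}/spacing.tsv, null.tsv, null_summary.tsv, contrasts.tsv")


if __name__ == "__main__":
    main()
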