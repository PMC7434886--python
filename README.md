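# nucpioneer

Analyses of how a pioneer transcription factor (the GATA family's
GATA3) engages its binding motifs on nucleosomal DNA: where nucleosome
dyads sit relative to bound motifs, how tandem 5′-GAT-3′ half-sites are
spaced and oriented at bound loci, and which rotational positions on the
nucleosome leave those half-sites solvent-accessible.

The package is organised as a library (`src/nucpioneer/`) driven by
numbered analysis scripts (`analysis/`), with a `nucpioneer` command-line
interface over the same functions.

## The analyses

**Dyad profiling** (`dyad_profile`). Mono-nucleosomal MNase fragment
midpoints estimate nucleosome dyads. For each class-labelled peak (G1:
loci opened by factor binding; G2: pre-accessible; G3: bound but
unremodeled), the WGATAR motif closest to the peak summit anchors a
profile of midpoint offsets, pooled per class, normalised by a sonicated
control, and rendered as a log2 heatmap over ±75 bp. Positioned classes
show symmetric dyad modes at characteristic distances: ~21 bp (superhelical
location SHL2, two helical turns) or ~52 bp (SHL5, five turns) from the
motif.

**Tandem GAT spacing** (`motif_spacing`). Two GAT trinucleotides separated
by 0–10 bp form a same-strand (5′-GATN_xGAT-3′) or convergent
opposite-strand (5′-GATN_xATC-3′) pair. Counts per class, orientation and
spacer are compared against (i) an analytic iid expectation — under which
the same-strand arrangement is exactly twice as probable as the convergent
one — (ii) a Monte Carlo null of random genomic windows, and (iii) other
classes via χ² on locus presence.

**Rotational geometry and construct design** (`nucgeom`). Positions on
nucleosomal DNA map to superhelical location SHL = (pos − dyad)/period
(default 10.4 bp/turn); half-integer SHLs present the major groove to
solvent, integer SHLs to the histone surface. The module classifies tandem
pairs (dual-exposed in consecutive grooves / one buried / both buried) and
designs nucleosome constructs on a 145-bp positioning template: GATA-motif
insertions (5′-AGATANCATCT-3′) in rotational series around SHL2 and SHL5,
the SHL5e construct whose introduced ATC sits one helical turn inside the
template's intrinsic SHL6.5 site (6-bp spacer), and single-site GAT
knockouts.

**Synthetic data** (`synthetic_data`). A seeded generator produces genomes,
peak sets and fragment files with the planted class structure above, so
every stage is testable end-to-end without downloads.

## Worked example

```bash
python analysis/01_simulate.py --seed 1          # writes results/sim/
python analysis/02_dyad_profiles.py              # writes results/profiles/
python analysis/03_motif_spacing.py --seed 1     # writes results/spacing/
python analysis/04_construct_geometry.py         # writes results/constructs/
```

Output printed by the drivers (seed 1):

```
normalised dyad-frequency maxima per class/condition:
  G1:post: argmax offsets -132 / +130 bp (ratio 3.56 / 3.75)
  G1:pre: argmax offsets -22 / +20 bp (ratio 12.51 / 15.54)
  G2:post: argmax offsets -86 / +97 bp (ratio 6.60 / 6.76)
  G2:pre: argmax offsets -86 / +96 bp (ratio 6.20 / 6.89)
  G3:post: argmax offsets -52 / +53 bp (ratio 13.26 / 16.51)
  G3:pre: argmax offsets -41 / +92 bp (ratio 1.87 / 1.80)

G3/GG: top spacer 6 (fold 5.9 vs random windows, chi2 p = 7.7e-25)
G1/GA: top spacer 3 (fold 3.6 vs random windows, chi2 p = 2.07e-08)
Monte Carlo enrichment: observed 758 pairs, R = 1000, empirical p = 0.000999

template: 3 intrinsic GAT sites at SHL -6.25, +2.79, +6.54
SHL5e solvent-exposed GATs at groove labels 5.5, 6.5
SHL5e spacer-6 same-strand tandem: dual_exposed_consecutive
```

Reading this: G1 loci had dyads ±21 bp from the motif before factor
expression (motif on the nucleosome at SHL2) and >100 bp away after
(nucleosome moved off); G2 dyads stay away from the motif in both
conditions; G3 dyads concentrate at ±52 bp (SHL5) after expression. The
planted spacing preferences (G3 same-strand spacer 6; G1 convergent spacer
3–4) are recovered with large folds over random windows, and GAT pairs are
enriched in peak windows at the smallest p the R=1000 null can produce
(1/1001). On the designed SHL5e construct the two same-strand GATs at
SHL5.5 and SHL6.5, six bases apart, are both solvent-exposed in
consecutive major grooves.

The same stages are available as subcommands:

```bash
nucpioneer simulate --seed 1 --out results/sim
nucpioneer spacing --genome results/sim/genome.fa --peaks results/sim/peaks.tsv \
    --replicates 1000 --seed 1 --out results/spacing
nucpioneer design --out results/constructs
nucpioneer run-all --seed 1 --out results/run
```

Every output directory gets a `manifest.json` recording parameters, input
digests, seed and version.

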