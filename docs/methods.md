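# Methods

`nucpioneer` implements three linked analyses of pioneer-factor binding in
chromatin — motif-anchored nucleosome dyad profiling, tandem 5′-GAT-3′
spacing statistics, and nucleosome rotational geometry — together with a
seeded generator of synthetic datasets that carry the statistical structure
the analyses assume. This note records the models, the defaults and why,
the numerical choices, and what the synthetic data do and do not show.

## Dyad profiling

**Model.** A mono-nucleosomal MNase fragment protects ~147 bp; its midpoint
estimates the nucleosome dyad. For each peak (a class-labelled locus with a
summit), every WGATAR match (W∈{A,T}, R∈{A,G}) on either strand of the
200-bp window is found and the hit whose centre (motif start + 3) is
nearest the summit is taken as the anchor — the summit standing in for the
point of maximal ChIP signal, which is standard peak metadata. Midpoints
within ±K bp of the anchor are binned by offset; profiles are pooled over
loci per class. With motif-strand orientation on (default), offsets at
minus-strand anchors are negated so the motif's 5′→3′ axis is consistent
across loci.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| analysis window | 200 bp | window centred on the peak |
| metaplot half-width K | 150 bp | covers a full nucleosome either side; the heatmap span (±75) is the stated quantity, the metaplot span is a presentation choice |
| heatmap half-width | 75 bp | motif positions within one wrap of the closest dyad |
| mono-nucleosome band | 120–200 bp | gel size selection has no published numeric bounds; the band brackets the canonical wrap |
| midpoint of even fragments | left of centre | a fixed deterministic tie-break |
| pseudocount ε | 0.5 | regularises sparse offsets; configurable |
| smoothing σ | 15 bp | browser-style display smoothing only; no statistic is computed from smoothed values |

**Normalisation.** Signal and control (sonicated-fragment) profiles are
reduced to frequencies, then a uniform pseudo-mass is mixed in:
f_i = (x_i/Σx + ε/M)/(1+ε) over M offsets, and the reported ratio is
f_sig/f_ctrl (log2 for heatmaps). Applying the pseudocount on the frequency
scale — rather than adding ε to raw counts — makes the ratio *exactly*
invariant under rescaling either profile's sequencing depth, which is the
property the normalisation exists to provide; at unit mean depth the two
forms coincide. Degenerate input (both profiles empty) is an error rather
than a silent flat ratio.

**Smoothing.** Discrete Gaussian kernel truncated at 3σ and renormalised;
output rescaled to the input total so mass is conserved to ~1e−9 relative.
σ=0 is the identity. This is a generic kernel smoother for track-style
output, not a reimplementation of any published nucleosome-calling
smoother.

**Pooling.** Profiles pool raw counts across loci (each locus contributes
proportionally to its depth). A per-locus-average variant would weight loci
equally; pooled counts are the default because the synthetic generator
fixes depth per locus, making the two equivalent there.

## Tandem GAT spacing

**Counting.** Two GAT trinucleotides with a spacer of x ∈ [0,10] bp form a
pair in one of two orientations: same-strand ("GG", footprint GATN_xGAT on
either strand) or convergent opposite-strand ("GA", GATN_xATC). Scanning
the plus strand only, for the three patterns GATN_xGAT, ATCN_xATC and
GATN_xATC, counts every physical pair exactly once because this pattern set
is closed under reverse complement. The divergent arrangement ATCN_xGAT is
not part of the analysis set but can be enabled by flag. All overlapping
and nested matches count; per-locus presence/absence is tracked separately
and used for class contrasts, since "how many loci contain such a site" and
"how many such sites exist" answer different questions.

**Analytic expectation.** Under an iid base model, the per-start-position
probability is p(GAT)·p(ATC) for GA and p(GAT)²+p(ATC)² for GG,
independent of the spacer length (spacer bases are free). Under a uniform
composition the GG/GA ratio is exactly 2 — the same-strand arrangement
matches two plus-strand patterns where the convergent one matches one. A
window of length L has L−5−x valid start positions for a footprint of
6+x bp.

**Monte Carlo null.** The observed statistic is the total pair count over
all peak windows. Each of R replicates redraws |peaks| windows uniformly
over all valid placements (window inside the chromosome, no N, no overlap
with peak windows — a self-contained stand-in for coordinate shuffling) and
recounts. The empirical p-value is (1 + #{null ≥ observed})/(1 + R), which
is never 0 and is super-uniform under the null (verified by a 200-repetition
calibration test). The sampler is genome-uniform; it does not match
replicates by chromosome or GC content.

**Chi-squared contrasts.** Class comparisons use a 2×2 table of (loci with
≥1 pair, loci without) × (class A, class B), Pearson χ² with df=1 and no
continuity correction (cross-checked against an independent implementation
in tests). Per-spacer enrichment contrasts (count at x vs count at other
spacers) in a class against the same split in pooled random windows, with
fold = pseudocounted proportion ratio (ε=0.5). Degenerate margins report
p=1 with a warning rather than failing a whole table.

## Nucleosome geometry and construct design

**Coordinate model.** A construct carries a dyad-centred frame: superhelical
location SHL(p) = (p − dyad)/period, with period 10.4 bp/turn by default
(nucleosomal twist varies; the period is an explicit parameter). The major
groove at half-integer SHLs faces solvent and at integer SHLs faces the
histone octamer; this is encoded as a phase threshold: solvent-exposed iff
|frac(|SHL|) − 0.5| < 0.25, boundary assigned histone-facing. A motif's
single-base anchor is the centre of its GAT trinucleotide.

**Tandem classification.** For a pair, both GAT centres get a groove-face
call; `dual_exposed_consecutive` requires both solvent-facing and a
separation of 0.7–1.3 turns (consecutive major grooves). A spacer-6
same-strand pair (centres 9 bp apart, ΔSHL ≈ 0.87) anchored in a groove is
classified dual-exposed for any period in [10.0, 10.6], which the tests
assert as a robustness band.

**The 145-bp template.** The designer operates on any user-supplied 145-bp
sequence (dyad index 72 by default). The built-in default is a *synthetic*
stand-in assembled from the published Widom 601 positioning sequence: its
central 145 bp with the GAT near SHL5.7 disrupted by one middle-base edit,
leaving exactly three intrinsic GAT-equivalent sites (SHL ≈ −6.3, +2.8,
+6.5). This layout reproduces the construct-template properties the
analyses rely on — three intrinsic sites, and an intrinsic solvent-exposed
site at SHL6.5 — without embedding any sequence that cannot be checked
against the open literature.

**Constructs.** The insertion motif is 5′-AGATANCATCT-3′ (N keeps the
template base), placed so its first GAT centre lands on the base pair
nearest a target SHL; length is preserved and every changed base is
recorded. The a–e rotational series steps targets by 0.2 SHL (~2 bp) and is
defined to end at base+0.1, so the final member ("e") places the introduced
ATC in the solvent-facing groove nearest SHL(base+0.5); the exact per-member
offsets of the original constructs are not published in text form, so this
convention is the package's own. `design_shl5e` instead anchors on the
template: the introduced ATC is placed 6 bp upstream of the intrinsic
SHL6.5 site, giving same-strand GATs in consecutive grooves at SHL5.5 and
SHL6.5 (6-bp spacer) and a buried GAT at SHL5 — the configuration the
downstream geometry analysis classifies. With the default template and
period this coincides with SHL5-series member e. Knockouts substitute the
middle base of one GAT/ATC (preference C>G>T>A) subject to: the site is
destroyed on both strands and no *new* GAT/ATC appears within ±4 bp.

## Synthetic data

The generator emulates, per class: G1 windows carry a convergent GAT–ATC
tandem (spacer 3 or 4, equal weights) embedded in a WGATAR; G2 a single
WGATAR; G3 a same-strand GAT tandem with spacer 6. Dyad models per (class,
condition), as offsets from the motif centre:

| class, condition | model |
|---|---|
| G1 pre | symmetric Gaussians at ±21 bp (σ=3) — two turns at 10.4 bp/turn |
| G1 post | symmetric Gaussians at ±130 bp (σ=15) — beyond 100 bp |
| G2 pre/post | uniform over the window, excluded within ±80 bp of the motif |
| G3 pre | uniform over the window |
| G3 post | symmetric Gaussians at ±52 bp (σ=3) — five turns |

Gaussian mixtures truncate at the control span (window ± margin); fragment
lengths are N(147, 10) truncated to the 120–200 band; the control draws
midpoints uniformly over window ± 100 bp at matched depth. Default depth is
200 fragments per locus and 100 peaks per class. An optional scrub pass
disrupts every background WGATAR (either strand) outside peak windows by a
single-base edit, iterating until a rescan is clean — used where planted
motifs must be the only anchors. The whole simulation is a pure function of
the configuration, including its seed; outputs are byte-identical across
runs.

What the generator does *not* emulate: MNase sequence bias, linker
histones, variable per-locus depth, chromosome structure (single uniform
chromosome), GC heterogeneity, or read-level noise. Passing tests therefore
demonstrate correctness of the estimators under the assumed generative
structure, not robustness to those real-data effects.

## Problem sizes and determinism

Analyses are exercised at desk scale: the analysis drivers use a 600-kb
genome with 300 peaks and 200 fragments/locus; the acceptance script uses a
1-Mb scrubbed genome, 300 peaks and R=1000 Monte Carlo replicates; the test
suite uses smaller instances of the same conditions (chosen as the package's
own sizes for quick iteration). A single global seed fans out to per-stage
seeds via a stage-name hash, so each stage is reproducible independently of
execution order; all derived seeds stay below 2³¹.

## Known limitations

- The peak summit proxies the ChIP signal maximum; no coverage is
  recomputed.
- The groove-face rule is a two-state threshold model; real accessibility
  varies continuously and depends on local twist.
- The analytic expectation treats positions as independent; overlapping
  pattern matches make window counts slightly over-dispersed relative to
  binomial, which is why enrichment inference uses the Monte Carlo null
  rather than the analytic expectation.
- The Monte Carlo sampler draws windows genome-uniformly; on strongly
  heterogeneous real genomes a matched (e.g. GC- or chromosome-stratified)
  null would be more conservative.
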