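"""Tandem 5'-GAT-3' spacing and orientation statistics.

Two GAT trinucleotides can sit on the same strand (GATN_xGAT; orientation
"GG") or on opposite strands in convergent arrangement (GATN_xATC; "GA"),
separated by a spacer of 0-10 bp. Scanning the plus strand for the three
patterns GATN_xGAT, ATCN_xATC and GATN_xATC counts every physical pair
exactly once, because that pattern set is closed under reverse complement.

Enrichment over the genome is assessed against an analytic iid expectation
and against a Monte Carlo null built from freshly sampled random genomic
windows (a self-contained stand-in for coordinate shuffling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tracks import Genome, GenomicInterval, Peak

ORIENTATIONS = ("GG", "GA")
DEFAULT_SPACERS = range(0, 11)


@dataclass(frozen=True)
class TandemPair:
    """An oriented GAT pair in plus-strand coordinates.

    ``plus_pattern`` records which plus-strand pattern matched:
    GATnGAT / ATCnATC (orientation GG) or GATnATC (orientation GA).
    """

    chrom: str
    first_start: int
    spacer: int
    orientation: str
    plus_pattern: str

    @property
    def footprint(self) -> int:
        return 6 + self.spacer


def _site_starts(seq: str, tri: str) -> list[int]:
    out, i = [], seq.find(tri)
    while i != -1:
        out.append(i)
        i = seq.find(tri, i + 1)
    return out


def find_tandem_pairs(
    window_sequence: str,
    spacer_range: Iterable[int] = DEFAULT_SPACERS,
    chrom: str = ".",
    offset: int = 0,
    include_divergent: bool = False,
) -> list[TandemPair]:
    """All tandem GAT pairs in a window, every (start, spacer) match reported.

    Overlapping and nested matches all count. N never matches. With
    ``include_divergent`` the ATCN_xGAT (divergent, opposite-strand)
    arrangement is also reported under orientation "GA".
    """
    seq = window_sequence.upper()
    spacers = set(spacer_range)
    gat = _site_starts(seq, "GAT")
    atc = _site_starts(seq, "ATC")
    pairs: list[TandemPair] = []

    def emit(first: Sequence[int], second: Sequence[int], orientation: str, name: str):
        second_set = set(second)
        for i in first:
            for x in spacers:
                if i + 3 + x in second_set:
                    if "N" in seq[i : i + 6 + x]:  # masked spacer: no match
                        continue
                    pairs.append(
                        TandemPair(chrom, offset + i, x, orientation, name)
                    )

    emit(gat, gat, "GG", "GATnGAT")
    emit(atc, atc, "GG", "ATCnATC")
    emit(gat, atc, "GA", "GATnATC")
    if include_divergent:
        emit(atc, gat, "GA", "ATCnGAT")
    pairs.sort(key=lambda p: (p.first_start, p.spacer, p.plus_pattern))
    return pairs


# ---------------------------------------------------------------------------
# fast counting path (used by the Monte Carlo null)

def site_masks(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean start-position masks for GAT and ATC over a sequence."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = arr.size
    gat = np.zeros(n, dtype=bool)
    atc = np.zeros(n, dtype=bool)
    if n >= 3:
        gat[: n - 2] = (arr[:-2] == b"G") & (arr[1:-1] == b"A") & (arr[2:] == b"T")
        atc[: n - 2] = (arr[:-2] == b"A") & (arr[1:-1] == b"T") & (arr[2:] == b"C")
    return gat, atc


def count_pairs_in_window(
    gat: np.ndarray,
    atc: np.ndarray,
    start: int,
    end: int,
    spacers: Iterable[int] = DEFAULT_SPACERS,
    orientation: str | None = None,
) -> int:
    """Pair count within [start, end) from precomputed site masks.

    Equivalent to ``len(find_tandem_pairs(seq[start:end], ...))`` filtered by
    orientation; both trinucleotides must lie fully inside the window.
    """
    total = 0
    for x in spacers:
        d = x + 3
        n = end - start - 5 - x  # valid first-start positions in the window
        if n <= 0:
            continue
        g1 = gat[start : start + n]
        g2 = gat[start + d : start + d + n]
        a1 = atc[start : start + n]
        a2 = atc[start + d : start + d + n]
        if orientation in (None, "GG"):
            total += int(np.count_nonzero(g1 & g2)) + int(np.count_nonzero(a1 & a2))
        if orientation in (None, "GA"):
            total += int(np.count_nonzero(g1 & a2))
    return total


# ---------------------------------------------------------------------------
# per-class spacing tables

@dataclass
class SpacingTable:
    """Per-class x orientation x spacer pair counts and locus presence counts."""

    counts: dict[tuple[str, str, int], int] = field(default_factory=dict)
    loci_with_pair: dict[tuple[str, str, int], int] = field(default_factory=dict)
    n_peaks: dict[str, int] = field(default_factory=dict)
    spacers: tuple[int, ...] = tuple(DEFAULT_SPACERS)

    def add_locus(self, class_label: str, pairs: Sequence[TandemPair]) -> None:
        self.n_peaks[class_label] = self.n_peaks.get(class_label, 0) + 1
        seen: set[tuple[str, int]] = set()
        for p in pairs:
            key = (class_label, p.orientation, p.spacer)
            self.counts[key] = self.counts.get(key, 0) + 1
            if (p.orientation, p.spacer) not in seen:
                seen.add((p.orientation, p.spacer))
                self.loci_with_pair[key] = self.loci_with_pair.get(key, 0) + 1

    def count(self, class_label: str, orientation: str, spacer: int) -> int:
        return self.counts.get((class_label, orientation, spacer), 0)

    def loci(self, class_label: str, orientation: str, spacer: int) -> int:
        return self.loci_with_pair.get((class_label, orientation, spacer), 0)

    def loci_any_spacer(self, class_label: str, orientation: str) -> int:
        """Loci with >=1 pair of the orientation at any spacer (<= n_peaks)."""
        return self._any_spacer.get((class_label, orientation), 0)

    def __post_init__(self) -> None:
        self._any_spacer: dict[tuple[str, str], int] = {}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in sorted(self.n_peaks):
            for ori in ORIENTATIONS:
                for x in self.spacers:
                    rows.append(
                        {
                            "class_label": cls,
                            "orientation": ori,
                            "spacer": x,
                            "pair_count": self.count(cls, ori, x),
                            "loci_with_pair": self.loci(cls, ori, x),
                            "n_peaks": self.n_peaks[cls],
                        }
                    )
        return pd.DataFrame(rows)


def spacing_table(
    peaks: Sequence[Peak],
    genome: Genome,
    window: int = 200,
    spacer_range: Iterable[int] = DEFAULT_SPACERS,
) -> SpacingTable:
    """Aggregate tandem-pair counts over each peak's window, per class.

    The window is centred on the peak interval's centre; windows running off
    the chromosome are clipped (with a warning).
    """
    table = SpacingTable(spacers=tuple(spacer_range))
    for peak in peaks:
        mid = (peak.interval.start + peak.interval.end) // 2
        s, e = mid - window // 2, mid + window - window // 2
        clip_s = max(0, s)
        clip_e = min(genome.length(peak.interval.chrom), e)
        if (clip_s, clip_e) != (s, e):
            warnings.warn(f"peak {peak.id}: window clipped to [{clip_s},{clip_e})")
        seq = genome.fetch(peak.interval.chrom, clip_s, clip_e)
        pairs = find_tandem_pairs(seq, spacer_range, peak.interval.chrom, clip_s)
        table.add_locus(peak.class_label, pairs)
        seen_ori = {p.orientation for p in pairs}
        for ori in seen_ori:
            key = (peak.class_label, ori)
            table._any_spacer[key] = table._any_spacer.get(key, 0) + 1
    return table


# ---------------------------------------------------------------------------
# analytic iid expectation

@dataclass(frozen=True)
class ExpectationModel:
    """Iid base-composition model for per-position pair probabilities."""

    base_frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.base_frequencies.get(b, 0.0) for b in "ACGT")
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"base frequencies sum to {total}, not 1")
        if any(not 0 <= self.base_frequencies.get(b, 0.0) <= 1 for b in "ACGT"):
            raise ValueError("base frequencies must lie in [0,1]")

    @classmethod
    def uniform(cls) -> "ExpectationModel":
        return cls({b: 0.25 for b in "ACGT"})

    def p(self, base: str) -> float:
        return float(self.base_frequencies[base])


def expected_pair_probability(
    model: ExpectationModel, orientation: str, spacer: int
) -> float:
    """Per-start-position probability of a tandem pair under the iid model.

    Spacer bases are unconstrained, so the value is independent of the
    spacer length. Same-strand pairs match two plus-strand patterns
    (GATnGAT, ATCnATC), hence are twice as likely as convergent pairs
    under a strand-symmetric composition.
    """
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    p_gat = model.p("G") * model.p("A") * model.p("T")
    p_atc = model.p("A") * model.p("T") * model.p("C")
    if orientation == "GG":
        return p_gat * p_gat + p_atc * p_atc
    if orientation == "GA":
        return p_gat * p_atc
    raise ValueError(f"unknown orientation: {orientation!r}")


# ---------------------------------------------------------------------------
# random-window null (shuffleBed stand-in)

class SamplingError(RuntimeError):
    """No valid random-window placement exists."""


class _PlacementIndex:
    """Uniform sampler over every valid window start in a genome.

    A start is valid when the window fits the chromosome, contains no N,
    and does not overlap any excluded interval.
    """

    def __init__(
        self,
        genome: Genome,
        window: int,
        exclude: Sequence[GenomicInterval] = (),
    ) -> None:
        self.window = window
        self.chroms: list[str] = []
        self.starts: list[np.ndarray] = []
        excl_by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in exclude:
            excl_by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            L = len(seq)
            if L < window:
                continue
            valid = np.ones(L - window + 1, dtype=bool)
            arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
            n_pos = np.flatnonzero(arr == b"N")
            for p in n_pos:
                lo = max(0, p - window + 1)
                hi = min(valid.size, p + 1)
                valid[lo:hi] = False
            for iv in excl_by_chrom.get(chrom, ()):
                lo = max(0, iv.start - window + 1)
                hi = min(valid.size, iv.end)
                valid[lo:hi] = False
            starts = np.flatnonzero(valid)
            if starts.size:
                self.chroms.append(chrom)
                self.starts.append(starts)
        if not self.starts:
            raise SamplingError("no valid random-window placement")
        self._sizes = np.array([s.size for s in self.starts])
        self._cum = np.cumsum(self._sizes)
        self.total = int(self._cum[-1])

    def draw(self, rng: np.random.Generator, n: int) -> list[tuple[str, int]]:
        idx = rng.integers(0, self.total, size=n)
        out = []
        for i in idx:
            c = int(np.searchsorted(self._cum, i, side="right"))
            local = i - (self._cum[c - 1] if c else 0)
            out.append((self.chroms[c], int(self.starts[c][local])))
        return out

    def draw_flat(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Flat placement indices (for vectorised replicate drawing)."""
        return rng.integers(0, self.total, size=n)

    def resolve(self, flat: int) -> tuple[str, int]:
        c = int(np.searchsorted(self._cum, flat, side="right"))
        local = flat - (self._cum[c - 1] if c else 0)
        return self.chroms[c], int(self.starts[c][local])


def sample_random_windows(
    genome: Genome,
    n: int,
    window: int,
    exclude: Sequence[GenomicInterval] = (),
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """n windows sampled uniformly over valid placements (may overlap)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _PlacementIndex(genome, window, exclude)
    return [
        GenomicInterval(chrom, start, start + window)
        for chrom, start in index.draw(rng, n)
    ]


@dataclass
class NullDistribution:
    replicate_counts: list[int]
    observed: int
    empirical_p: float
    R: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"replicate": range(1, self.R + 1), "count": self.replicate_counts})


def monte_carlo_enrichment(
    peaks: Sequence[Peak],
    genome: Genome,
    orientation: str | None = None,
    R: int = 1000,
    seed: int = 0,
    window: int = 200,
    spacer_range: Iterable[int] = DEFAULT_SPACERS,
    exclude_peaks: bool = True,
) -> NullDistribution:
    """Empirical enrichment p-value of tandem pairs in peak windows.

    observed: total pair count over the peak windows. Null: R replicates,
    each recounting over len(peaks) freshly sampled random windows (peak
    windows excluded from placement). p = (1 + #{null >= obs}) / (1 + R).
    """
    if R < 99:
        raise ValueError("R must be >= 99")
    spacers = tuple(spacer_range)
    masks = {c: site_masks(genome.sequences[c]) for c in genome.chrom_names}

    def window_of(peak: Peak) -> tuple[str, int, int]:
        mid = (peak.interval.start + peak.interval.end) // 2
        s = max(0, mid - window // 2)
        e = min(genome.length(peak.interval.chrom), s + window)
        return peak.interval.chrom, s, e

    observed = 0
    for peak in peaks:
        chrom, s, e = window_of(peak)
        gat, atc = masks[chrom]
        observed += count_pairs_in_window(gat, atc, s, e, spacers, orientation)

    exclude = [p.interval for p in peaks] if exclude_peaks else []
    index = _PlacementIndex(genome, window, exclude)
    rng = np.random.default_rng(seed)
    flat = index.draw_flat(rng, R * len(peaks)).reshape(R, len(peaks))
    reps: list[int] = []
    for r in range(R):
        tot = 0
        for f in flat[r]:
            chrom, start = index.resolve(int(f))
            gat, atc = masks[chrom]
            tot += count_pairs_in_window(gat, atc, start, start + window, spacers, orientation)
        reps.append(tot)
    ge = sum(1 for t in reps if t >= observed)
    return NullDistribution(
        replicate_counts=reps,
        observed=observed,
        empirical_p=(1 + ge) / (1 + R),
        R=R,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# chi-squared contrasts

def chisq_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("degenerate 2x2 table: zero margin")
    expected = np.outer(row, col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def chisq_class_compare(
    loci_with_a: int, n_a: int, loci_with_b: int, n_b: int
) -> tuple[float, float]:
    """Compare presence/absence of a pair type between two peak classes."""
    table = np.array(
        [[loci_with_a, n_a - loci_with_a], [loci_with_b, n_b - loci_with_b]]
    )
    return chisq_2x2(table)


def spacer_enrichment(
    table: SpacingTable,
    class_label: str,
    orientation: str,
    background_counts: Mapping[int, int],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-spacer fold and chi-squared contrast against a pooled background.

    For each spacer x: 2x2 of (count at x, count at other spacers) in the
    class versus the same split in the background (random windows); fold is
    the pseudocounted proportion ratio. Degenerate margins report p = 1.
    """
    spacers = table.spacers
    cls = np.array([table.count(class_label, orientation, x) for x in spacers], dtype=float)
    bkg = np.array([background_counts.get(x, 0) for x in spacers], dtype=float)
    k = len(spacers)
    rows = []
    for i, x in enumerate(spacers):
        c_in, c_out = cls[i], cls.sum() - cls[i]
        b_in, b_out = bkg[i], bkg.sum() - bkg[i]
        p_cls = (c_in + pseudocount) / (cls.sum() + pseudocount * k)
        p_bkg = (b_in + pseudocount) / (bkg.sum() + pseudocount * k)
        fold = p_cls / p_bkg
        try:
            stat, p = chisq_2x2(np.array([[c_in, c_out], [b_in, b_out]]))
        except ValueError:
            warnings.warn(f"degenerate contrast at spacer {x}; p set to 1")
            stat, p = 0.0, 1.0
        rows.append(
            {
                "class_label": class_label,
                "orientation": orientation,
                "spacer": x,
                "count": int(c_in),
                "background": int(b_in),
                "fold": fold,
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def background_spacer_counts(
    genome: Genome,
    windows: Sequence[GenomicInterval],
    orientation: str,
    spacer_range: Iterable[int] = DEFAULT_SPACERS,
) -> dict[int, int]:
    """Pooled per-spacer pair counts over a set of (random) windows."""
    out = {x: 0 for x in spacer_range}
    for iv in windows:
        seq = genome.fetch_interval(iv)
        for p in find_tandem_pairs(seq, spacer_range):
            if p.orientation == orientation:
                out[p.spacer] += 1
    return out
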