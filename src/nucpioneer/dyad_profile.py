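"""Motif-anchored nucleosome dyad profiling.

Workflow: scan each peak window for the GATA consensus WGATAR, keep the hit
closest to the peak summit, accumulate mono-nucleosomal fragment midpoints
(dyad estimates) around that anchor, normalise against a sonicated control,
and render per-class log2 heatmaps of motif position within the nucleosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tracks import Genome, GenomicInterval, Peak

#: WGATAR: W in {A,T}, R in {A,G}; the GATA-family consensus.
_W = "AT"
_R = "AG"

MOTIF_LEN = 6

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_wgatar(kmer: str) -> bool:
    return (
        len(kmer) == MOTIF_LEN
        and kmer[0] in _W
        and kmer[1:5] == "GATA"
        and kmer[5] in _R
    )


@dataclass(frozen=True)
class MotifHit:
    """A WGATAR match; ``matched`` reads 5'->3' on ``strand``."""

    chrom: str
    start: int
    strand: str
    matched: str

    @property
    def end(self) -> int:
        return self.start + MOTIF_LEN

    @property
    def center(self) -> int:
        """Single-base anchor: start + 3 (the A of GATA...R boundary)."""
        return self.start + 3


def scan_wgatar(genome: Genome, interval: GenomicInterval) -> list[MotifHit]:
    """All WGATAR hits on both strands inside ``interval``.

    A minus-strand hit at [s, s+6) means the reverse complement of the
    plus-strand 6-mer matches WGATAR. Hits are sorted by start, then
    + before - at the same start. Intervals shorter than 6 bp yield [].
    """
    seq = genome.fetch_interval(interval)
    hits: list[MotifHit] = []
    for i in range(len(seq) - MOTIF_LEN + 1):
        kmer = seq[i : i + MOTIF_LEN]
        if "N" in kmer:
            continue
        if _matches_wgatar(kmer):
            hits.append(MotifHit(interval.chrom, interval.start + i, "+", kmer))
        rc = revcomp(kmer)
        if _matches_wgatar(rc):
            hits.append(MotifHit(interval.chrom, interval.start + i, "-", rc))
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def closest_motif(peak: Peak, hits: Sequence[MotifHit]) -> MotifHit | None:
    """The hit whose center is nearest the peak summit; ties resolve left."""
    best = None
    for h in hits:
        key = (abs(h.center - peak.summit), h.start, 0 if h.strand == "+" else 1)
        if best is None or key < best[0]:
            best = (key, h)
    return None if best is None else best[1]


@dataclass
class DyadProfile:
    """Anchor-relative midpoint counts over offsets -K..+K."""

    offsets: np.ndarray
    counts: np.ndarray
    n_loci: int = 0
    anchor_motif: MotifHit | None = None

    @classmethod
    def empty(cls, K: int) -> "DyadProfile":
        offs = np.arange(-K, K + 1)
        return cls(offsets=offs, counts=np.zeros(offs.size, dtype=np.int64))

    @property
    def K(self) -> int:
        return int(self.offsets[-1])

    def add(self, other: "DyadProfile") -> "DyadProfile":
        if not np.array_equal(self.offsets, other.offsets):
            raise ValueError("offset grids differ")
        self.counts = self.counts + other.counts
        self.n_loci += max(other.n_loci, 1)
        return self


def accumulate_profile(
    midpoints: Iterable[int],
    anchor: MotifHit,
    K: int = 150,
    orient_by_motif_strand: bool = True,
) -> DyadProfile:
    """Bin midpoints by offset from the anchor motif center.

    With ``orient_by_motif_strand``, offsets at minus-strand anchors are
    negated so the motif's 5'->3' axis points the same way at every locus.
    Midpoints farther than K bp are discarded.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    prof = DyadProfile.empty(K)
    prof.anchor_motif = anchor
    prof.n_loci = 1
    flip = orient_by_motif_strand and anchor.strand == "-"
    c = anchor.center
    for m in midpoints:
        off = m - c
        if flip:
            off = -off
        if -K <= off <= K:
            prof.counts[off + K] += 1
    return prof


@dataclass
class NormalizedProfile:
    offsets: np.ndarray
    ratio: np.ndarray
    pseudocount: float
    signal_total: int
    control_total: int

    def log2(self) -> np.ndarray:
        return np.log2(self.ratio)


def normalize_profile(
    signal: DyadProfile,
    control: DyadProfile,
    pseudocount: float = 0.5,
) -> NormalizedProfile:
    """Depth-invariant per-offset ratio of signal to control frequency.

    Each profile is reduced to frequencies first, then a uniform pseudo-mass
    of ``pseudocount`` (relative to the unit data mass) is mixed in:
    f_i = (x_i / sum(x) + eps/M) / (1 + eps) over M offsets. Applying the
    pseudocount on the frequency scale makes the ratio exactly invariant
    under rescaling either profile's depth; at unit mean depth it coincides
    with count-space pseudocounting ((x_i + eps) / sum(x + eps)).
    """
    if not np.array_equal(signal.offsets, control.offsets):
        raise ValueError("offset grids differ")
    s = signal.counts.astype(float)
    c = control.counts.astype(float)
    if s.sum() == 0 and c.sum() == 0:
        raise ValueError("degenerate input: signal and control both all-zero")
    eps = float(pseudocount)
    M = s.size

    def freqs(x: np.ndarray) -> np.ndarray:
        p = x / x.sum() if x.sum() > 0 else np.zeros_like(x)
        return (p + eps / M) / (1 + eps) if eps > 0 else p

    sf = freqs(s)
    cf = freqs(c)
    return NormalizedProfile(
        offsets=signal.offsets.copy(),
        ratio=sf / cf,
        pseudocount=eps,
        signal_total=int(s.sum()),
        control_total=int(c.sum()),
    )


def smooth_profile(values: np.ndarray, sigma_bp: float) -> np.ndarray:
    """Discrete Gaussian smoothing, kernel truncated at 3 sigma, renormalised.

    Mass spilling over the finite offset grid is folded back by rescaling the
    output to the input total, so smoothing never changes overall depth.
    sigma 0 returns the input unchanged.
    """
    if sigma_bp < 0:
        raise ValueError("sigma must be >= 0")
    v = np.asarray(values, dtype=float)
    if sigma_bp == 0:
        return v.copy()
    half = int(np.ceil(3 * sigma_bp))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma_bp) ** 2)
    kernel /= kernel.sum()
    out = np.convolve(v, kernel, mode="same")
    total = out.sum()
    if total > 0:
        out *= v.sum() / total
    return out


def profile_peaks(
    peaks: Sequence[Peak],
    genome: Genome,
    midpoints_by_chrom: Mapping[str, np.ndarray],
    K: int = 150,
    orient_by_motif_strand: bool = True,
) -> dict[str, DyadProfile]:
    """Pooled per-class dyad profiles around each peak's summit-closest motif.

    ``midpoints_by_chrom`` maps chromosome -> sorted array of fragment
    midpoints. Peaks without a WGATAR hit in their window are skipped.
    """
    pooled: dict[str, DyadProfile] = {}
    for peak in peaks:
        hits = scan_wgatar(genome, peak.interval)
        anchor = closest_motif(peak, hits)
        if anchor is None:
            continue
        mids = midpoints_by_chrom.get(peak.interval.chrom)
        if mids is None or mids.size == 0:
            local: list[int] = []
        else:
            lo = np.searchsorted(mids, anchor.center - K, side="left")
            hi = np.searchsorted(mids, anchor.center + K, side="right")
            local = mids[lo:hi].tolist()
        prof = accumulate_profile(local, anchor, K, orient_by_motif_strand)
        if peak.class_label not in pooled:
            pooled[peak.class_label] = prof
        else:
            pooled[peak.class_label].add(prof)
    return pooled


@dataclass
class PositionHeatmap:
    """Rows of log2 normalised dyad frequency over offsets -W..+W."""

    rows: list[str]
    offsets: np.ndarray
    values: np.ndarray  # shape (len(rows), 2W+1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.rows, columns=self.offsets)
        df.index.name = "row"
        return df


def _clip_profile(prof: DyadProfile, W: int) -> DyadProfile:
    K = prof.K
    if W > K:
        raise ValueError(f"heatmap half-width {W} exceeds profile half-width {K}")
    sl = slice(K - W, K + W + 1)
    return DyadProfile(prof.offsets[sl].copy(), prof.counts[sl].copy(), prof.n_loci)


def build_heatmap(
    signal_profiles: Mapping[str, DyadProfile],
    control_profiles: Mapping[str, DyadProfile],
    W: int = 75,
    pseudocount: float = 0.5,
) -> PositionHeatmap:
    """log2(signal/control frequency) per row over offsets within +/-W bp.

    Keys of ``signal_profiles`` label the rows ("G1:pre", ...); each row is
    normalised against the control profile under the same key, or a single
    shared control under the key "control" if present.
    """
    rows, mats = [], []
    offs = np.arange(-W, W + 1)
    for label, sig in signal_profiles.items():
        ctrl = control_profiles.get(label, control_profiles.get("control"))
        if ctrl is None:
            raise KeyError(f"no control profile for row {label!r}")
        norm = normalize_profile(_clip_profile(sig, W), _clip_profile(ctrl, W), pseudocount)
        rows.append(label)
        mats.append(norm.log2())
    return PositionHeatmap(rows=rows, offsets=offs, values=np.vstack(mats))


def midpoint_index(midpoints: Iterable[tuple[str, int]]) -> dict[str, np.ndarray]:
    """Group (chrom, midpoint) pairs into sorted per-chromosome arrays."""
    by: dict[str, list[int]] = {}
    for chrom, m in midpoints:
        by.setdefault(chrom, []).append(m)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}
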