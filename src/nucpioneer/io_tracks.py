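"""Core genomic types and flat-file I/O.

All coordinates in this package are 0-based, half-open (BED convention).
Any 1-based coordinate is presentation only and never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: Default fragment-length band treated as mono-nucleosomal, in bp.
#: Gel-based size selection has no published numeric bounds; this band
#: brackets the canonical ~147 bp wrap.
MONO_NUCLEOSOME_BAND = (120, 200)

#: Default half-width, in bp, of the peak analysis window (200 bp total).
PEAK_WINDOW = 200


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start},{self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Fragment:
    """A mapped fragment; its midpoint is read as a nucleosome dyad."""

    interval: GenomicInterval

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Peak:
    """A class-labelled bound locus anchored at its signal summit."""

    id: str
    interval: GenomicInterval
    summit: int
    class_label: str

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.class_label not in ("G1", "G2", "G3"):
            raise ValueError(f"unknown class label: {self.class_label!r}")


@dataclass
class Genome:
    """An in-memory genome: ordered chromosomes of uppercase A/C/G/T/N."""

    chrom_names: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise FormatError(f"duplicate chromosome name: {name!r}")
        seq = seq.upper()
        if not seq:
            raise FormatError(f"empty sequence for {name!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(f"invalid characters in {name!r}: {sorted(bad)}")
        self.chrom_names.append(name)
        self.sequences[name] = seq

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the subsequence [start, end) of a chromosome."""
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"range [{start},{end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end)


def read_fasta(path: str | Path) -> Genome:
    """Load a multi-record FASTA into a :class:`Genome` (validated, uppercased)."""
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(rec.id, str(rec.seq))
    if not genome.chrom_names:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Genome | dict[str, str], path: str | Path, width: int = 80) -> None:
    seqs = genome.sequences if isinstance(genome, Genome) else genome
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals; column 6, when present, is the strand."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from e
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(cols[0], start, end, strand))
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv{i}\t0\t{iv.strand}\n")


def read_fragments(path: str | Path) -> list[Fragment]:
    return [Fragment(GenomicInterval(iv.chrom, iv.start, iv.end)) for iv in read_bed(path)]


def fragment_midpoint(f: Fragment) -> int:
    """Fragment midpoint (dyad estimate); even lengths resolve left-of-center."""
    return f.interval.start + (len(f) - 1) // 2


def filter_mono_nucleosomal(
    fragments: Sequence[Fragment],
    band: tuple[int, int] = MONO_NUCLEOSOME_BAND,
) -> list[Fragment]:
    """Keep fragments whose length falls in the mono-nucleosome band (inclusive)."""
    lo, hi = band
    return [f for f in fragments if lo <= len(f) <= hi]


# Peaks travel as BED6+2 TSV: chrom start end id score strand summit class_label
PEAK_COLUMNS = ["chrom", "start", "end", "id", "score", "strand", "summit", "class_label"]


def read_peaks(path: str | Path, window: int = PEAK_WINDOW) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing peak columns {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), str(row.strand))
        if len(iv) != window:
            raise FormatError(
                f"{path}: peak {row.id} window {len(iv)} != configured {window}"
            )
        peaks.append(Peak(str(row.id), iv, int(row.summit), str(row.class_label)))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    rows = [
        {
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "id": p.id,
            "score": 0,
            "strand": p.interval.strand,
            "summit": p.summit,
            "class_label": p.class_label,
        }
        for p in peaks
    ]
    write_table(pd.DataFrame(rows, columns=PEAK_COLUMNS), path)


def write_table(rows, path: str | Path) -> None:
    """Write a TSV with a header line; floats at 6 significant digits."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
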