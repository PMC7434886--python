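"""Nucleosome rotational geometry and positioning-template construct design.

Positions on nucleosomal DNA are expressed as superhelical location (SHL):
signed helical turns from the dyad base pair. With the convention used
throughout this package, half-integer SHLs present the major groove to
solvent and integer SHLs press it against the histone surface, encoded as a
phase threshold of 0.25 around the half-integer point.

The module also designs nucleosome constructs on a 145-bp positioning
template: a rotational/translational series of GATA-motif insertions
(5'-AGATANCATCT-3') and single-site GAT knockouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dyad_profile import revcomp
from .motif_spacing import TandemPair, find_tandem_pairs

#: Mean helical twist of nucleosomal DNA, bp per turn. Nucleosomal twist
#: varies with position and sequence; 10.4 is a conventional average.
DEFAULT_PERIOD = 10.4

#: Introduced GATA-binding motif; N is filled with the template base.
INSERTION_MOTIF = "AGATANCATCT"
_INS_GAT_OFFSET = 1  # GAT at offsets 1..3 of the insert
_INS_ATC_OFFSET = 7  # ATC at offsets 7..9 of the insert


@dataclass(frozen=True)
class NucleosomeFrame:
    """Dyad-centred coordinate frame over a construct."""

    dyad_index: int = 72
    wrap_length: int = 145
    period: float = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.dyad_index < 0:
            raise ValueError("dyad_index must be >= 0")


def shl_of(position: int, frame: NucleosomeFrame, length: int | None = None) -> float:
    """Superhelical location of a base-pair position: (pos - dyad) / period."""
    if position < 0 or (length is not None and position >= length):
        raise ValueError(f"position {position} outside construct")
    return (position - frame.dyad_index) / frame.period


@dataclass(frozen=True)
class GeometryCall:
    shl: float
    phase: float
    face: str  # solvent_major | histone_major

    @property
    def groove_label(self) -> float:
        """Nearest half-turn label (e.g. 5.67 -> 5.5), the naming convention for grooves."""
        import math

        return math.floor(abs(self.shl) * 2 + 0.5) / 2 * (1 if self.shl >= 0 else -1)


def groove_face(shl: float) -> GeometryCall:
    """Classify the major-groove face at an SHL.

    Solvent-exposed iff |phase - 0.5| < 0.25, where phase is the fractional
    part of |shl|; the boundary itself is assigned histone_major.
    """
    phase = abs(shl) % 1.0
    face = "solvent_major" if abs(phase - 0.5) < 0.25 else "histone_major"
    return GeometryCall(shl=shl, phase=phase, face=face)


def classify_tandem_geometry(
    pair: TandemPair,
    motif_position: int,
    frame: NucleosomeFrame,
    length: int | None = None,
) -> str:
    """Geometry class of a tandem GAT pair on a nucleosome.

    ``motif_position`` is the construct coordinate of ``pair.first_start``.
    Each GAT's anchor is its centre base (start + 1). Returns one of
    dual_exposed_consecutive, one_buried, both_buried, other.
    """
    c1 = motif_position + 1
    c2 = motif_position + 3 + pair.spacer + 1
    wrap_lo = frame.dyad_index - frame.wrap_length // 2
    wrap_hi = frame.dyad_index + frame.wrap_length // 2
    for c in (c1, c2):
        if not (wrap_lo <= c <= wrap_hi) or (length is not None and c >= length):
            raise ValueError(f"motif centre {c} outside wrapped region")
    g1 = groove_face(shl_of(c1, frame, length))
    g2 = groove_face(shl_of(c2, frame, length))
    buried = [g.face == "histone_major" for g in (g1, g2)]
    if all(buried):
        return "both_buried"
    if any(buried):
        return "one_buried"
    dshl = abs(g2.shl - g1.shl)
    if 0.7 <= dshl <= 1.3:
        return "dual_exposed_consecutive"
    return "other"


@dataclass
class ConstructDesign:
    """A designed construct: name, full-length sequence, and its edits."""

    name: str
    sequence: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pos, old, new in self.edits:
            if old == new:
                raise ValueError(f"edit at {pos} records no change")


def _apply(template: str, start: int, replacement: str, name: str) -> ConstructDesign:
    if start < 0 or start + len(replacement) > len(template):
        raise ValueError(f"{name}: footprint [{start},{start + len(replacement)}) out of bounds")
    edits = [
        (start + i, template[start + i], b)
        for i, b in enumerate(replacement)
        if template[start + i] != b
    ]
    seq = template[:start] + replacement + template[start + len(replacement) :]
    return ConstructDesign(name=name, sequence=seq, edits=edits)


def design_insertion(
    template: str,
    frame: NucleosomeFrame,
    target_shl: float,
    name: str,
) -> ConstructDesign:
    """Place the GATA motif so its first GAT centre sits nearest target_shl.

    The 11-bp motif replaces template bases in place (length preserved); the
    ambiguous N position keeps the template base.
    """
    center = frame.dyad_index + round(target_shl * frame.period)
    start = center - (_INS_GAT_OFFSET + 1)
    motif = list(INSERTION_MOTIF)
    n_pos = start + motif.index("N")
    if not (0 <= start and start + len(motif) <= len(template)):
        raise ValueError(f"{name}: insertion footprint out of template")
    motif[motif.index("N")] = template[n_pos]
    return _apply(template, start, "".join(motif), name)


def design_series(
    template: str,
    frame: NucleosomeFrame,
    base_shl: float,
    prefix: str,
    n: int = 5,
    step_shl: float = 0.2,
) -> list[ConstructDesign]:
    """A rotational series of n insertion constructs labelled a, b, c, ...

    Targets step by ``step_shl`` (~2 bp) and end at base_shl + 0.1, so the
    final member places the introduced ATC in the solvent-facing major
    groove nearest SHL(base + 0.5).
    """
    labels = "abcdefghij"
    targets = [base_shl + 0.1 - step_shl * (n - 1 - k) for k in range(n)]
    return [
        design_insertion(template, frame, t, f"{prefix}{labels[k]}")
        for k, t in enumerate(targets)
    ]


_KNOCKOUT_PREFERENCE = "CGTA"


def _sites_near(seq: str, pos: int, radius: int = 4) -> set[int]:
    """Start positions of GAT/ATC sites overlapping pos +/- radius."""
    lo = max(0, pos - radius - 2)
    hi = min(len(seq), pos + radius + 1)
    return {
        i
        for i in range(lo, hi)
        if seq[i : i + 3] in ("GAT", "ATC")
    }


def knockout_gat(sequence: str, gat_start: int, name: str | None = None) -> ConstructDesign:
    """Disrupt one GAT/ATC site by a single middle-base substitution.

    The replacement (preference C > G > T > A) must leave no GAT on either
    strand at the site and create no new GAT/ATC within +/-4 bp of the edit
    (pre-existing neighbouring sites are untouched and allowed).
    """
    tri = sequence[gat_start : gat_start + 3]
    if tri not in ("GAT", "ATC"):
        raise ValueError(f"no GAT/ATC at position {gat_start} (found {tri!r})")
    mid = gat_start + 1
    before = _sites_near(sequence, mid) - {gat_start}
    for base in _KNOCKOUT_PREFERENCE:
        if base == sequence[mid]:
            continue
        edited = sequence[:mid] + base + sequence[mid + 1 :]
        after = _sites_near(edited, mid)
        if gat_start not in after and after <= before:
            return ConstructDesign(
                name=name or f"knockout@{gat_start}",
                sequence=edited,
                edits=[(mid, sequence[mid], base)],
            )
    raise RuntimeError(f"no valid single-base knockout at {gat_start}")


# ---------------------------------------------------------------------------
# the 145-bp positioning template and the experimental construct set

#: The published 147-bp Widom 601 nucleosome positioning sequence
#: (strong synthetic positioning sequence selected in vitro).
WIDOM_601_147 = (
    "CTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTA"
    "CGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATAT"
    "ACATCCTGT"
)


def make_template_601(frame: NucleosomeFrame | None = None) -> str:
    """Synthetic 145-bp positioning template with three intrinsic GAT sites.

    Central 145 bp of the published 601 sequence with the GAT at SHL~5.7
    disrupted by a single middle-base edit, leaving exactly three intrinsic
    GAT-equivalent sites (SHL ~ -6.3, ~ +2.8 and ~ +6.5 with dyad 72).
    This is a synthetic stand-in for the construct template used in the
    source experiments, reconstructed from its described properties; the
    original's exact sequence is not embedded here.
    """
    frame = frame or NucleosomeFrame()
    t = WIDOM_601_147[1:146]
    # intrinsic GAT at 130 sits near SHL5.7; remove it so the template's
    # intrinsic sites match the described three-site layout
    return knockout_gat(t, 130, "template").sequence


def intrinsic_gat_sites(sequence: str) -> list[tuple[int, str]]:
    """(start, strand) of every GAT read 5'->3' on either strand.

    A plus-strand ATC is a minus-strand GAT.
    """
    sites = []
    for i in range(len(sequence) - 2):
        tri = sequence[i : i + 3]
        if tri == "GAT":
            sites.append((i, "+"))
        elif tri == "ATC":
            sites.append((i, "-"))
    return sites


def design_shl5e(template: str, frame: NucleosomeFrame | None = None) -> ConstructDesign:
    """The SHL5e construct: introduced motif phased against the SHL6.5 site.

    The GATA motif is inserted so its ATC trinucleotide lies 6 bp upstream
    of the template's intrinsic solvent-exposed site nearest SHL6.5, placing
    the introduced ATC in the SHL5.5 major groove (one turn inside) and the
    introduced GAT buried at SHL5.
    """
    frame = frame or NucleosomeFrame()
    target = None
    for start, strand in intrinsic_gat_sites(template):
        call = groove_face(shl_of(start + 1, frame, len(template)))
        if call.face == "solvent_major" and abs(call.groove_label - 6.5) < 0.26:
            target = start
            break
    if target is None:
        raise RuntimeError("template has no intrinsic solvent-exposed SHL6.5 site")
    atc_start = target - 3 - 6  # 6-bp spacer between introduced ATC and the site
    ins_start = atc_start - _INS_ATC_OFFSET
    motif = list(INSERTION_MOTIF)
    motif[motif.index("N")] = template[ins_start + INSERTION_MOTIF.index("N")]
    return _apply(template, ins_start, "".join(motif), "SHL5e")


def design_delta_mutants(shl5e: ConstructDesign, frame: NucleosomeFrame | None = None) -> list[ConstructDesign]:
    """Single-site GAT knockouts of the SHL5e construct, named by SHL label."""
    frame = frame or NucleosomeFrame()
    out = []
    for start, strand in intrinsic_gat_sites(shl5e.sequence):
        label = groove_face(shl_of(start + 1, frame, len(shl5e.sequence))).groove_label
        ko = knockout_gat(shl5e.sequence, start, f"{shl5e.name}dSHL{label:g}")
        out.append(ko)
    return out


def geometry_table(sequence: str, frame: NucleosomeFrame | None = None):
    """Per-site geometry calls for every GAT-equivalent in a construct."""
    import pandas as pd

    frame = frame or NucleosomeFrame()
    rows = []
    for start, strand in intrinsic_gat_sites(sequence):
        call = groove_face(shl_of(start + 1, frame, len(sequence)))
        rows.append(
            {
                "start": start,
                "strand": strand,
                "trinucleotide": sequence[start : start + 3],
                "shl": call.shl,
                "phase": call.phase,
                "face": call.face,
                "groove_label": call.groove_label,
            }
        )
    return pd.DataFrame(rows)
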