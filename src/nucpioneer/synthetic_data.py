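"""Synthetic genomes, class-labelled peak sets, and fragment files.

The generator emulates the statistical structure the analyses assume:

* G1 loci carry a convergent GAT-ATC tandem (spacer 3 or 4) embedded in a
  WGATAR; nucleosome dyads sit symmetrically ~two helical turns (+/-21 bp)
  from the motif before factor expression and move >100 bp away after.
* G2 loci carry a single WGATAR in a nucleosome-depleted region: dyads are
  uniform over the window but excluded within +/-80 bp of the motif.
* G3 loci carry a same-strand GAT tandem with a 6-bp spacer; dyads are
  unpositioned before and concentrate ~five helical turns (+/-52 bp) from
  the motif after expression.
* Sonicated controls are uniform over the window plus a margin.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dyad_profile import MOTIF_LEN
from .io_tracks import (
    Fragment,
    Genome,
    GenomicInterval,
    Peak,
    write_bed,
    write_fasta,
    write_peaks,
    write_table,
)

# Planted locus sequences. Each embeds one WGATAR (TGATAA at plant offset 0)
# whose centre (offset 3) anchors the dyad model, plus the class tandem.
#   G1 spacer 3: TGATAACATC   (GAT@1 ... ATC@7)
#   G1 spacer 4: TGATAAACATC  (GAT@1 ... ATC@8)
#   G3 spacer 6: TGATAACAAAGATAC (GAT@1 ... GAT@10)
#   G2:          TGATAA
_PLANT = {
    ("G1", 3): "TGATAACATC",
    ("G1", 4): "TGATAAACATC",
    ("G3", 6): "TGATAACAAAGATAC",
    ("G2", None): "TGATAA",
}
_WGATAR_CENTER_OFFSET = 3  # centre of the planted TGATAA


@dataclass(frozen=True)
class MixtureComponent:
    offset: float
    sd: float
    weight: float


@dataclass(frozen=True)
class DyadModel:
    """Either a Gaussian mixture of offsets or a uniform band with a gap."""

    components: tuple[MixtureComponent, ...] = ()
    uniform: bool = False
    exclude_radius: int = 0  # for uniform models: no dyads within this of the motif

    def __post_init__(self) -> None:
        if not self.uniform:
            w = sum(c.weight for c in self.components)
            if not np.isclose(w, 1.0):
                raise ValueError(f"mixture weights sum to {w}, not 1")


def _sym(offset: float, sd: float) -> DyadModel:
    return DyadModel(
        components=(
            MixtureComponent(-offset, sd, 0.5),
            MixtureComponent(+offset, sd, 0.5),
        )
    )


#: Default dyad models per (class, condition). Offsets 21 bp ~ two helical
#: turns and 52 bp ~ five turns at 10.4 bp/turn.
DEFAULT_DYAD_MODELS: dict[tuple[str, str], DyadModel] = {
    ("G1", "pre"): _sym(21, 3),
    ("G1", "post"): _sym(130, 15),
    ("G2", "pre"): DyadModel(uniform=True, exclude_radius=80),
    ("G2", "post"): DyadModel(uniform=True, exclude_radius=80),
    ("G3", "pre"): DyadModel(uniform=True),
    ("G3", "post"): _sym(52, 3),
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome_length: int = 200_000
    base_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in "ACGT"}
    )
    n_peaks: Mapping[str, int] = field(
        default_factory=lambda: {"G1": 100, "G2": 100, "G3": 100}
    )
    peak_window: int = 200
    g1_spacer_weights: Mapping[int, float] = field(
        default_factory=lambda: {3: 0.5, 4: 0.5}
    )
    dyad_models: Mapping[tuple[str, str], DyadModel] = field(
        default_factory=lambda: dict(DEFAULT_DYAD_MODELS)
    )
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 10.0
    fragment_length_band: tuple[int, int] = (120, 200)
    fragments_per_locus: int = 200
    control_margin: int = 100
    scrub_background_motifs: bool = False
    chrom_name: str = "chrSim"


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: Genome
    peaks: list[Peak]
    truth: pd.DataFrame


def _random_sequence(rng: np.random.Generator, length: int, freqs: Mapping[str, float]) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([freqs[b] for b in "ACGT"], dtype=float)
    if not np.isclose(p.sum(), 1.0) or (p < 0).any():
        raise ValueError("base frequencies must be a probability vector")
    return "".join(rng.choice(bases, size=length, p=p))


def make_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Iid background genome from the configured base composition."""
    rng = rng or np.random.default_rng(config.seed)
    genome = Genome()
    genome.add(config.chrom_name, _random_sequence(rng, config.genome_length, config.base_frequencies))
    return genome


#: WGATAR on the plus strand, or its reverse complement (a minus-strand hit).
_WGATAR_EITHER = re.compile(r"(?=[AT]GATA[AG]|[CT]TATC[AT])")


def _scrub_wgatar(seq: list[str], protected: Sequence[tuple[int, int]]) -> None:
    """Disrupt every WGATAR on either strand outside protected spans.

    Base 3 of the 6-mer (the T of GATA, or the T of the TATC complement) is
    flipped, which destroys the match at that frame; flips can create new
    frames nearby, so passes repeat until a full rescan finds nothing.
    """
    prot = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        prot[max(0, s) : min(len(seq), e)] = True
    for _ in range(32):
        s = "".join(seq)
        edited = False
        for m in _WGATAR_EITHER.finditer(s):
            i = m.start()
            if prot[i : i + MOTIF_LEN].any():
                continue
            seq[i + 3] = "C" if seq[i + 3] != "C" else "G"
            edited = True
        if not edited:
            return
    raise RuntimeError("motif scrub did not converge")


def plant_peaks(
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Place non-overlapping class-labelled peak windows with planted motifs.

    Each window is centred on its summit; the class motif plan is written
    into the genome with the planted WGATAR centre at the summit. Planted
    coordinates go to a truth table. With ``scrub_background_motifs`` every
    WGATAR outside peak windows is disrupted by a single-base edit.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    w = config.peak_window
    total = sum(config.n_peaks.values())
    L = config.genome_length
    spacing = L // total
    if spacing < w + 10:
        raise ValueError("genome too short for non-overlapping peak placement")
    seq = list(genome.sequences[config.chrom_name])

    classes = [c for c, n in sorted(config.n_peaks.items()) for _ in range(n)]
    order = rng.permutation(len(classes))
    peaks: list[Peak] = []
    rows = []
    windows = []
    for k, idx in enumerate(order):
        cls = classes[idx]
        slot_lo = k * spacing
        jitter = int(rng.integers(0, max(1, spacing - w)))
        start = min(slot_lo + jitter, L - w)
        summit = start + w // 2
        if cls == "G1":
            spacers = sorted(config.g1_spacer_weights)
            pw = np.array([config.g1_spacer_weights[s] for s in spacers], dtype=float)
            spacer = int(rng.choice(spacers, p=pw / pw.sum()))
            plant = _PLANT[("G1", spacer)]
        elif cls == "G3":
            spacer = 6
            plant = _PLANT[("G3", 6)]
        else:
            spacer = -1
            plant = _PLANT[("G2", None)]
        plant_start = summit - _WGATAR_CENTER_OFFSET
        seq[plant_start : plant_start + len(plant)] = list(plant)
        peak = Peak(f"{cls}_{k:04d}", GenomicInterval(config.chrom_name, start, start + w), summit, cls)
        peaks.append(peak)
        windows.append((start, start + w))
        rows.append(
            {
                "id": peak.id,
                "class_label": cls,
                "chrom": config.chrom_name,
                "summit": summit,
                "motif_center": summit,
                "plant_start": plant_start,
                "plant_seq": plant,
                "spacer": spacer,
                "orientation": {"G1": "GA", "G3": "GG", "G2": "."}[cls],
            }
        )

    if config.scrub_background_motifs:
        _scrub_wgatar(seq, windows)

    genome.sequences[config.chrom_name] = "".join(seq)
    truth = pd.DataFrame(rows)
    peaks.sort(key=lambda p: p.interval.start)
    return SimulatedDataset(config=config, genome=genome, peaks=peaks, truth=truth)


def _draw_fragment_lengths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    lo, hi = config.fragment_length_band
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=2 * (n - filled))
        draw = np.rint(draw).astype(np.int64)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _draw_offsets(rng: np.random.Generator, n: int, model: DyadModel, half_window: int) -> np.ndarray:
    if model.uniform:
        offs = rng.integers(-half_window, half_window + 1, size=2 * n + 16)
        if model.exclude_radius:
            offs = offs[np.abs(offs) > model.exclude_radius]
        while offs.size < n:
            extra = rng.integers(-half_window, half_window + 1, size=n)
            if model.exclude_radius:
                extra = extra[np.abs(extra) > model.exclude_radius]
            offs = np.concatenate([offs, extra])
        return offs[:n]
    weights = np.array([c.weight for c in model.components])
    comp = rng.choice(len(model.components), size=n, p=weights)
    mu = np.array([c.offset for c in model.components])[comp]
    sd = np.array([c.sd for c in model.components])[comp]
    offs = np.rint(rng.normal(mu, sd)).astype(np.int64)
    return np.clip(offs, -half_window, half_window)


def simulate_fragments(
    dataset: SimulatedDataset,
    condition: str,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Fragments whose midpoints follow each class's dyad model.

    Midpoint = planted motif centre + offset drawn from the (class,
    condition) model; fragment length from the truncated normal band.
    """
    config = dataset.config
    rng = rng or np.random.default_rng(config.seed + {"pre": 2, "post": 3}[condition])
    # uniform models live on the peak window; Gaussian mixtures may place
    # dyads beyond it (e.g. >100 bp offsets) and truncate at the control span
    half = config.peak_window // 2
    half_gauss = half + config.control_margin
    frags: list[Fragment] = []
    centers = dict(zip(dataset.truth["id"], dataset.truth["motif_center"]))
    for peak in dataset.peaks:
        model = config.dyad_models.get((peak.class_label, condition))
        if model is None:
            raise ValueError(f"no dyad model for ({peak.class_label}, {condition})")
        n = config.fragments_per_locus
        offs = _draw_offsets(rng, n, model, half if model.uniform else half_gauss)
        mids = centers[peak.id] + offs
        lens = _draw_fragment_lengths(rng, n, config)
        starts = mids - (lens - 1) // 2
        for s, ln in zip(starts, lens):
            s = int(max(0, min(s, config.genome_length - ln)))
            frags.append(Fragment(GenomicInterval(peak.interval.chrom, s, s + int(ln))))
    return frags


def simulate_control(
    dataset: SimulatedDataset,
    rng: np.random.Generator | None = None,
    depth_per_locus: int | None = None,
) -> list[Fragment]:
    """Sonication stand-in: midpoints uniform over window +/- margin."""
    config = dataset.config
    rng = rng or np.random.default_rng(config.seed + 4)
    half = config.peak_window // 2 + config.control_margin
    n = depth_per_locus if depth_per_locus is not None else config.fragments_per_locus
    frags: list[Fragment] = []
    for peak in dataset.peaks:
        offs = rng.integers(-half, half + 1, size=n)
        mids = peak.summit + offs
        lens = _draw_fragment_lengths(rng, n, config)
        starts = mids - (lens - 1) // 2
        for s, ln in zip(starts, lens):
            s = int(max(0, min(s, config.genome_length - ln)))
            frags.append(Fragment(GenomicInterval(peak.interval.chrom, s, s + int(ln))))
    return frags


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Genome + planted peaks in one call (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config, rng)
    return plant_peaks(genome, config, rng)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, peaks.tsv, truth.tsv, fragments_{pre,post}.bed, control.bed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "peaks": outdir / "peaks.tsv",
        "truth": outdir / "truth.tsv",
        "fragments_pre": outdir / "fragments_pre.bed",
        "fragments_post": outdir / "fragments_post.bed",
        "control": outdir / "control.bed",
    }
    write_fasta(dataset.genome, paths["genome"])
    write_peaks(dataset.peaks, paths["peaks"])
    write_table(dataset.truth, paths["truth"])
    for cond in ("pre", "post"):
        frags = simulate_fragments(dataset, cond)
        write_bed([f.interval for f in frags], paths[f"fragments_{cond}"])
    control = simulate_control(dataset)
    write_bed([f.interval for f in control], paths["control"])
    return paths
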