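"""Synthetic chromatin and chemical-cleavage fragment generator.

Emulates the statistics the downstream analyses assume: per-cell nucleosome
arrays phased at promoters with quantized linkers, a nucleosome-depleted
region (NDR) at each promoter, two cleavage sites per nucleosome cutting
independently with probability ``p``, a fixed number of base pairs lost at
every realized cut (the "gap"), 51-bp intranucleosomal cores, and a uniform
background of spurious fragments.

Cleavage geometry. A nucleosome with dyad ``d`` owns two cleavage sites at
``d -/+ (c + 1/2 gap)`` with ``c = (core - 1) / 2``; a realized cut at the
left site makes the upstream piece end at ``d - (c + gap + 1)`` and the
downstream piece start at ``d - c`` (mirror-image on the right), so cutting
both sites of one nucleosome releases exactly the ``core``-bp fragment
centered on the dyad, two dyad-proximal cuts of neighbors spaced NRL apart
release an ``NRL - core - 2*gap`` fragment, and skipping one intervening
site releases an ``NRL - gap`` fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import ChromosomeSpec, FragmentRecord, GeneAnnotation

#: default per-cleavage-site cut probability
DEFAULT_CUT_PROBABILITY = 0.8
#: default fraction of spurious (free-phenanthroline) fragments
DEFAULT_BACKGROUND_RATE = 0.05


@dataclass
class SyntheticConfig:
    """Stated world for the generator; every analysis default lives here."""

    seed: int
    genome: list[ChromosomeSpec]
    genes: list[GeneAnnotation]
    n_cells: int = 40
    nucleosome_length: int = 147
    linker_lengths: tuple[int, ...] = (5, 15, 25)
    linker_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    ndr_width_range: tuple[int, int] = (80, 160)
    cut_probability: float = DEFAULT_CUT_PROBABILITY
    gap: int = 4
    core_length: int = 51
    background_rate: float = DEFAULT_BACKGROUND_RATE
    plus_one_offset: int = 60
    gc_oscillation: bool = False
    ww_amplitude: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.cut_probability <= 1:
            raise ValueError("cut_probability must be in (0, 1]")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")
        if self.nucleosome_length % 2 == 0:
            raise ValueError("nucleosome_length must be odd (single-bp dyad)")
        if self.core_length % 2 == 0:
            raise ValueError("core_length must be odd")
        if len(self.linker_lengths) != len(self.linker_weights):
            raise ValueError("linker_lengths and linker_weights differ in length")
        w = np.asarray(self.linker_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("linker weights must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class CellConfiguration:
    """Ordered dyad positions per chromosome for one cell."""

    dyads: dict[str, np.ndarray]


@dataclass(frozen=True)
class GeneGeometry:
    """Per-gene ground truth: flanking dyads and the NDR interval."""

    gene_id: str
    chrom: str
    strand: str
    plus_one: int
    minus_one: int
    ndr_width: int

    @property
    def ndr_center(self) -> int:
        return (self.plus_one + self.minus_one) // 2


# randomness stream ids
_STREAM_GEOMETRY = 0
_STREAM_CHROMATIN = 1
_STREAM_CLEAVE = 2
_STREAM_SEQUENCE = 3


def gene_geometry(cfg: SyntheticConfig) -> list[GeneGeometry]:
    """Draw the fixed promoter geometry (+1/-1 dyads, NDR width) per gene.

    The NDR width is drawn once per gene (not per cell) so the NDR center is
    a well-defined ground truth; per-cell variability enters through the
    linkers drawn in :func:`generate_chromatin`.
    """
    rng = cfg.rng(_STREAM_GEOMETRY)
    lo, hi = cfg.ndr_width_range
    out = []
    for g in cfg.genes:
        direction = 1 if g.strand == "+" else -1
        p1 = g.tss + direction * cfg.plus_one_offset
        w = int(rng.integers(lo, hi + 1))
        m1 = p1 - direction * (cfg.nucleosome_length + w)
        out.append(GeneGeometry(g.gene_id, g.chrom, g.strand, p1, m1, w))
    return out


def _territories(
    cfg: SyntheticConfig, geoms: Sequence[GeneGeometry]
) -> dict[str, list[tuple[GeneGeometry, int, int]]]:
    """Disjoint genomic interval owned by each gene, split at anchor midpoints."""
    by_chrom: dict[str, list[GeneGeometry]] = {}
    for gm in geoms:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    lengths = {c.name: c.length for c in cfg.genome}
    out: dict[str, list[tuple[GeneGeometry, int, int]]] = {}
    for chrom, gms in by_chrom.items():
        gms = sorted(gms, key=lambda g: g.plus_one)
        L = lengths[chrom]
        terr = []
        for i, gm in enumerate(gms):
            left = 1 if i == 0 else (gms[i - 1].plus_one + gm.plus_one) // 2 + 1
            right = L if i == len(gms) - 1 else (gm.plus_one + gms[i + 1].plus_one) // 2
            if right - left + 1 < cfg.nucleosome_length:
                raise ValueError(
                    f"gene {gm.gene_id}: territory too small to fit one nucleosome"
                )
            terr.append((gm, left, right))
        out[chrom] = terr
    return out


def generate_chromatin(cfg: SyntheticConfig) -> list[CellConfiguration]:
    """Tile per-cell nucleosome arrays outward from each gene's +1 dyad.

    Dyad-to-dyad spacings are ``nucleosome_length + linker`` with linkers
    drawn independently from the configured mixture; the promoter NDR (the
    interval between the -1 and +1 cores) stays dyad-free.
    """
    geoms = gene_geometry(cfg)
    terr = _territories(cfg, geoms)
    rng = cfg.rng(_STREAM_CHROMATIN)
    linkers = np.asarray(cfg.linker_lengths)
    weights = np.asarray(cfg.linker_weights, dtype=float)
    lengths = {c.name: c.length for c in cfg.genome}
    half = cfg.nucleosome_length // 2

    cells = []
    for _ in range(cfg.n_cells):
        dyads: dict[str, np.ndarray] = {}
        for chrom, gene_territories in terr.items():
            lo_valid, hi_valid = 1 + half, lengths[chrom] - half
            positions: list[int] = []
            for gm, left, right in gene_territories:
                direction = 1 if gm.strand == "+" else -1
                # downstream arm: +1, +2, ... in the gene-body direction
                d = gm.plus_one
                while left <= d <= right and lo_valid <= d <= hi_valid:
                    positions.append(d)
                    d += direction * (
                        cfg.nucleosome_length + linkers[rng.choice(len(linkers), p=weights)]
                    )
                # upstream arm: -1, -2, ... behind the NDR
                d = gm.minus_one
                while left <= d <= right and lo_valid <= d <= hi_valid:
                    positions.append(d)
                    d -= direction * (
                        cfg.nucleosome_length + linkers[rng.choice(len(linkers), p=weights)]
                    )
            arr = np.sort(np.asarray(positions, dtype=np.int64))
            # territories are disjoint but adjacent arms may abut; enforce hard core
            keep = np.ones(len(arr), dtype=bool)
            last = -(10**9)
            for i, d in enumerate(arr):
                if d - last < cfg.nucleosome_length:
                    keep[i] = False
                else:
                    last = d
            dyads[chrom] = arr[keep]
        cells.append(CellConfiguration(dyads))
    return cells


def consensus_configuration(cfg: SyntheticConfig) -> CellConfiguration:
    """Deterministic dyad tiling at the mean linker; the anchor set for
    sequence-signal embedding and rotational-position tests."""
    mean_linker = int(round(float(np.dot(cfg.linker_lengths, cfg.linker_weights))))
    det = SyntheticConfig(
        seed=cfg.seed,
        genome=cfg.genome,
        genes=cfg.genes,
        n_cells=1,
        nucleosome_length=cfg.nucleosome_length,
        linker_lengths=(mean_linker,),
        linker_weights=(1.0,),
        ndr_width_range=cfg.ndr_width_range,
        cut_probability=cfg.cut_probability,
        gap=cfg.gap,
        core_length=cfg.core_length,
        background_rate=0.0,
        plus_one_offset=cfg.plus_one_offset,
    )
    return generate_chromatin(det)[0]


def cleave(
    cells: Sequence[CellConfiguration], cfg: SyntheticConfig
) -> list[FragmentRecord]:
    """Chemically cleave each cell's chromatin into sequenceable fragments.

    Each nucleosome carries two cleavage sites; every site cuts with
    probability ``cut_probability`` independently and a realized cut deletes
    ``gap`` bp. Emitted fragments are the maximal uncut intervals between
    consecutive realized cuts (chromosome-terminal pieces, which are bounded
    by a free end rather than a cut, are not emitted). A fraction
    ``background_rate`` of the output is uniform random intervals with
    lengths resampled from the real fragments.
    """
    rng = cfg.rng(_STREAM_CLEAVE)
    c = (cfg.core_length - 1) // 2
    g = cfg.gap
    frags: list[FragmentRecord] = []
    for cell in cells:
        for chrom, dyads in cell.dyads.items():
            if len(dyads) == 0:
                continue
            # each cut is (end of upstream piece, start of downstream piece)
            left_cut = np.stack([dyads - (c + g + 1), dyads - c], axis=1)
            right_cut = np.stack([dyads + c, dyads + (c + g + 1)], axis=1)
            sites = np.concatenate([left_cut, right_cut], axis=0)
            sites = sites[np.argsort(sites[:, 0])]
            realized = sites[rng.random(len(sites)) < cfg.cut_probability]
            for i in range(len(realized) - 1):
                start = int(realized[i, 1])
                end = int(realized[i + 1, 0])
                if start <= end:
                    frags.append(FragmentRecord(chrom, start, end))
    if cfg.background_rate > 0 and frags:
        n_bg = int(round(len(frags) * cfg.background_rate / (1 - cfg.background_rate)))
        lengths = np.array([f.length for f in frags])
        chrom_names = [cs.name for cs in cfg.genome]
        chrom_lens = np.array([cs.length for cs in cfg.genome], dtype=float)
        p_chrom = chrom_lens / chrom_lens.sum()
        for _ in range(n_bg):
            ln = int(rng.choice(lengths))
            ci = rng.choice(len(chrom_names), p=p_chrom)
            Lc = int(chrom_lens[ci])
            if ln >= Lc:
                ln = Lc
            start = int(rng.integers(1, Lc - ln + 2))
            frags.append(FragmentRecord(chrom_names[ci], start, start + ln - 1))
    return frags


def generate_sequence(cfg: SyntheticConfig) -> dict[str, str]:
    """Random genome with an optional 10-bp WW periodicity under dyads.

    Bases are i.i.d. uniform except within +/-73 bp of each consensus dyad
    when ``gc_oscillation`` is set, where the probability of a weak base
    (A or T) is ``0.5 + ww_amplitude * cos(2 pi x / 10)`` at dyad offset x.
    """
    rng = cfg.rng(_STREAM_SEQUENCE)
    half = cfg.nucleosome_length // 2
    p_weak: dict[str, np.ndarray] = {
        cs.name: np.full(cs.length, 0.5) for cs in cfg.genome
    }
    if cfg.gc_oscillation and cfg.ww_amplitude > 0:
        if not 0 < cfg.ww_amplitude <= 0.5:
            raise ValueError("ww_amplitude must be in (0, 0.5]")
        offsets = np.arange(-half, half + 1)
        wave = 0.5 + cfg.ww_amplitude * np.cos(2 * np.pi * offsets / 10.0)
        consensus = consensus_configuration(cfg)
        for chrom, dyads in consensus.dyads.items():
            vec = p_weak[chrom]
            for d in dyads:
                lo = d - 1 - half
                hi = d - 1 + half + 1
                if lo >= 0 and hi <= len(vec):
                    vec[lo:hi] = wave
    genome: dict[str, str] = {}
    bases = np.array(list("ATCG"))
    for chrom, pw in p_weak.items():
        weak = rng.random(len(pw)) < pw
        coin = rng.integers(0, 2, size=len(pw))
        idx = np.where(weak, coin, 2 + coin)  # A/T if weak else C/G
        genome[chrom] = "".join(bases[idx])
    return genome


# ---------------------------------------------------------------------------
# ready-made stated world
# ---------------------------------------------------------------------------

def default_world(
    seed: int,
    *,
    n_genes: int = 150,
    gene_spacing: int = 2000,
    n_cells: int = 40,
    **overrides,
) -> SyntheticConfig:
    """One-chromosome default configuration: ``n_genes`` tandem '+' genes
    spaced ``gene_spacing`` bp apart, yielding >1e5 fragments at defaults."""
    margin = 1000
    L = 2 * margin + n_genes * gene_spacing
    genome = [ChromosomeSpec("chrS", L)]
    genes = []
    for i in range(n_genes):
        tss = margin + i * gene_spacing + 500
        genes.append(GeneAnnotation(f"gene{i:04d}", "chrS", "+", tss, tss + 1200))
    return SyntheticConfig(
        seed=seed, genome=genome, genes=genes, n_cells=n_cells, **overrides
    )
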