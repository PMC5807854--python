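"""Promoter nucleosome architecture: NDR detection, template-based +1/-1
dyad refinement, and gene-pair orientation classification.

Nucleosomes occupy alternative rotational positions in different cells,
spaced by multiples of the ~10-bp helical twist. The refinement template is
a symmetric comb of Gaussians at 0, +/-10, +/-20, +/-30 bp with linearly
decaying weights,

    D0(x) = G(x,0,2) + 0.75 G(x,+/-10,2) + 0.50 G(x,+/-20,2)
          + 0.25 G(x,+/-30,2),       G(x,c,s) = exp(-(x-c)^2 / (2 s^2)),

whose cross-correlation with the pooled dyad counts peaks at the center of a
cluster of rotational positions rather than at its strongest single member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import DyadProfile, GeneAnnotation, OccupancyProfile

#: template comb support (bp offsets)
TEMPLATE_SUPPORT = 35
#: half the refinement search window (bp)
SEARCH_HALF_WINDOW = 25


def template_value(x) -> np.ndarray | float:
    """Evaluate the oscillatory dyad template D0 at offset(s) ``x`` (bp)."""
    x = np.asarray(x, dtype=float)
    sigma = 2.0
    val = np.zeros_like(x)
    for c, w in ((0, 1.0), (10, 0.75), (20, 0.50), (30, 0.25)):
        val += w * np.exp(-((x - c) ** 2) / (2 * sigma**2))
        if c:
            val += w * np.exp(-((x + c) ** 2) / (2 * sigma**2))
    return val if val.shape else float(val)


_TEMPLATE_OFFSETS = np.arange(-TEMPLATE_SUPPORT, TEMPLATE_SUPPORT + 1)
_TEMPLATE = template_value(_TEMPLATE_OFFSETS)


@dataclass
class NDRCall:
    gene_id: str
    chrom: str
    strand: str
    center: int
    run_width: int  # length of the low-occupancy run
    width: int  # distance between half-maximum crossings flanking the run
    minus_one: int  # provisional -1 dyad (genomically left for '+' genes)
    plus_one: int  # provisional +1 dyad


@dataclass
class NucCall:
    gene_id: str
    role: str  # '+1' or '-1'
    chrom: str
    dyad: int
    score: float
    flagged: bool = False


def detect_ndrs(
    occ: OccupancyProfile,
    genes: Sequence[GeneAnnotation],
    dyads: DyadProfile | None = None,
    *,
    threshold: float = 0.4,
    min_run: int = 50,
    window_upstream: int = 500,
    window_downstream: int = 150,
    flank_search: int = 147,
) -> list[NDRCall]:
    """Call one NDR per gene as the widest low-occupancy run near the TSS.

    Within a transcription-oriented promoter window (default TSS-500 ..
    TSS+150) the widest maximal run with occupancy < ``threshold`` times the
    chromosome mean and length >= ``min_run`` bp is reported; its midpoint is
    the NDR center and ``width`` is measured between the half-maximum
    crossings adjacent to the flanking peaks. Provisional -1/+1 dyads are
    the argmax of the dyad-count profile within ``flank_search`` bp beyond
    each run edge when ``dyads`` is supplied (a footprint-occupancy peak
    around a well-positioned nucleosome is a flat-top plateau whose local
    maxima do not localize the dyad); without a dyad profile they fall back
    to the first local occupancy maxima flanking the run. Genes without a
    qualifying run are omitted (reported as "no NDR" by callers that care).
    """
    calls: list[NDRCall] = []
    for g in genes:
        vec = occ.data[g.chrom]
        L = len(vec)
        cut = threshold * vec.mean()
        if g.strand == "+":
            lo, hi = g.tss - window_upstream, g.tss + window_downstream
        else:
            lo, hi = g.tss - window_downstream, g.tss + window_upstream
        lo, hi = max(1, lo), min(L, hi)
        if hi - lo + 1 < min_run:
            continue
        sub = vec[lo - 1 : hi]
        below = sub < cut
        best = None  # (run length, start, end) in genomic bp
        i = 0
        n = len(below)
        while i < n:
            if below[i]:
                j = i
                while j + 1 < n and below[j + 1]:
                    j += 1
                run_len = j - i + 1
                if run_len >= min_run and (best is None or run_len > best[0]):
                    best = (run_len, lo + i, lo + j)
                i = j + 1
            else:
                i += 1
        if best is None:
            continue
        run_len, run_lo, run_hi = best
        center = (run_lo + run_hi) // 2
        left_max = right_max = None
        if dyads is not None:
            dvec = dyads.data[g.chrom]
            left_max = _dyad_argmax(dvec, run_lo - flank_search, run_lo - 1)
            right_max = _dyad_argmax(dvec, run_hi + 1, run_hi + flank_search)
        if left_max is None:
            left_max = _first_local_max(vec, run_lo - 1, -1)
        if right_max is None:
            right_max = _first_local_max(vec, run_hi + 1, +1)
        if left_max is None or right_max is None:
            continue
        width = _half_max_width(vec, left_max, right_max)
        if g.strand == "+":
            m1, p1 = left_max, right_max
        else:
            m1, p1 = right_max, left_max
        calls.append(
            NDRCall(g.gene_id, g.chrom, g.strand, center, run_len, width, m1, p1)
        )
    return calls


def _dyad_argmax(dvec: np.ndarray, lo: int, hi: int) -> int | None:
    """1-based argmax of dyad counts on [lo, hi]; None if the window is
    empty of dyads or off-chromosome."""
    lo, hi = max(1, lo), min(len(dvec), hi)
    if hi < lo:
        return None
    sub = dvec[lo - 1 : hi]
    if sub.max() <= 0:
        return None
    return lo + int(np.argmax(sub))


def _first_local_max(vec: np.ndarray, start: int, step: int) -> int | None:
    """First local maximum of ``vec`` at or beyond bp ``start`` walking by
    ``step`` (+1 right / -1 left); plateaus return the nearest edge bp."""
    L = len(vec)
    i = start
    while 1 <= i <= L:
        v = vec[i - 1]
        nxt = vec[i - 1 + step] if 1 <= i + step <= L else -np.inf
        prv = vec[i - 1 - step] if 1 <= i - step <= L else -np.inf
        if v > 0 and v >= nxt and v >= prv:
            return i
        i += step
    return None


def _half_max_width(vec: np.ndarray, left_peak: int, right_peak: int) -> int:
    """Distance between the half-maximum crossings on the NDR-facing slopes
    of the two flanking peaks."""
    half_l = vec[left_peak - 1] / 2
    half_r = vec[right_peak - 1] / 2
    i = left_peak
    while i < right_peak and vec[i - 1] > half_l:
        i += 1
    j = right_peak
    while j > left_peak and vec[j - 1] > half_r:
        j -= 1
    return max(0, j - i)


def refine_flank(
    dyads: DyadProfile,
    chrom: str,
    provisional: int,
    *,
    half_window: int = SEARCH_HALF_WINDOW,
    gene_id: str = "",
    role: str = "+1",
) -> NucCall:
    """Refine a provisional flanking-nucleosome dyad with the D0 template.

    Scans candidate centers c within ``provisional +/- half_window`` and
    returns the argmax of sum_x dyads(c+x) * D0(x) over x in [-35, 35]. Ties
    are broken by the smallest |c - provisional|, then the lower coordinate.
    An all-zero search neighborhood returns the provisional dyad, flagged.
    """
    vec = dyads.data[chrom]
    L = len(vec)
    if not 1 <= provisional <= L:
        raise ValueError(f"provisional dyad {provisional} outside {chrom}")
    candidates = np.arange(
        max(1, provisional - half_window), min(L, provisional + half_window) + 1
    )
    scores = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        x = _TEMPLATE_OFFSETS + c
        valid = (x >= 1) & (x <= L)
        scores[i] = float(np.dot(vec[x[valid] - 1], _TEMPLATE[valid]))
    if np.all(scores == 0):
        return NucCall(gene_id, role, chrom, provisional, 0.0, flagged=True)
    best = scores.max()
    tied = candidates[scores >= best - 1e-12 * max(1.0, abs(best))]
    dist = np.abs(tied - provisional)
    tied = tied[dist == dist.min()]
    c = int(tied.min())
    return NucCall(gene_id, role, chrom, c, float(best))


def refine_calls(dyads: DyadProfile, ndr_calls: Sequence[NDRCall]) -> list[NucCall]:
    """Refine both flanks of every NDR call."""
    out = []
    for nc in ndr_calls:
        out.append(
            refine_flank(dyads, nc.chrom, nc.plus_one, gene_id=nc.gene_id, role="+1")
        )
        out.append(
            refine_flank(dyads, nc.chrom, nc.minus_one, gene_id=nc.gene_id, role="-1")
        )
    return out


@dataclass
class GenePairLabels:
    gene_id: str
    five_prime: str  # 'divergent' | 'tandem' | 'no neighbor'
    three_prime: str  # 'convergent' | 'tandem' | 'no neighbor'
    upstream_distance: int | None  # 5' end to the upstream neighbor's nearest end
    downstream_distance: int | None


def classify_gene_pairs(genes: Sequence[GeneAnnotation]) -> list[GenePairLabels]:
    """Label each gene's 5' end divergent/tandem and 3' end convergent/tandem.

    Neighbors are taken in genomic order of gene midpoints per chromosome.
    The 5' label is 'divergent' when the upstream neighbor transcribes away
    from this gene, 'tandem' when it transcribes toward/through; mirror logic
    at the 3' end. Chromosome-terminal ends are labeled 'no neighbor'.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    labels: dict[str, GenePairLabels] = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tss + g.tts) / 2)
        for i, g in enumerate(gs):
            left = gs[i - 1] if i > 0 else None
            right = gs[i + 1] if i + 1 < len(gs) else None
            if g.strand == "+":
                up, down = left, right
            else:
                up, down = right, left
            if up is None:
                five, d5 = "no neighbor", None
            else:
                five = "divergent" if up.strand != g.strand else "tandem"
                d5 = abs(g.tss - (up.tts if five == "tandem" else up.tss))
            if down is None:
                three, d3 = "no neighbor", None
            else:
                three = "convergent" if down.strand != g.strand else "tandem"
                d3 = abs(g.tts - (down.tts if three == "convergent" else down.tss))
            labels[g.gene_id] = GenePairLabels(g.gene_id, five, three, d5, d3)
    return [labels[g.gene_id] for g in genes]
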