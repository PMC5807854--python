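"""Two-dimensional occupancy (fragment length x position), V-plot end
matrices, and anchor-aligned heatmaps.

The length-position matrix generalizes the 1D occupancy track: the column
sums reproduce the 1D occupancy restricted to the retained length range, and
the row sums reproduce the fragment length histogram (each fragment of
length ``l`` contributes ``l`` covered bp to row ``l``, so row sums divided
by ``l`` count fragments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import FragmentRecord, Profile

#: value used for positions falling outside a chromosome
MISSING = np.nan


@dataclass(frozen=True)
class Anchor:
    """A strand-oriented alignment point (e.g. a +1 dyad or NDR center)."""

    name: str
    chrom: str
    pos: int
    strand: str = "+"


@dataclass
class LengthPositionMatrix:
    matrix: np.ndarray  # rows: lengths, cols: positions
    lengths: np.ndarray  # row index -> fragment length (bp)
    positions: np.ndarray  # col index -> position (genomic or anchor-relative)
    n_anchors: int = 1

    def column_marginal(self) -> np.ndarray:
        """1D occupancy restricted to the retained length range."""
        return self.matrix.sum(axis=0)

    def row_marginal(self) -> np.ndarray:
        """Fragment length histogram (counts of fragments fully in window)."""
        with np.errstate(invalid="ignore"):
            return self.matrix.sum(axis=1) / self.lengths

    def relative(self, mean_occupancy: float = 1.0) -> np.ndarray:
        """Relative occupancy: counts / (n_anchors * mean occupancy)."""
        return self.matrix / (self.n_anchors * mean_occupancy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.lengths, columns=self.positions)


@dataclass
class EndMatrix:
    left: np.ndarray
    right: np.ndarray
    lengths: np.ndarray
    positions: np.ndarray


@dataclass
class AlignedHeatmap:
    matrix: np.ndarray  # rows: anchors (sorted), cols: window offsets
    anchors: list[Anchor]  # row order after sorting
    offsets: np.ndarray
    sort_keys: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=[a.name for a in self.anchors], columns=self.offsets
        )

    def column_means(self) -> np.ndarray:
        """Per-offset average over anchors, ignoring out-of-chromosome pads."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-pad columns
            return np.nanmean(self.matrix, axis=0)


def _relative_coords(
    frag: FragmentRecord, anchor: Anchor
) -> tuple[int, int]:
    """Fragment start/end in anchor-relative, strand-oriented coordinates."""
    if anchor.strand == "-":
        return anchor.pos - frag.end, anchor.pos - frag.start
    return frag.start - anchor.pos, frag.end - anchor.pos


def build_2d_occupancy(
    frags: Sequence[FragmentRecord],
    anchors: Sequence[Anchor],
    window: tuple[int, int] = (-500, 1000),
    length_range: tuple[int, int] = (20, 200),
) -> LengthPositionMatrix:
    """Accumulate fragment coverage into a (length x relative position) matrix.

    A fragment of length ``l`` within ``length_range`` adds +1 to row ``l``
    at every anchor-relative position it covers inside ``window``. Counts
    are accumulated over all anchors first; any normalization happens once,
    afterwards (see :meth:`LengthPositionMatrix.relative`).
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    lo_l, hi_l = length_range
    lo_w, hi_w = window
    lengths = np.arange(lo_l, hi_l + 1)
    positions = np.arange(lo_w, hi_w + 1)
    mat = np.zeros((len(lengths), len(positions)))
    by_chrom: dict[str, list[FragmentRecord]] = {}
    for f in frags:
        if lo_l <= f.length <= hi_l:
            by_chrom.setdefault(f.chrom, []).append(f)
    for a in anchors:
        for f in by_chrom.get(a.chrom, ()):
            rs, re = _relative_coords(f, a)
            s = max(rs, lo_w)
            e = min(re, hi_w)
            if s <= e:
                mat[f.length - lo_l, s - lo_w : e - lo_w + 1] += 1
    return LengthPositionMatrix(mat, lengths, positions, n_anchors=len(anchors))


def build_vplot(
    frags: Sequence[FragmentRecord],
    anchors: Sequence[Anchor],
    window: tuple[int, int] = (-500, 500),
    length_range: tuple[int, int] = (20, 200),
) -> EndMatrix:
    """Left/right fragment-end matrices around strand-resolved anchors.

    The left matrix counts the lower-coordinate terminus of each fragment at
    (length, relative position); minus-strand anchors flip the position sign
    and swap the left/right roles, so "left" is always the
    transcription-upstream end.
    """
    lo_l, hi_l = length_range
    lo_w, hi_w = window
    lengths = np.arange(lo_l, hi_l + 1)
    positions = np.arange(lo_w, hi_w + 1)
    left = np.zeros((len(lengths), len(positions)))
    right = np.zeros((len(lengths), len(positions)))
    by_chrom: dict[str, list[FragmentRecord]] = {}
    for f in frags:
        if lo_l <= f.length <= hi_l:
            by_chrom.setdefault(f.chrom, []).append(f)
    for a in anchors:
        for f in by_chrom.get(a.chrom, ()):
            rs, re = _relative_coords(f, a)
            for pos, target in ((rs, left), (re, right)):
                if lo_w <= pos <= hi_w:
                    target[f.length - lo_l, pos - lo_w] += 1
    return EndMatrix(left, right, lengths, positions)


def build_aligned_heatmap(
    profile: Profile,
    anchors: Sequence[Anchor],
    window: tuple[int, int] = (-1000, 1000),
    sort_keys: Sequence[float] | None = None,
) -> AlignedHeatmap:
    """Extract per-anchor profile rows in strand-oriented relative coordinates.

    Rows are sorted ascending by ``sort_keys`` (ties broken by anchor name);
    positions outside the chromosome are padded with NaN, which
    :meth:`AlignedHeatmap.column_means` excludes from averages.
    """
    lo_w, hi_w = window
    offsets = np.arange(lo_w, hi_w + 1)
    if sort_keys is None:
        keys = np.zeros(len(anchors))
    else:
        keys = np.asarray(sort_keys, dtype=float)
        if len(keys) != len(anchors):
            raise ValueError("sort_keys length must match anchor count")
    order = sorted(range(len(anchors)), key=lambda i: (keys[i], anchors[i].name))
    mat = np.full((len(anchors), len(offsets)), MISSING)
    for row, i in enumerate(order):
        a = anchors[i]
        vec = profile.data[a.chrom]
        L = len(vec)
        if a.strand == "-":
            idx = a.pos - offsets  # oriented: offset +x is upstream in genome
        else:
            idx = a.pos + offsets
        valid = (idx >= 1) & (idx <= L)
        mat[row, valid] = vec[idx[valid] - 1]
    return AlignedHeatmap(
        mat, [anchors[i] for i in order], offsets, keys[np.array(order)]
    )
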