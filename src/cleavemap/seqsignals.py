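"""Sequence-composition signals around aligned nucleosome dyads.

WW dinucleotides (AA, AT, TA, TT) preferentially face the histone surface
where the DNA minor groove contacts the octamer, alternating every ~10 bp
with SS dinucleotides (CC, CG, GC, GG); a 10-bp periodicity in the dyad-
aligned WW frequency therefore reports rotational positioning. Both classes
are closed under reverse complement, so strand-flipped anchors are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import DyadProfile

WW = {"AA", "AT", "TA", "TT"}
SS = {"CC", "CG", "GC", "GG"}

#: dinucleotide at offset x spans bases (dyad + x, dyad + x + 1)
DINUC_CONVENTION = "offset x covers (dyad+x, dyad+x+1)"


@dataclass
class DinucleotideProfile:
    offsets: np.ndarray
    ww: np.ndarray  # frequency of WW starting at each offset
    ss: np.ndarray
    n_dyads_used: float
    n_dyads_skipped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "ww_freq": self.ww, "ss_freq": self.ss}
        )


def _dinuc_classes(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position boolean arrays: dinucleotide starting at i is WW / SS /
    unambiguous (no N in either base). Length = len(seq) - 1."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    a, b = arr[:-1], arr[1:]
    is_w = lambda x: (x == b"A") | (x == b"T")
    is_s = lambda x: (x == b"C") | (x == b"G")
    ww = is_w(a) & is_w(b)
    ss = is_s(a) & is_s(b)
    ok = (is_w(a) | is_s(a)) & (is_w(b) | is_s(b))
    return ww, ss, ok


def dinucleotide_phasing(
    dyads: DyadProfile,
    genome: Mapping[str, str],
    window: int = 73,
) -> DinucleotideProfile:
    """Dyad-count-weighted WW/SS dinucleotide frequencies around dyads.

    Every dyad contributes its count's worth of weight to the dinucleotide
    starting at each offset in [-window, +window]; frequencies are averages
    over that weight, with ambiguous (N-containing) dinucleotides removed
    from the denominator. Dyads closer than ``window + 1`` bp to a contig
    end are skipped and counted.
    """
    offsets = np.arange(-window, window + 1)
    ww_w = np.zeros(len(offsets))
    ss_w = np.zeros(len(offsets))
    tot_w = np.zeros(len(offsets))
    used = 0.0
    skipped = 0
    for chrom, vec in dyads.data.items():
        seq = genome.get(chrom)
        if seq is None:
            continue
        ww, ss, ok = _dinuc_classes(seq.upper())
        pos = np.nonzero(vec)[0]  # 0-based dyad indices
        counts = vec[pos]
        L = len(seq)
        in_range = (pos - window >= 0) & (pos + window + 1 <= L - 1)
        skipped += int((~in_range).sum())
        for p, w in zip(pos[in_range], counts[in_range]):
            sl = slice(p - window, p + window + 1)
            ww_w += w * ww[sl]
            ss_w += w * ss[sl]
            tot_w += w * ok[sl]
            used += w
    with np.errstate(invalid="ignore", divide="ignore"):
        ww_f = np.where(tot_w > 0, ww_w / tot_w, np.nan)
        ss_f = np.where(tot_w > 0, ss_w / tot_w, np.nan)
    return DinucleotideProfile(offsets, ww_f, ss_f, used, skipped)


def at_content(
    anchors: Sequence[tuple[str, int, str]],
    genome: Mapping[str, str],
    window: int = 1000,
) -> pd.DataFrame:
    """Per-offset A/T fraction across aligned, strand-oriented windows.

    ``anchors`` is a sequence of (chrom, 1-based position, strand); '-'
    anchors are read right-to-left so offset +x is always downstream in
    transcription. Anchors whose window leaves the contig are skipped.
    """
    offsets = np.arange(-window, window + 1)
    at = np.zeros(len(offsets))
    tot = np.zeros(len(offsets))
    for chrom, pos, strand in anchors:
        seq = genome.get(chrom)
        if seq is None:
            continue
        L = len(seq)
        idx = pos - 1 + offsets if strand == "+" else pos - 1 - offsets
        valid = (idx >= 0) & (idx < L)
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        sub = arr[idx[valid]]
        known = (sub == b"A") | (sub == b"T") | (sub == b"C") | (sub == b"G")
        at[valid] += ((sub == b"A") | (sub == b"T")) & known
        tot[valid] += known
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, at / tot, np.nan)
    return pd.DataFrame({"offset": offsets, "at_fraction": frac})


def profile_autocorrelation(profile: np.ndarray, max_lag: int = 30) -> np.ndarray:
    """Autocorrelation (Pearson, mean-subtracted) of a positional profile;
    entry k is the correlation at lag k. Used to read out the 10-bp
    rotational periodicity of WW frequencies."""
    x = np.asarray(profile, dtype=float)
    x = x[np.isfinite(x)]
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return np.zeros(max_lag + 1)
    return np.array(
        [np.dot(x[: len(x) - k], x[k:]) / denom for k in range(max_lag + 1)]
    )
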