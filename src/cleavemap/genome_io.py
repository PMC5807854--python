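"""Data model, file I/O, fragment-to-dyad conversion and occupancy profiles.

Internal coordinates are 1-based inclusive everywhere; BED (0-based,
half-open) is converted at the I/O boundary only. Per-base-pair profiles are
stored as numpy arrays where index ``i`` corresponds to base pair ``i + 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fragment-length window retained for dyad calling (51 +/- 7 bp cores)
DYAD_SIZE_WINDOW = (44, 58)
#: fragment-length window retained for plain coverage occupancy
OCC_SIZE_WINDOW = (50, 200)
#: half-width of the symmetric dyad extension (101-bp footprint)
FOOTPRINT_HALF_WIDTH = 50


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome name and its length in bp."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"chromosome {self.name!r} has length {self.length} < 1")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with transcription start/termination sites (1-based bp).

    For '+' genes ``tss < tts``; for '-' genes ``tss > tts``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss == self.tts:
            raise ValueError(f"gene {self.gene_id}: tss == tts")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: '+' gene requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: '-' gene requires tss > tts")


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced paired-end fragment as a 1-based inclusive interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end}: end < start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        """Fragment center; even lengths round toward the lower coordinate."""
        return (self.start + self.end) // 2


@dataclass
class Profile:
    """Per-chromosome per-bp vector of non-negative reals.

    ``data[chrom][i]`` is the value at base pair ``i + 1``.
    """

    data: dict[str, np.ndarray]
    normalized: bool = False

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def chroms(self) -> list[str]:
        return list(self.data)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "Profile":
        return Profile({c: v.copy() for c, v in self.data.items()}, self.normalized)

    @classmethod
    def zeros(cls, genome: Sequence[ChromosomeSpec]) -> "Profile":
        return cls({c.name: np.zeros(c.length) for c in genome})


# DyadProfile and OccupancyProfile share the container; the distinction is
# what the entries mean (dyad counts vs bp coverage).
DyadProfile = Profile
OccupancyProfile = Profile


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fragments(
    path: str | Path,
    genome: Sequence[ChromosomeSpec] | None = None,
    *,
    dialect: str = "bed",
) -> list[FragmentRecord]:
    """Read fragment intervals from a BED3 or 1-based TSV file.

    ``dialect='bed'``: 0-based half-open (``chrom  start  end``); converted to
    1-based inclusive. ``dialect='tsv'``: columns already 1-based inclusive.
    Records on chromosomes absent from ``genome`` are dropped with a logged
    count rather than raising, to tolerate partial genomes.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    known = {c.name for c in genome} if genome is not None else None
    frags: list[FragmentRecord] = []
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                lo, hi = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if dialect == "bed":
                if hi <= lo:
                    raise ValueError(
                        f"{path}:{lineno}: empty or inverted BED interval {lo}-{hi}"
                    )
                start, end = lo + 1, hi
            else:
                if hi < lo:
                    raise ValueError(f"{path}:{lineno}: end < start")
                start, end = lo, hi
            if known is not None and chrom not in known:
                n_unknown += 1
                continue
            frags.append(FragmentRecord(chrom, start, end))
    if n_unknown:
        logger.warning("dropped %d fragments on unknown chromosomes", n_unknown)
    return frags


def write_fragments(
    frags: Iterable[FragmentRecord], path: str | Path, *, dialect: str = "bed"
) -> None:
    """Write fragments in the BED3 or 1-based TSV dialect (see read_fragments)."""
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for f in frags:
            if dialect == "bed":
                fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\n")
            else:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with columns gene_id, chrom, strand, tss, tts."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss", "tts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.tts))
        for r in df.itertuples(index=False)
    ]


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tts) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "tts"],
    ).to_csv(path, sep="\t", index=False)


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into an upper-cased dict of sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_track(profile: Profile, path: str | Path, *, fmt: str = "bedgraph") -> None:
    """Write a profile as bedGraph (run-length, 0-based half-open) or wiggle.

    Round-trips bit-exactly with :func:`read_track` for integer counts.
    """
    if fmt not in ("bedgraph", "wiggle"):
        raise ValueError(f"unknown track format {fmt!r}")
    with open(path, "w") as fh:
        for chrom, vec in profile.data.items():
            if fmt == "wiggle":
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                for v in vec:
                    fh.write(f"{v:.10g}\n")
            else:
                # run-length encode constant stretches
                n = len(vec)
                i = 0
                while i < n:
                    j = i + 1
                    while j < n and vec[j] == vec[i]:
                        j += 1
                    if vec[i] != 0:
                        fh.write(f"{chrom}\t{i}\t{j}\t{vec[i]:.10g}\n")
                    i = j


def read_track(
    path: str | Path, genome: Sequence[ChromosomeSpec], *, fmt: str = "bedgraph"
) -> Profile:
    """Read a bedGraph or fixed-step wiggle track back into a Profile."""
    prof = Profile.zeros(genome)
    with open(path) as fh:
        if fmt == "wiggle":
            chrom, pos = None, 0
            for line in fh:
                line = line.strip()
                if line.startswith("fixedStep"):
                    kv = dict(p.split("=") for p in line.split()[1:])
                    chrom, pos = kv["chrom"], int(kv["start"]) - 1
                elif line:
                    prof.data[chrom][pos] = float(line)
                    pos += 1
        else:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, lo, hi, val = line.split("\t")
                prof.data[chrom][int(lo) : int(hi)] = float(val)
    return prof


# ---------------------------------------------------------------------------
# fragment -> dyad -> occupancy
# ---------------------------------------------------------------------------

def _filter_by_length(
    frags: Iterable[FragmentRecord], size_window: tuple[int, int]
) -> list[FragmentRecord]:
    lo, hi = size_window
    return [f for f in frags if lo <= f.length <= hi]


def dyads_from_fragments(
    frags: Iterable[FragmentRecord],
    genome: Sequence[ChromosomeSpec],
    size_window: tuple[int, int] = DYAD_SIZE_WINDOW,
) -> DyadProfile:
    """Dyad counts from fragment centers, keeping core-sized fragments only.

    Each retained fragment (length within ``size_window``, default 44-58 bp)
    adds +1 at its midpoint; even lengths round the midpoint down. Returns
    unnormalized counts.
    """
    prof = Profile.zeros(genome)
    kept = _filter_by_length(frags, size_window)
    if not kept:
        warnings.warn("no fragments within the dyad size window; all-zero profile")
    for f in kept:
        vec = prof.data.get(f.chrom)
        if vec is None:
            raise KeyError(f"fragment on unknown chromosome {f.chrom!r}")
        mid = f.midpoint
        if not 1 <= mid <= len(vec):
            raise ValueError(f"midpoint {mid} outside chromosome {f.chrom}")
        vec[mid - 1] += 1
    return prof


def normalize_profile(p: Profile) -> Profile:
    """Divide each chromosome by its mean so the per-chromosome average is 1."""
    out: dict[str, np.ndarray] = {}
    for chrom, vec in p.data.items():
        m = vec.mean()
        if m == 0:
            raise ValueError(f"cannot normalize all-zero chromosome {chrom!r}")
        out[chrom] = vec / m
    return Profile(out, normalized=True)


def occupancy_from_dyads(
    d: DyadProfile, half_width: int = FOOTPRINT_HALF_WIDTH
) -> OccupancyProfile:
    """Symmetric dyad extension: Occ(i) = sum of dyad counts within +/- h bp.

    The default half-width of 50 bp gives each dyad a 101-bp footprint,
    clipped at chromosome edges.
    """
    window = np.ones(2 * half_width + 1)
    out = {
        chrom: np.convolve(vec, window, mode="same")
        for chrom, vec in d.data.items()
    }
    return Profile(out)


def occupancy_from_fragments(
    frags: Iterable[FragmentRecord],
    genome: Sequence[ChromosomeSpec],
    size_window: tuple[int, int] = OCC_SIZE_WINDOW,
) -> OccupancyProfile:
    """Coverage occupancy: each retained fragment adds +1 to every bp it covers."""
    prof = Profile.zeros(genome)
    for f in _filter_by_length(frags, size_window):
        vec = prof.data.get(f.chrom)
        if vec is None:
            continue
        vec[f.start - 1 : f.end] += 1
    return prof


def fragment_dataframe(frags: Sequence[FragmentRecord]) -> pd.DataFrame:
    """Vectorized view of a fragment list (chrom, start, end, length, midpoint)."""
    df = pd.DataFrame(
        [(f.chrom, f.start, f.end) for f in frags],
        columns=["chrom", "start", "end"],
    )
    if len(df):
        df["length"] = df.end - df.start + 1
        df["midpoint"] = (df.start + df.end) // 2
    else:
        df["length"] = df["midpoint"] = pd.Series(dtype=int)
    return df
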