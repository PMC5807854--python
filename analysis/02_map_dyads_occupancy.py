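#!/usr/bin/env python
"""Map fragments to nucleosome dyads and occupancy tracks.

Dyads are the centers of 44-58 bp core fragments; occupancy extends each
dyad symmetrically by 50 bp (101-bp footprint). Both tracks are normalized
so the per-chromosome mean is 1 and written as bedGraph under results/.
"""

from pathlib import Path

import numpy as np

from cleavemap import genome_io
from cleavemap.pipeline import read_chrom_sizes

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    genome = read_chrom_sizes(IN / "chrom.sizes")
    frags = genome_io.read_fragments(IN / "fragments.bed", genome)
    dyads = genome_io.dyads_from_fragments(frags, genome)
    occ = genome_io.normalize_profile(genome_io.occupancy_from_dyads(dyads))
    genome_io.write_track(dyads, OUT / "dyads.bedgraph")
    genome_io.write_track(occ, OUT / "occupancy.bedgraph")

    lengths = np.array([f.length for f in frags])
    n_core = int(((lengths >= 44) & (lengths <= 58)).sum())
    print(f"{len(frags)} fragments; {n_core} core-sized -> dyads "
          f"({100 * n_core / len(frags):.1f}%)")
    print(f"dyad counts total {int(dyads.total())}; tracks in {OUT}/")


if __name__ == "__main__":
    main()
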