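import numpy as np
import pytest

from cleavemap import genome_io
from cleavemap.synthetic import cleave, default_world, generate_chromatin


@pytest.fixture(scope="session")
def default_world_run():
    """One full-scale default synthetic run (>1e5 fragments), shared across
    tests that only read from it."""
    cfg = default_world(1)
    cells = generate_chromatin(cfg)
    frags = cleave(cells, cfg)
    return cfg, cells, frags


@pytest.fixture(scope="session")
def small_world_run():
    """A light synthetic run for tests that need structure, not depth."""
    cfg = default_world(7, n_genes=30, n_cells=25)
    cells = generate_chromatin(cfg)
    frags = cleave(cells, cfg)
    return cfg, cells, frags


@pytest.fixture()
def one_chrom():
    return [genome_io.ChromosomeSpec("chrI", 10_000)]
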