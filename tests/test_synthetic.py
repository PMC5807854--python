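import numpy as np
import pytest

from cleavemap.genome_io import ChromosomeSpec, GeneAnnotation
from cleavemap.synthetic import (
    CellConfiguration,
    SyntheticConfig,
    cleave,
    consensus_configuration,
    default_world,
    gene_geometry,
    generate_chromatin,
    generate_sequence,
)


def spacings(cells):
    out = []
    for cell in cells:
        for arr in cell.dyads.values():
            out.extend(np.diff(arr))
    return np.asarray(out)


def one_nucleosome_config(**overrides) -> SyntheticConfig:
    kw = dict(
        seed=0,
        genome=[ChromosomeSpec("chrI", 2000)],
        genes=[GeneAnnotation("g1", "chrI", "+", 940, 1500)],
        n_cells=1,
        cut_probability=1.0,
        background_rate=0.0,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


class TestGenerateChromatin:
    def test_degenerate_linker_forces_constant_spacing(self):
        # single gene on a long chromosome: no array junctions, so every
        # spacing is either 152 or the NDR gap (147 + width >= 227)
        cfg = default_world(0, n_genes=1, gene_spacing=100_000, n_cells=5,
                            linker_lengths=(5,), linker_weights=(1.0,))
        sp = spacings(generate_chromatin(cfg))
        assert np.all((sp == 152) | (sp >= 227))

    def test_default_mixture_spacing_histogram(self):
        cfg = default_world(0, n_genes=1, gene_spacing=300_000, n_cells=8)
        sp = spacings(generate_chromatin(cfg))
        sp = sp[sp < 227]  # exclude the NDR gap (147 + width)
        assert len(sp) >= 10_000
        values, counts = np.unique(sp, return_counts=True)
        assert set(values) == {152, 162, 172}
        # equal-weight mixture: each class within 3 sigma binomial error
        n = len(sp)
        for cnt in counts:
            assert abs(cnt - n / 3) < 3 * np.sqrt(n * (1 / 3) * (2 / 3))

    def test_seed_reproducibility(self):
        cfg = default_world(9, n_genes=5, n_cells=3)
        a = generate_chromatin(cfg)
        b = generate_chromatin(cfg)
        for ca, cb in zip(a, b):
            for chrom in ca.dyads:
                assert np.array_equal(ca.dyads[chrom], cb.dyads[chrom])

    def test_hard_core_and_ndr_invariants(self):
        cfg = default_world(4, n_genes=10, n_cells=5)
        geoms = {g.gene_id: g for g in gene_geometry(cfg)}
        for cell in generate_chromatin(cfg):
            for arr in cell.dyads.values():
                assert np.all(np.diff(arr) >= cfg.nucleosome_length)
                for gm in geoms.values():
                    lo, hi = sorted((gm.minus_one, gm.plus_one))
                    inside = (arr > lo) & (arr < hi)
                    assert not inside.any(), "dyad inside an NDR"

    def test_too_dense_genes_error(self):
        # three promoters 100 bp apart: the middle gene's territory cannot
        # host a single nucleosome
        genome = [ChromosomeSpec("chrI", 3000)]
        genes = [
            GeneAnnotation("a", "chrI", "+", 900, 2500),
            GeneAnnotation("b", "chrI", "+", 1000, 2600),
            GeneAnnotation("c", "chrI", "+", 1100, 2700),
        ]
        cfg = SyntheticConfig(seed=0, genome=genome, genes=genes, n_cells=1)
        with pytest.raises(ValueError, match="territory"):
            generate_chromatin(cfg)


class TestCleave:
    def test_both_sites_cut_release_51bp_core(self):
        cfg = one_nucleosome_config()
        cell = CellConfiguration({"chrI": np.array([1000])})
        frags = cleave([cell], cfg)
        assert len(frags) == 1
        f = frags[0]
        assert f.length == 51 and f.midpoint == 1000
        assert (f.start, f.end) == (975, 1025)

    def test_neighbor_cut_classes(self):
        # two nucleosomes spaced NRL = 161 apart, all four sites cut:
        # two 51-bp cores and one medium fragment of NRL - 59 = 102
        cfg = one_nucleosome_config()
        cell = CellConfiguration({"chrI": np.array([800, 961])})
        lengths = sorted(f.length for f in cleave([cell], cfg))
        assert lengths == [51, 51, 102]

    def test_skipped_site_gives_long_fragment(self):
        # with the right site of nucleosome 1 uncut, the fragment runs from
        # the left cut of nucleosome 1 to the left cut of nucleosome 2:
        # [d1 - 25, d2 - 30], i.e. NRL - gap = 157 for NRL 161; realize it
        # by sampling until the cut pattern occurs
        cfg = one_nucleosome_config(cut_probability=0.5)
        cell = CellConfiguration({"chrI": np.array([800, 961])})
        seen = set()
        for seed in range(40):
            cfg2 = one_nucleosome_config(cut_probability=0.5, seed=seed)
            seen.update(f.length for f in cleave([cell], cfg2))
        assert 157 in seen  # long class, NRL - 4
        assert seen <= {51, 102, 157, 161 + 51}

    def test_p1_length_multiset_is_cores_plus_mediums(self):
        cfg = default_world(5, n_genes=10, n_cells=4,
                            cut_probability=1.0, background_rate=0.0)
        cells = generate_chromatin(cfg)
        frags = cleave(cells, cfg)
        lengths = np.array([f.length for f in frags])
        sp = spacings(cells)
        n_nucs = sum(len(a) for c in cells for a in c.dyads.values())
        # every nucleosome releases its 51-bp core
        assert (lengths == 51).sum() == n_nucs
        # every adjacent pair releases a medium fragment of spacing - 59
        others = np.sort(lengths[lengths != 51])
        assert np.array_equal(others, np.sort(sp - 59))

    def test_long_class_matches_spacing_distribution(self):
        # single gene avoids array-junction spacings; NDR widths >= 90 keep
        # the NDR-crossing fragments (147 + w - 59 bp) out of the long class
        cfg = default_world(6, n_genes=1, gene_spacing=200_000, n_cells=25,
                            background_rate=0.0, ndr_width_range=(90, 160))
        cells = generate_chromatin(cfg)
        frags = cleave(cells, cfg)
        lengths = np.array([f.length for f in frags])
        long_counts = np.array(
            [(lengths == s).sum() for s in (148, 158, 168)], dtype=float
        )
        sp = spacings(cells)
        sp_counts = np.array([(sp == s).sum() for s in (152, 162, 172)], dtype=float)
        # each spacing yields a long (skip-one) fragment with the same
        # probability, so the class proportions must agree
        p_hat = long_counts / long_counts.sum()
        p_true = sp_counts / sp_counts.sum()
        n = long_counts.sum()
        for ph, pt in zip(p_hat, p_true):
            assert abs(ph - pt) < 3 * np.sqrt(pt * (1 - pt) / n)

    def test_cores_never_overlap_lost_gaps(self):
        cfg = one_nucleosome_config()
        cell = CellConfiguration({"chrI": np.array([600, 761, 922])})
        for f in cleave([cell], cfg):
            if f.length != 51:
                continue
            d = f.midpoint
            for gap_lo, gap_hi in ((d - 29, d - 26), (d + 26, d + 29)):
                assert f.end < gap_lo or f.start > gap_hi

    def test_background_fraction(self):
        cfg = default_world(8, n_genes=10, n_cells=10, background_rate=0.2)
        frags = cleave(generate_chromatin(cfg), cfg)
        cfg0 = default_world(8, n_genes=10, n_cells=10, background_rate=0.0)
        n_real = len(cleave(generate_chromatin(cfg0), cfg0))
        assert len(frags) - n_real == pytest.approx(0.25 * n_real, rel=0.02)


class TestGenerateSequence:
    def test_reproducible_and_uniform_without_oscillation(self):
        cfg = default_world(3, n_genes=5, n_cells=1)
        a = generate_sequence(cfg)
        b = generate_sequence(cfg)
        assert a == b
        seq = a["chrS"]
        at = sum(seq.count(b_) for b_ in "AT") / len(seq)
        assert at == pytest.approx(0.5, abs=0.01)

    def test_oscillation_amplitude_shapes_composition_under_dyads(self):
        cfg = default_world(3, n_genes=20, n_cells=1,
                            gc_oscillation=True, ww_amplitude=0.3)
        seq = generate_sequence(cfg)["chrS"]
        cons = consensus_configuration(cfg).dyads["chrS"]
        # A/T frequency at the dyad itself should be near 0.5 + amplitude
        at_dyad = np.mean([seq[d - 1] in "AT" for d in cons])
        assert at_dyad == pytest.approx(0.8, abs=0.1)
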