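import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavemap import genome_io
from cleavemap.genome_io import (
    ChromosomeSpec,
    FragmentRecord,
    Profile,
    dyads_from_fragments,
    normalize_profile,
    occupancy_from_dyads,
    occupancy_from_fragments,
    read_fragments,
    read_track,
    write_fragments,
    write_track,
)


class TestReadFragments:
    def test_bed_is_converted_to_one_based_inclusive(self, tmp_path, one_chrom):
        p = tmp_path / "f.bed"
        p.write_text("chrI\t99\t150\n")
        (f,) = read_fragments(p, one_chrom)
        assert (f.start, f.end, f.length) == (100, 150, 51)

    def test_zero_length_bed_interval_is_an_error(self, tmp_path, one_chrom):
        p = tmp_path / "f.bed"
        p.write_text("chrI\t100\t100\n")
        with pytest.raises(ValueError, match="1"):
            read_fragments(p, one_chrom)

    def test_tsv_dialect_is_taken_verbatim(self, tmp_path, one_chrom):
        p = tmp_path / "f.tsv"
        p.write_text("chrI\t100\t150\n")
        (f,) = read_fragments(p, one_chrom, dialect="tsv")
        assert (f.start, f.end) == (100, 150)

    def test_malformed_line_error_names_line_number(self, tmp_path, one_chrom):
        p = tmp_path / "f.bed"
        p.write_text("chrI\t0\t50\nchrI\tx\ty\n")
        with pytest.raises(ValueError, match=":2"):
            read_fragments(p, one_chrom)

    def test_unknown_chromosomes_dropped_with_count(self, tmp_path, one_chrom, caplog):
        p = tmp_path / "f.bed"
        p.write_text("chrI\t0\t50\nchrZ\t0\t50\n")
        with caplog.at_level("WARNING"):
            frags = read_fragments(p, one_chrom)
        assert len(frags) == 1
        assert "1" in caplog.text

    @settings(deadline=None, max_examples=25)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(1, 900), st.integers(1, 100)),
            min_size=1,
            max_size=30,
        ),
        dialect=st.sampled_from(["bed", "tsv"]),
    )
    def test_roundtrip_across_dialects(self, tmp_path_factory, intervals, dialect):
        frags = [FragmentRecord("chrI", s, s + l - 1) for s, l in intervals]
        p = tmp_path_factory.mktemp("rt") / "f.txt"
        write_fragments(frags, p, dialect=dialect)
        back = read_fragments(p, [ChromosomeSpec("chrI", 2000)], dialect=dialect)
        assert back == frags


class TestDyads:
    def test_odd_length_midpoint(self, one_chrom):
        prof = dyads_from_fragments([FragmentRecord("chrI", 100, 150)], one_chrom)
        assert prof["chrI"][125 - 1] == 1

    def test_even_length_midpoint_rounds_down(self, one_chrom):
        # 44-bp fragment: arithmetic midpoint 121.5 floors to 121
        prof = dyads_from_fragments([FragmentRecord("chrI", 100, 143)], one_chrom)
        assert prof["chrI"][121 - 1] == 1

    def test_fragments_outside_size_window_are_dropped(self, one_chrom):
        prof = dyads_from_fragments([FragmentRecord("chrI", 100, 159)], one_chrom)
        assert prof.total() == 0

    def test_empty_retained_set_warns(self, one_chrom):
        with pytest.warns(UserWarning):
            prof = dyads_from_fragments([FragmentRecord("chrI", 1, 10)], one_chrom)
        assert prof.total() == 0

    def test_count_conservation(self, one_chrom):
        rng = np.random.default_rng(0)
        frags = [
            FragmentRecord("chrI", int(s), int(s) + int(l) - 1)
            for s, l in zip(rng.integers(100, 9000, 500), rng.integers(30, 80, 500))
        ]
        retained = sum(1 for f in frags if 44 <= f.length <= 58)
        prof = dyads_from_fragments(frags, one_chrom)
        assert prof.total() == retained


class TestNormalize:
    def test_constant_vector_becomes_ones(self):
        p = Profile({"c": np.array([2.0, 2, 2, 2])})
        assert np.allclose(normalize_profile(p)["c"], 1.0)

    def test_mean_one_vector_unchanged(self):
        p = Profile({"c": np.array([4.0, 0, 0, 0])})
        assert np.allclose(normalize_profile(p)["c"], [4, 0, 0, 0])

    def test_general_case(self):
        p = Profile({"c": np.array([3.0, 1.0])})
        assert np.allclose(normalize_profile(p)["c"], [1.5, 0.5])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        p = Profile({"c": rng.random(100) + 0.1})
        once = normalize_profile(p)
        twice = normalize_profile(once)
        assert np.allclose(once["c"], twice["c"])
        assert twice.normalized

    def test_all_zero_chromosome_errors_with_name(self):
        p = Profile({"chrZ": np.zeros(5)})
        with pytest.raises(ValueError, match="chrZ"):
            normalize_profile(p)


class TestOccupancy:
    def test_single_dyad_gives_101_bp_footprint(self, one_chrom):
        d = Profile.zeros(one_chrom)
        d["chrI"][500 - 1] = 1
        occ = occupancy_from_dyads(d)
        nz = np.nonzero(occ["chrI"])[0] + 1
        assert nz[0] == 450 and nz[-1] == 550 and len(nz) == 101

    def test_edge_clipping(self):
        d = Profile.zeros([ChromosomeSpec("chrI", 1000)])
        d["chrI"][10 - 1] = 1
        occ = occupancy_from_dyads(d)
        nz = np.nonzero(occ["chrI"])[0] + 1
        assert nz[0] == 1 and nz[-1] == 60

    def test_overlapping_footprints_add(self, one_chrom):
        d = Profile.zeros(one_chrom)
        d["chrI"][500 - 1] = 1
        d["chrI"][510 - 1] = 1
        occ = occupancy_from_dyads(d)
        assert occ["chrI"][505 - 1] == 2

    def test_mass_identity_away_from_edges(self, one_chrom):
        rng = np.random.default_rng(2)
        d = Profile.zeros(one_chrom)
        for pos in rng.integers(200, 9800, 50):
            d["chrI"][pos - 1] += 1
        occ = occupancy_from_dyads(d)
        assert occ["chrI"].sum() == pytest.approx(101 * d["chrI"].sum())

    def test_fragment_coverage(self, one_chrom):
        frags = [
            FragmentRecord("chrI", 100, 150),  # covered
            FragmentRecord("chrI", 200, 239),  # 40 bp, below window
            FragmentRecord("chrI", 120, 170),  # overlaps the first
        ]
        occ = occupancy_from_fragments(frags, one_chrom)
        v = occ["chrI"]
        assert v[99] == 1 and v[130] == 2 and v[210] == 0
        assert v.sum() == 51 + 51


class TestTracks:
    @pytest.mark.parametrize("fmt", ["bedgraph", "wiggle"])
    def test_roundtrip_integer_counts(self, tmp_path, one_chrom, fmt):
        rng = np.random.default_rng(3)
        p = Profile.zeros(one_chrom)
        p["chrI"][rng.integers(0, 10_000, 200)] = rng.integers(1, 9, 200)
        path = tmp_path / f"t.{fmt}"
        write_track(p, path, fmt=fmt)
        back = read_track(path, one_chrom, fmt=fmt)
        assert np.array_equal(p["chrI"], back["chrI"])

    def test_roundtrip_preserves_occupancy_profile(self, tmp_path, one_chrom):
        d = Profile.zeros(one_chrom)
        d["chrI"][499] = 3
        occ = occupancy_from_dyads(d)
        path = tmp_path / "occ.bedgraph"
        write_track(occ, path)
        back = read_track(path, one_chrom)
        assert np.array_equal(occ["chrI"], back["chrI"])
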