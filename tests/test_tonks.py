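import numpy as np
import pytest

from cleavemap.genome_io import ChromosomeSpec, Profile
from cleavemap.promoter import NDRCall
from cleavemap.tonks import (
    BarrierParams,
    LatticeModel,
    YEAST_BARRIER,
    brute_force_oracle,
    build_barrier,
    fit_barrier,
    heatmap_correlation,
    partition_function,
    predict_genome,
)


def uniform_model(L, a, u_minus_mu=0.0):
    return LatticeModel(L, np.full(L, float(u_minus_mu)), a=a)


class TestPartitionFunction:
    def test_counting_identity_L10_a3(self):
        # with all weights 1, Z counts the non-overlapping configurations
        out = partition_function(uniform_model(10, 3))
        assert np.exp(out.log_z) == pytest.approx(28.0, rel=1e-12)

    def test_smallest_lattice_exact_values(self):
        out = partition_function(uniform_model(3, 3))
        assert np.exp(out.log_z) == pytest.approx(2.0, rel=1e-12)
        assert out.n[1] == pytest.approx(0.5)
        assert np.allclose(out.occ, 0.5)

    def test_single_site_closed_form(self):
        # L = a: exactly one dyad position, Z = 1 + exp(mu - u)
        for umu in (-2.0, 0.0, 1.5):
            out = partition_function(uniform_model(147, 147, umu))
            assert np.exp(out.log_z) == pytest.approx(1 + np.exp(-umu), rel=1e-12)

    def test_uniform_landscape_is_mirror_symmetric(self):
        out = partition_function(uniform_model(1000, 147, -2.0))
        assert np.allclose(out.n, out.n[::-1], atol=1e-12)
        assert np.all((out.occ >= 0) & (out.occ <= 1 + 1e-12))

    def test_occupancy_is_dyad_sum(self):
        out = partition_function(uniform_model(2000, 147, -1.0))
        direct = np.convolve(out.n, np.ones(147), mode="same")
        assert np.allclose(out.occ, np.clip(direct, 0, 1))

    def test_dilute_limit_is_noninteracting(self):
        # for u - mu >> 0, n(k) -> exp(mu - u) to first order
        out = partition_function(uniform_model(2000, 147, 12.0))
        lo, hi = 74, 2000 - 73
        interior = out.n[lo - 1 : hi]
        assert np.allclose(interior, np.exp(-12.0), rtol=1e-3)

    def test_lattice_shorter_than_rod_rejected(self):
        with pytest.raises(ValueError):
            partition_function(uniform_model(100, 147))


class TestOracleEquivalence:
    def test_random_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = int(rng.choice([3, 5, 7]))
            L = int(rng.integers(a, 31))
            u = rng.normal(0.0, 1.5, size=L)
            model = LatticeModel(L, u, a=a)
            fast = partition_function(model)
            slow = brute_force_oracle(model)
            assert np.exp(fast.log_z) == pytest.approx(
                np.exp(slow.log_z), rel=1e-10
            )
            assert np.allclose(fast.n, slow.n, rtol=1e-10, atol=1e-12)
            assert np.allclose(fast.occ, slow.occ, rtol=1e-10, atol=1e-12)

    def test_oracle_refuses_large_lattices(self):
        with pytest.raises(ValueError):
            brute_force_oracle(uniform_model(31, 3))


def one_promoter_calls(p1=1500, w=120):
    m1 = p1 - 147 - w
    return [NDRCall("g", "chrT", "+", (p1 + m1) // 2, w, w, m1, p1)]


class TestBarrier:
    def test_barrier_values_at_landmarks(self):
        params = BarrierParams(H=5.0, sigma=20.0, x0=60.0, u_minus_mu=-2.0)
        calls = one_promoter_calls()
        u = build_barrier(calls, params, 3000)
        p_l, p_r = calls[0].minus_one, calls[0].plus_one
        c_l, c_r = p_l + 60, p_r - 60
        assert u[int(c_l) - 1] == pytest.approx(-2.0 + 5.0)
        # one sigma outside the left center: H * exp(-1/2)
        assert u[int(c_l - 20) - 1] == pytest.approx(-2.0 + 5.0 * np.exp(-0.5), rel=1e-6)
        # flat top between the centers
        mid = (int(c_l) + int(c_r)) // 2
        assert u[mid - 1] == pytest.approx(3.0)
        # far away: baseline
        assert u[10] == pytest.approx(-2.0, abs=1e-6)

    def test_narrow_ndr_degrades_to_max_of_shoulders(self):
        params = BarrierParams(H=5.0, sigma=20.0, x0=200.0, u_minus_mu=0.0)
        calls = one_promoter_calls(w=100)  # centers cross
        u = build_barrier(calls, params, 3000)
        # each shoulder still tops out at H at its own center, but there is
        # no flat top: between the crossed centers the barrier dips
        assert u.max() == pytest.approx(5.0)
        p_l, p_r = calls[0].minus_one, calls[0].plus_one
        mid = (p_l + p_r) // 2
        assert u[mid - 1] < 0.9 * 5.0

    def test_raising_H_never_raises_occupancy_at_barrier_center(self):
        calls = one_promoter_calls()
        center = calls[0].center
        occs = []
        for H in (2.0, 5.0, 8.0):
            params = BarrierParams(H, 25.0, 60.0, -2.79)
            out = predict_genome(calls, params, [ChromosomeSpec("chrT", 3000)])
            occs.append(out["chrT"].occ[center - 1])
        assert occs[0] >= occs[1] >= occs[2]

    def test_statistical_positioning_oscillations_decay_from_barrier(self):
        calls = one_promoter_calls(p1=3000, w=120)
        out = predict_genome(
            calls, YEAST_BARRIER, [ChromosomeSpec("chrT", 8000)]
        )["chrT"]
        n = out.n
        # peaks downstream of the +1 dyad decay in amplitude
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(n[3000:6000], height=n.max() * 0.01)
        heights = n[3000:6000][peaks][:5]
        assert len(heights) >= 4
        assert np.all(np.diff(heights) < 0)
        # nucleosomes pack against the barrier roughly every rod length
        assert 147 <= np.mean(np.diff(peaks[:5])) <= 185

    def test_interference_between_barrier_pairs(self):
        # two promoters an integer number of repeat lengths apart phase
        # constructively; a half-integer offset interferes destructively
        def mid_amplitude(separation):
            p1a = 3000
            p1b = p1a + separation
            calls = [
                one_promoter_calls(p1=p1a, w=120)[0],
                NDRCall("g2", "chrT", "+", 0, 120, 120, p1b, p1b + 147 + 120),
            ]
            out = predict_genome(
                calls, YEAST_BARRIER, [ChromosomeSpec("chrT", p1b + 4000)]
            )["chrT"]
            seg = out.n[p1a + 300 : p1b - 300]
            return seg.max() - seg.min()

        nrl = 165
        assert mid_amplitude(8 * nrl) > mid_amplitude(8 * nrl + nrl // 2)


class TestFit:
    def test_objective_is_one_for_identical_profiles(self):
        calls = one_promoter_calls()
        out = predict_genome(calls, YEAST_BARRIER, [ChromosomeSpec("chrT", 3000)])
        prof = Profile({"chrT": out["chrT"].n})
        assert heatmap_correlation(prof, prof, calls, window=(-300, 800)) == pytest.approx(1.0)

    def test_degenerate_observed_heatmap_errors(self):
        calls = one_promoter_calls()
        flat = Profile({"chrT": np.ones(3000)})
        with pytest.raises(ValueError, match="variance"):
            fit_barrier(flat, calls, ChromosomeSpec("chrT", 3000), seed=0)

    def test_truth_is_a_local_optimum_of_the_objective(self):
        # objective at the generating parameters beats nearby perturbations
        rng = np.random.default_rng(5)
        calls = []
        for i in range(20):
            p1 = 2000 + i * 2000
            w = int(rng.integers(80, 161))
            calls.append(NDRCall(f"g{i}", "chrT", "+", 0, w, w, p1 - 147 - w, p1))
        chrom = ChromosomeSpec("chrT", 42_000)
        truth = YEAST_BARRIER
        out = predict_genome(calls, truth, [chrom])
        obs = Profile({"chrT": out["chrT"].n})

        def score(params):
            pred = predict_genome(calls, params, [chrom])
            return heatmap_correlation(
                obs, Profile({"chrT": pred["chrT"].n}), calls
            )

        best = score(truth)
        assert best == pytest.approx(1.0)
        for dH, ds, dx, du in ((1.5, 0, 0, 0), (0, 8, 0, 0),
                               (0, 0, 15, 0), (0, 0, 0, 0.8)):
            perturbed = BarrierParams(
                truth.H + dH, truth.sigma + ds, truth.x0 + dx,
                truth.u_minus_mu + du,
            )
            assert score(perturbed) < best
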