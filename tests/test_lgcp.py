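import numpy as np
import pytest

from coxmix.errors import ConvergenceError
from coxmix.lgcp import (
    EvidenceCache,
    GridSpec,
    PriorSpec,
    bin_events,
    build_prior_precision,
    cluster_log_marginal,
    estimate_intensity,
    laplace_fit,
)
from coxmix.simulate import BumpIntensity, GaussianBump, sample_ipp
from oracles import gh_log_marginal


class TestGridSpec:
    def test_delta_times_B_equals_L(self):
        g = GridSpec(B=7, L=50.0)
        assert g.delta * g.B == pytest.approx(50.0)
        assert len(g.midpoints) == 7

    def test_rejects_small_B(self):
        with pytest.raises(ValueError):
            GridSpec(B=3)


class TestBinEvents:
    def test_simple_counts(self, pattern_factory):
        g = GridSpec(B=5, L=50.0)
        counts, exposure = bin_events(pattern_factory([5.0, 25.0, 45.0]), g)
        assert counts.tolist() == [1, 0, 1, 0, 1]
        assert exposure.tolist() == [10.0] * 5

    def test_event_at_L_in_last_bin(self, pattern_factory):
        g = GridSpec(B=5, L=50.0)
        counts, _ = bin_events(pattern_factory([50.0]), g)
        assert counts.tolist() == [0, 0, 0, 0, 1]

    def test_pooling(self, pattern_factory):
        g = GridSpec(B=10, L=50.0)
        rng = np.random.default_rng(0)
        p1 = pattern_factory(np.sort(rng.uniform(0, 50, 10)))
        p2 = pattern_factory(np.sort(rng.uniform(0, 50, 10)))
        counts, exposure = bin_events([p1, p2], g)
        assert counts.sum() == 20
        assert np.allclose(exposure, 2 * g.delta)

    def test_out_of_range_rejected(self):
        g = GridSpec(B=5, L=50.0)
        from coxmix.projection import PointPattern

        pat = PointPattern("P", "s", np.array([80.0]), L=100.0)
        with pytest.raises(ValueError, match="outside"):
            bin_events(pat, g)

    def test_count_conservation_under_refinement(self, pattern_factory):
        rng = np.random.default_rng(1)
        pat = pattern_factory(np.sort(rng.uniform(0, 50, 137)))
        totals = {
            B: bin_events(pat, GridSpec(B=B, L=50.0))[0].sum() for B in (5, 50, 400)
        }
        assert set(totals.values()) == {137}


class TestPriorPrecision:
    def test_definition(self):
        theta = PriorSpec(kappa=1.0, ridge=1e-8)
        Q = build_prior_precision(theta, 5)
        d2 = np.array(
            [[1, -2, 1, 0, 0], [0, 1, -2, 1, 0], [0, 0, 1, -2, 1]], dtype=float
        )
        assert np.allclose(Q, d2.T @ d2 + 1e-8 * np.eye(5))

    def test_kappa_linearity(self):
        t1 = PriorSpec(kappa=1.0, ridge=1e-8)
        t2 = PriorSpec(kappa=2.0, ridge=1e-8)
        q1 = build_prior_precision(t1, 6) - 1e-8 * np.eye(6)
        q2 = build_prior_precision(t2, 6) - 1e-8 * np.eye(6)
        assert np.allclose(q2, 2 * q1)

    @pytest.mark.parametrize("B", [4, 50, 400])
    def test_spd(self, B):
        Q = build_prior_precision(PriorSpec(), B)
        assert np.all(np.linalg.eigvalsh(Q) > 0)

    def test_kappa_must_be_positive(self):
        with pytest.raises(ValueError):
            PriorSpec(kappa=0.0)


class TestLaplaceFit:
    def test_no_data_limit(self):
        # with a hugely negative mean level the likelihood term vanishes and
        # the marginal of all-zero counts is the Gaussian prior integral = 1
        B = 8
        g = GridSpec(B=B, L=50.0)
        Q = build_prior_precision(PriorSpec(), B)
        fit = laplace_fit(np.zeros(B), np.full(B, g.delta), Q, mean0=-40.0)
        assert np.max(np.abs(fit.mode)) < 1e-6
        assert abs(fit.log_marginal) < 1e-6

    def test_mode_is_stationary(self):
        rng = np.random.default_rng(3)
        B = 20
        g = GridSpec(B=B, L=50.0)
        counts = rng.poisson(5.0, size=B)
        Q = build_prior_precision(PriorSpec(), B)
        fit = laplace_fit(counts, np.full(B, g.delta), Q, mean0=0.0)
        assert fit.grad_norm < 1e-8

    def test_homogeneous_recovery(self):
        # 200 uniform events on [0,50]: true intensity 4 events/unit
        g = GridSpec(B=50, L=50.0)
        theta = PriorSpec()
        curves = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            from conftest import make_pattern

            pat = make_pattern(np.sort(rng.uniform(0, 50, 200)))
            curves.append(estimate_intensity(pat, g, theta))
        mean_curve = np.mean(curves, axis=0)
        interior = mean_curve[2:-2]
        assert np.all(np.abs(interior - 4.0) <= 1.0)

    def test_quadrature_oracle_toy(self):
        # B=5 toy: Laplace within 0.05 nats of tensor Gauss-Hermite quadrature
        rng = np.random.default_rng(7)
        B = 5
        g = GridSpec(B=B, L=50.0)
        Q = build_prior_precision(PriorSpec(), B)
        counts = rng.poisson(2.0 * g.delta, size=B)
        exposure = np.full(B, g.delta)
        mean0 = np.log(counts.sum() / exposure.sum())
        fit = laplace_fit(counts, exposure, Q, mean0)
        oracle = gh_log_marginal(counts, exposure, Q, mean0)
        assert abs(fit.log_marginal - oracle) <= 0.05

    def test_nonconvergence_carries_grad_norm(self):
        B = 6
        g = GridSpec(B=B, L=50.0)
        Q = build_prior_precision(PriorSpec(), B)
        with pytest.raises(ConvergenceError) as exc:
            laplace_fit(
                np.full(B, 50.0), np.full(B, g.delta), Q, mean0=0.0, max_iter=1
            )
        assert exc.value.grad_norm > 0


class TestEstimateIntensity:
    def test_triangle_peak_location(self, pattern_factory):
        tri = BumpIntensity([GaussianBump(center=20.0, width=4.0, height=8.0)])
        rng = np.random.default_rng(11)
        ev = sample_ipp(tri, L=50.0, rng=rng)
        g = GridSpec(B=100, L=50.0)
        curve = estimate_intensity(pattern_factory(ev), g, PriorSpec())
        assert abs(g.midpoints[np.argmax(curve)] - 20.0) <= 5.0  # 10% of L

    def test_pooling_scaling_consistency(self, pattern_factory):
        rng = np.random.default_rng(2)
        bump = BumpIntensity([GaussianBump(25.0, 4.0, 12.0)])
        ev = sample_ipp(bump, L=50.0, rng=rng)
        g = GridSpec(B=50, L=50.0)
        one = estimate_intensity(pattern_factory(ev), g, PriorSpec())
        two = estimate_intensity(
            [pattern_factory(ev), pattern_factory(ev)], g, PriorSpec()
        )
        # doubled counts against a fixed prior smooth slightly less, so the
        # curves agree in shape rather than bit-for-bit
        assert np.corrcoef(one, two)[0, 1] > 0.99
        assert np.allclose(one, two, rtol=0.15, atol=0.02 * one.max())

    def test_empty_pattern_flat_near_zero(self, pattern_factory):
        g = GridSpec(B=20, L=50.0)
        curve = estimate_intensity(pattern_factory([]), g, PriorSpec())
        assert np.all(curve < 0.05)
        assert np.ptp(curve) < 1e-6

    def test_monotone_data_support(self, pattern_factory):
        rng = np.random.default_rng(5)
        ev = np.sort(rng.uniform(0, 50, 80))
        g = GridSpec(B=25, L=50.0)
        curve = estimate_intensity(pattern_factory(ev), g, PriorSpec())
        b = int(np.argmax(curve))
        extra = np.sort(np.append(ev, [g.midpoints[b]] * 5))
        curve2 = estimate_intensity(pattern_factory(extra), g, PriorSpec())
        assert curve2[b] >= curve[b] - 1e-9


class TestClusterLogMarginal:
    def test_single_member_equals_laplace_fit(self, pattern_factory):
        rng = np.random.default_rng(9)
        pat = pattern_factory(np.sort(rng.uniform(0, 50, 60)))
        g = GridSpec(B=30, L=50.0)
        theta = PriorSpec()
        counts, exposure = bin_events(pat, g)
        Q = build_prior_precision(theta, g.B)
        mean0 = np.log(counts.sum() / exposure.sum())
        fit = laplace_fit(counts, exposure, Q, mean0)
        assert cluster_log_marginal([pat], g, theta) == pytest.approx(
            fit.log_marginal
        )

    def test_member_order_invariance(self, pattern_factory):
        rng = np.random.default_rng(10)
        pats = [
            pattern_factory(np.sort(rng.uniform(0, 50, 40)), protein=f"P{i}")
            for i in range(3)
        ]
        g = GridSpec(B=20, L=50.0)
        a = cluster_log_marginal(pats, g)
        b = cluster_log_marginal(pats[::-1], g)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("same", [True, False])
    def test_merge_score_sign(self, pattern_factory, same):
        # Bayes factor favours merging same-intensity pairs, splitting
        # disjoint-support pairs; majority sign over 20 replicates.
        g = GridSpec(B=100, L=50.0)
        theta = PriorSpec()
        bump_a = BumpIntensity([GaussianBump(10.0, 3.0, 20.0)])
        bump_b = bump_a if same else BumpIntensity([GaussianBump(40.0, 3.0, 20.0)])
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pa = pattern_factory(sample_ipp(bump_a, 50.0, rng=rng), protein="A")
            pb = pattern_factory(sample_ipp(bump_b, 50.0, rng=rng), protein="B")
            score = (
                cluster_log_marginal([pa, pb], g, theta)
                - cluster_log_marginal([pa], g, theta)
                - cluster_log_marginal([pb], g, theta)
            )
            signs.append(score > 0)
        if same:
            assert sum(signs) >= 15
        else:
            assert sum(signs) <= 5


class TestEvidenceCache:
    def test_matches_direct_computation(self, pattern_factory):
        rng = np.random.default_rng(12)
        pats = [
            pattern_factory(np.sort(rng.uniform(0, 50, 30)), protein=f"P{i}")
            for i in range(3)
        ]
        g = GridSpec(B=20, L=50.0)
        theta = PriorSpec()
        cache = EvidenceCache(pats, g, theta)
        assert cache(frozenset({0, 2})) == pytest.approx(
            cluster_log_marginal([pats[0], pats[2]], g, theta)
        )

    def test_cached_value_stable(self, pattern_factory):
        pats = [pattern_factory([10.0, 20.0]), pattern_factory([30.0])]
        cache = EvidenceCache(pats, GridSpec(B=10, L=50.0))
        assert cache({0, 1}) == cache(frozenset({1, 0}))


def test_quadrature_property_small_grids():
    # |Laplace - numerical integral| <= 0.1 nats across random datasets, B <= 6
    rng = np.random.default_rng(2024)
    for trial in range(10):
        B = int(rng.integers(4, 6))
        g = GridSpec(B=B, L=50.0)
        Q = build_prior_precision(PriorSpec(), B)
        counts = rng.poisson(rng.uniform(0.5, 4.0) * g.delta, size=B)
        exposure = np.full(B, g.delta)
        mean0 = np.log(max(counts.sum(), 1) / exposure.sum())
        fit = laplace_fit(counts, exposure, Q, mean0)
        oracle = gh_log_marginal(counts, exposure, Q, mean0)
        assert abs(fit.log_marginal - oracle) <= 0.1
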