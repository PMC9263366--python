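import numpy as np
import pytest

import nlts
from nlts import EmbeddingSpec, delay_embed
from nlts.dynamics import DivergenceCurve


def brute_force_correlation_sum(states, epsilons, theiler):
    """Independent O(n^2) pair-count loop."""
    n = len(states)
    counts = np.zeros(len(epsilons), dtype=int)
    n_pairs = 0
    for i in range(n):
        for j in range(i + theiler + 1, n):
            d = np.max(np.abs(states[i] - states[j]))
            n_pairs += 1
            counts += d <= epsilons
    return counts / n_pairs


class TestCorrelationSum:
    @pytest.mark.parametrize("theiler", [0, 5])
    def test_matches_brute_force(self, rng, theiler):
        x = rng.standard_normal(200)
        ps = delay_embed(x, EmbeddingSpec(2, 3))
        eps = np.geomspace(0.1, 5.0, 8)
        curve = nlts.correlation_sum(ps, eps, theiler=theiler, chunk=64)
        expected = brute_force_correlation_sum(ps.states, eps, theiler)
        assert np.allclose(curve.C[2], expected)

    def test_saturates_at_one_beyond_diameter(self, rng):
        ps = delay_embed(rng.uniform(size=300), EmbeddingSpec(2, 1))
        curve = nlts.correlation_sum(ps, np.array([2 * ps.diameter()]))
        assert curve.C[2][0] == 1.0

    def test_monotone_in_epsilon(self, rng):
        ps = delay_embed(rng.standard_normal(400), EmbeddingSpec(3, 2))
        curve = nlts.correlation_sum(ps, theiler=2)
        assert np.all(np.diff(curve.C[3]) >= 0)

    def test_uniform_line_scales_linearly(self, rng):
        # points on a 1-D segment: C(eps) ~ eps, log-log slope ~ 1
        x = rng.uniform(size=800)
        ps = nlts.PhaseSpace(x[:, None], EmbeddingSpec(1, 1), 800)
        eps = np.geomspace(0.01, 0.2, 12)
        curve = nlts.correlation_sum(ps, eps)
        d2 = nlts.correlation_dimension(curve, (0.01, 0.2))
        assert d2[1] == pytest.approx(1.0, abs=0.1)

    def test_2d_noise_fills_the_plane(self, rng):
        pts = rng.uniform(size=(1500, 2))
        ps = nlts.PhaseSpace(pts, EmbeddingSpec(2, 1), 1501)
        eps = np.geomspace(0.02, 0.2, 10)
        curve = nlts.correlation_sum(ps, eps)
        d2 = nlts.correlation_dimension(curve, (0.02, 0.2))
        assert d2[2] == pytest.approx(2.0, abs=0.2)

    def test_rescaling_invariance_in_relative_units(self, rng):
        x = rng.standard_normal(300)
        for scale in (1.0, 7.5):
            ps = delay_embed(scale * x, EmbeddingSpec(2, 1))
            eps = np.array([0.1, 0.3]) * ps.diameter()
            c = nlts.correlation_sum(ps, eps).C[2]
            if scale == 1.0:
                ref = c
        assert np.allclose(c, ref)


class TestLyapunov:
    def test_synthetic_linear_curve_fit_is_exact(self):
        curve = DivergenceCurve(np.arange(11), 0.1 * np.arange(11.0), fs=10.0)
        lam = nlts.lyapunov_fit(curve, (1, 10))
        assert lam == pytest.approx(0.1)
        assert curve.lam_per_second == pytest.approx(1.0)

    def test_periodic_signal_has_zero_exponent(self):
        x = np.sin(2 * np.pi * np.arange(3000) / 50)
        ps = delay_embed(x, EmbeddingSpec(2, 12))
        c = nlts.lyapunov_curve(ps, "kantz", epsilon=0.05 * ps.diameter(),
                                iterations=10, theiler=25)
        lam = nlts.lyapunov_fit(c, (1, 10))
        assert abs(lam) < 0.005

    def test_logistic_map_recovers_ln2(self):
        # the fully chaotic logistic map (a=4) has lambda = ln 2 per iterate
        ts = nlts.generate_logistic(
            nlts.LogisticParams(a=4.0, x0=0.2345, n=10_000))
        ps = delay_embed(ts, EmbeddingSpec(1, 1))
        c = nlts.lyapunov_curve(ps, "kantz", epsilon=0.01 * ps.diameter(),
                                iterations=6, theiler=1)
        lam = nlts.lyapunov_fit(c, (0, 4))
        assert lam == pytest.approx(np.log(2), rel=0.05)

    def test_kantz_and_rosenstein_agree_on_lorenz(self, lorenz):
        ts, _ = lorenz
        ps = delay_embed(ts, EmbeddingSpec(3, 8))
        lams = {}
        for alg in ("kantz", "rosenstein"):
            c = nlts.lyapunov_curve(ps, alg, epsilon=0.005 * ps.diameter(),
                                    iterations=120, theiler=20,
                                    max_references=2000, seed=0)
            lams[alg] = nlts.lyapunov_fit(c, (24, 120))
        assert lams["kantz"] == pytest.approx(lams["rosenstein"], rel=0.10)

    def test_empty_neighborhoods_fail(self, rng):
        ps = delay_embed(rng.standard_normal(100), EmbeddingSpec(2, 1))
        with pytest.raises(ValueError):
            nlts.lyapunov_curve(ps, "kantz", epsilon=1e-12, iterations=5)


class TestUpo:
    def test_logistic_fixed_point_a2(self):
        ts = nlts.generate_logistic(nlts.LogisticParams(a=2.0, x0=0.17, n=100))
        res = nlts.upo_transform(ts, n_transforms=500, seed=0)
        assert res.mode == pytest.approx(0.5, abs=0.02)

    def test_logistic_fixed_point_a392(self):
        ts = nlts.generate_logistic(nlts.LogisticParams(a=3.92, x0=0.41, n=100))
        res = nlts.upo_transform(ts, n_transforms=500, seed=0)
        assert res.mode == pytest.approx(1 - 1 / 3.92, abs=0.02)

    def test_density_integrates_to_one(self):
        ts = nlts.generate_logistic(nlts.LogisticParams(a=3.92, x0=0.41, n=100))
        for n_tr in (1, 50):
            res = nlts.upo_transform(ts, n_transforms=n_tr, seed=1)
            width = res.bin_centers[1] - res.bin_centers[0]
            assert res.density.sum() * width == pytest.approx(1.0)

    def test_noise_not_significant(self, rng):
        x = rng.uniform(0.05, 0.95, size=100)
        _, significant = nlts.upo_significance(x, n_surrogates=100, seed=2,
                                               n_transforms=50)
        assert not significant


class TestDfa:
    def test_white_noise_exponent(self):
        x = np.random.default_rng(10).standard_normal(10_000)
        _, _, alpha = nlts.dfa(x)
        assert alpha == pytest.approx(0.5, abs=0.05)

    def test_random_walk_exponent(self):
        # scales capped at n/10 keep enough windows per scale for a stable fit
        x = np.cumsum(np.random.default_rng(11).standard_normal(10_000))
        scales = np.unique(np.geomspace(16, 1000, 12).astype(int))
        _, _, alpha = nlts.dfa(x, scales=scales)
        assert alpha == pytest.approx(1.5, abs=0.1)

    def test_constant_series_fails(self):
        with pytest.raises(ValueError):
            nlts.dfa(np.ones(1000))

    def test_oversized_scales_excluded_with_warning(self):
        x = np.random.default_rng(12).standard_normal(400)
        with pytest.warns(RuntimeWarning):
            scales, F, _ = nlts.dfa(x, scales=np.array([8, 16, 32, 64, 200]))
        assert scales.max() <= 100
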