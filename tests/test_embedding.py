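import numpy as np
import pytest

import nlts
from nlts import EmbeddingSpec, FnnParams, TimeSeries, delay_embed


def brute_force_neighbors(states, epsilon, theiler):
    """Independent O(n^2) max-norm neighbor scan."""
    n = len(states)
    out = []
    for i in range(n):
        lst = []
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            if np.max(np.abs(states[i] - states[j])) <= epsilon:
                lst.append(j)
        out.append(lst)
    return out


class TestDelayEmbed:
    def test_explicit_small_example(self):
        ps = delay_embed(np.array([1.0, 2, 3, 4, 5]), EmbeddingSpec(2, 1))
        assert np.array_equal(ps.states,
                              [[1, 2], [2, 3], [3, 4], [4, 5]])

    def test_dim_one_is_identity(self):
        x = np.arange(10.0)
        ps = delay_embed(x, EmbeddingSpec(1, 5))
        assert ps.n_states == 10
        assert np.array_equal(ps.states[:, 0], x)

    def test_state_count_formula(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        ps = delay_embed(x, EmbeddingSpec(3, 8))
        assert ps.n_states == 10_000 - 2 * 8

    def test_too_short_names_minimum_length(self):
        with pytest.raises(ValueError, match="at least 21 samples"):
            delay_embed(np.arange(20.0), EmbeddingSpec(5, 5))


class TestFindNeighbors:
    def test_collinear_points(self):
        ps = delay_embed(np.array([0.0, 1.0, 2.0]), EmbeddingSpec(1, 1))
        ns = nlts.find_neighbors(ps, "radius", 1.5)
        assert sorted(ns.neighbors[1]) == [0, 2]
        assert list(ns.neighbors[0]) == [1]
        assert list(ns.neighbors[2]) == [1]

    def test_full_theiler_exclusion_empties_all(self):
        ps = delay_embed(np.random.default_rng(1).standard_normal(30),
                         EmbeddingSpec(2, 1))
        ns = nlts.find_neighbors(ps, "radius", 10.0, theiler=ps.n_states)
        assert all(len(lst) == 0 for lst in ns.neighbors)

    @pytest.mark.parametrize("theiler", [0, 3])
    def test_matches_brute_force_scan(self, rng, theiler):
        states = rng.uniform(size=(200, 2))
        ps = nlts.PhaseSpace(states, EmbeddingSpec(2, 1), 201)
        ns = nlts.find_neighbors(ps, "radius", 0.1, theiler=theiler)
        expected = brute_force_neighbors(states, 0.1, theiler)
        for got, want in zip(ns.neighbors, expected):
            assert sorted(got.tolist()) == sorted(want)

    def test_count_mode_returns_k_nearest(self, rng):
        states = rng.uniform(size=(100, 2))
        ps = nlts.PhaseSpace(states, EmbeddingSpec(2, 1), 101)
        ns = nlts.find_neighbors(ps, "count", 5, theiler=2)
        for i, got in enumerate(ns.neighbors):
            assert len(got) == 5
            assert np.all(np.abs(got - i) > 2)


class TestAutoMutualInformation:
    def test_zero_lag_equals_marginal_entropy(self, rng):
        x = rng.standard_normal(2000)
        ami, _ = nlts.auto_mutual_information(x, 5, bins=16)
        h = nlts.entropy_binned(x, bins=16).value
        assert ami[0] == pytest.approx(h, abs=1e-12)

    def test_iid_noise_ami_at_shuffle_null_level(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(size=10_000)
        ami, _ = nlts.auto_mutual_information(x, 3)
        null = []
        for _ in range(100):
            s = rng.permutation(x)
            null.append(nlts.auto_mutual_information(s, 1)[0][1])
        assert ami[1] < np.quantile(null, 0.95)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            nlts.auto_mutual_information(np.ones(100), 5)


class TestFalseNearestNeighbors:
    def test_noiseless_sine_embeds_in_the_plane(self):
        x = np.sin(2 * np.pi * np.arange(3000) / 100)
        fracs, dim = nlts.false_nearest_neighbors(x, tau=25)
        assert dim == 2
        assert np.all(fracs[1:] < 0.01)

    def test_affine_rescaling_invariance(self, rng):
        x = np.cumsum(rng.standard_normal(600))
        f1, _ = nlts.false_nearest_neighbors(x, tau=2)
        f2, _ = nlts.false_nearest_neighbors(5.0 * x - 3.0, tau=2)
        assert np.allclose(f1, f2)

    def test_broadband_signal_declines_gradually(self, rng):
        # a stochastic signal has no sharp FNN drop to zero
        x = rng.standard_normal(3000)
        x = np.convolve(x, np.ones(5) / 5, mode="valid")
        fracs, _ = nlts.false_nearest_neighbors(
            x, tau=1, params=FnnParams(dims=tuple(range(1, 7))))
        assert np.all(fracs[:4] > 0.01)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            nlts.false_nearest_neighbors(np.ones(100), tau=1)


class TestRagwitz:
    def test_ar1_recovers_order_and_error(self):
        # x_t = 0.8 x_{t-1} + eta: one-step memory, analytic prediction
        # error SD = SD(eta) = 1
        rng = np.random.default_rng(3)
        x = np.zeros(5000)
        for i in range(1, 5000):
            x[i] = 0.8 * x[i - 1] + rng.standard_normal()
        grid, dims, taus, (d, t) = nlts.ragwitz_optimize(
            x, dims=range(1, 5), taus=(1, 2, 3), k=50)
        assert d == 1
        assert np.nanmin(grid) == pytest.approx(1.0, rel=0.02)

    def test_periodic_series_predicts_exactly(self):
        x = np.tile([0.0, 1.0], 300)
        ps = delay_embed(x, EmbeddingSpec(1, 1))
        _, rmspe, skipped = nlts.nonlinear_predict(ps, epsilon=0.1)
        assert rmspe == pytest.approx(0.0, abs=1e-12)
        assert skipped == 0

    def test_white_noise_large_epsilon_reaches_mean_predictor_limit(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        ps = delay_embed(x, EmbeddingSpec(1, 1))
        _, rmspe, _ = nlts.nonlinear_predict(ps, epsilon=100.0)
        assert rmspe == pytest.approx(np.std(x), rel=0.05)


class TestSpaceTimeSeparation:
    def test_iid_noise_curves_flat(self, rng):
        x = rng.standard_normal(3000)
        ps = delay_embed(x, EmbeddingSpec(2, 1))
        dts, curves, sug = nlts.space_time_separation(ps, max_dt=40)
        med = curves[1]
        assert np.ptp(med) < 0.1 * ps.diameter()
        assert sug <= 5

    def test_sine_curves_oscillate_with_its_period(self):
        x = np.sin(2 * np.pi * np.arange(4000) / 50)
        ps = delay_embed(x, EmbeddingSpec(2, 12))
        dts, curves, _ = nlts.space_time_separation(ps, max_dt=110)
        med = curves[1]
        # distance of phase-shifted sinusoids vanishes at full-period shifts
        assert med[49] < 0.1 * med[24]
        assert med[99] < 0.1 * med[74]


class TestOptimizeEmbedding:
    def test_sine_deterministic_route(self):
        x = np.sin(2 * np.pi * np.arange(4000) / 100)
        spec = nlts.optimize_embedding(x, "deterministic")
        assert spec.dim == 2

    def test_ar1_stochastic_route(self):
        rng = np.random.default_rng(5)
        x = np.zeros(3000)
        for i in range(1, 3000):
            x[i] = 0.8 * x[i - 1] + rng.standard_normal()
        spec = nlts.optimize_embedding(x, "stochastic", dims=range(1, 4),
                                       taus=(1, 2), k=30)
        assert spec.dim == 1
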