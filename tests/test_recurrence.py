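import numpy as np
import pytest

import nlts
from nlts import EmbeddingSpec, delay_embed


def brute_force_recurrence_times(states, epsilon, Tmin, Tmax):
    """Count vertical zero-runs between recurrence points, column by column,
    on an explicitly constructed recurrence matrix (independent oracle)."""
    n = len(states)
    M = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            M[i, j] = np.max(np.abs(states[i] - states[j])) <= epsilon
    hist = np.zeros(Tmax - Tmin + 1, dtype=int)
    for col in range(n):
        ones = [i for i in range(n) if M[i, col]]
        for a, b in zip(ones[:-1], ones[1:]):
            gap = b - a - 1
            if Tmin <= gap <= Tmax:
                hist[gap - Tmin] += 1
    return hist


class TestRecurrenceMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        ps = delay_embed(rng.standard_normal(80), EmbeddingSpec(2, 1))
        rm = nlts.recurrence_matrix(ps, "epsilon", 0.5)
        assert np.all(np.diag(rm.M))
        assert np.array_equal(rm.M, rm.M.T)

    def test_periodic_signal_diagonal_lines(self):
        x = np.sin(2 * np.pi * np.arange(600) / 100)
        ps = delay_embed(x, EmbeddingSpec(2, 25))
        rm = nlts.recurrence_matrix(ps, "epsilon", 0.05)
        # recurrences recur on diagonals spaced by the 100-sample period
        d100 = np.diagonal(rm.M, offset=100)
        d50 = np.diagonal(rm.M, offset=50)
        assert d100.mean() > 0.9
        assert d50.mean() < 0.1

    def test_rate_mode_hits_target_fill(self, rng):
        pts = rng.uniform(size=(1000, 2))
        ps = nlts.PhaseSpace(pts, EmbeddingSpec(2, 1), 1001)
        rm = nlts.recurrence_matrix(ps, "rate", 5.0)
        assert rm.recurrence_rate == pytest.approx(0.05, abs=0.005)

    def test_rate_too_small_fails(self, rng):
        ps = delay_embed(rng.standard_normal(50), EmbeddingSpec(1, 1))
        with pytest.raises(ValueError):
            nlts.recurrence_matrix(ps, "rate", 0.01)


class TestCrossJointRecurrence:
    def test_joint_with_itself_is_idempotent(self, rng):
        ps = delay_embed(rng.standard_normal(100), EmbeddingSpec(2, 1))
        jm = nlts.joint_recurrence(ps, ps, 0.5)
        am = nlts.recurrence_matrix(ps, "epsilon", 0.5)
        assert np.array_equal(jm.M, am.M)

    def test_joint_of_independent_noise_multiplies_rates(self, rng):
        a = delay_embed(rng.standard_normal(600), EmbeddingSpec(1, 1))
        b = delay_embed(rng.standard_normal(600), EmbeddingSpec(1, 1))
        ra = nlts.recurrence_matrix(a, "epsilon", 0.5).recurrence_rate
        rb = nlts.recurrence_matrix(b, "epsilon", 0.5).recurrence_rate
        rj = nlts.joint_recurrence(a, b, 0.5).recurrence_rate
        assert rj == pytest.approx(ra * rb, rel=0.1)

    def test_cross_of_identical_series_has_unit_diagonal(self, rng):
        ps = delay_embed(rng.standard_normal(100), EmbeddingSpec(2, 1))
        cm = nlts.cross_recurrence(ps, ps, 0.01)
        assert np.all(np.diag(cm.M))

    def test_cross_dimension_mismatch_fails(self, rng):
        a = delay_embed(rng.standard_normal(100), EmbeddingSpec(2, 1))
        b = delay_embed(rng.standard_normal(100), EmbeddingSpec(3, 1))
        with pytest.raises(ValueError):
            nlts.cross_recurrence(a, b, 0.5)


class TestRqaMeasures:
    def test_periodic_signal_is_deterministic(self):
        x = np.sin(2 * np.pi * np.arange(500) / 50)
        ps = delay_embed(x, EmbeddingSpec(2, 12))
        rm = nlts.recurrence_matrix(ps, "epsilon", 0.1)
        m = nlts.rqa_measures(rm)
        assert m.determinism >= 0.99
        assert m.rpde < 0.2

    def test_constant_signal_fully_laminar(self):
        ps = nlts.PhaseSpace(np.zeros((50, 1)), EmbeddingSpec(1, 1), 50)
        m = nlts.rqa_measures(nlts.recurrence_matrix(ps, "epsilon", 1.0))
        assert m.laminarity == 1.0
        assert m.recurrence_rate == 1.0

    def test_noise_less_deterministic_than_periodic(self, rng):
        xp = np.sin(2 * np.pi * np.arange(500) / 50)
        xn = rng.standard_normal(500)
        det = {}
        for name, x in (("periodic", xp), ("noise", xn)):
            ps = delay_embed(x, EmbeddingSpec(2, 12))
            rm = nlts.recurrence_matrix(ps, "rate", 5.0)
            det[name] = nlts.rqa_measures(rm).determinism
        assert det["noise"] < det["periodic"] - 0.2

    def test_measures_bounded(self, rng):
        ps = delay_embed(rng.standard_normal(300), EmbeddingSpec(2, 2))
        m = nlts.rqa_measures(nlts.recurrence_matrix(ps, "rate", 5.0))
        for v in (m.recurrence_rate, m.determinism, m.laminarity, m.rpde):
            assert 0.0 <= v <= 1.0

    def test_generalized_autocorrelation_peaks_at_period(self):
        x = np.sin(2 * np.pi * np.arange(600) / 100)
        ps = delay_embed(x, EmbeddingSpec(2, 25))
        m = nlts.rqa_measures(nlts.recurrence_matrix(ps, "epsilon", 0.05))
        g = m.generalized_autocorrelation
        assert g[100] > 0.9 and g[50] < 0.1


class TestRecurrenceTimes:
    def test_probabilities_normalize(self, rng):
        ps = delay_embed(rng.standard_normal(400), EmbeddingSpec(2, 2))
        dens = nlts.recurrence_times(ps, 0.5, Tmin=1, Tmax=100)
        if not dens.empty:
            assert dens.P.sum() == pytest.approx(1.0)
            assert np.all(dens.P >= 0)

    def test_sine_peak_at_its_period(self):
        x = np.sin(2 * np.pi * np.arange(1000) / 40)
        ps = delay_embed(x, EmbeddingSpec(2, 10))
        dens = nlts.recurrence_times(ps, 0.1, Tmin=5, Tmax=100)
        assert dens.T[np.argmax(dens.P)] in (39, 40)

    @pytest.mark.parametrize("n,eps", [(300, 0.4), (600, 0.8)])
    def test_matches_vertical_zero_run_oracle(self, rng, n, eps):
        x = rng.standard_normal(n)
        ps = delay_embed(x, EmbeddingSpec(2, 3))
        dens = nlts.recurrence_times(ps, eps, Tmin=1, Tmax=50, chunk=97)
        expected = brute_force_recurrence_times(ps.states, eps, 1, 50)
        assert np.array_equal(dens.R, expected)

    def test_total_count_conserved_between_R_and_P(self, rng):
        ps = delay_embed(rng.standard_normal(300), EmbeddingSpec(2, 2))
        dens = nlts.recurrence_times(ps, 0.6, Tmin=1, Tmax=60)
        assert dens.P.sum() * dens.R.sum() == pytest.approx(dens.R.sum())


class TestRecurrenceAmplitude:
    def test_constant_signal_zero_amplitude(self):
        ps = nlts.PhaseSpace(np.zeros((60, 1)), EmbeddingSpec(1, 1), 60)
        # constant signal: every state recurs immediately, no gaps at all
        dens, amp, _, _ = nlts.recurrence_amplitude(ps, 0.5, Tmin=1, Tmax=20)
        assert np.all(amp == 0.0)

    def test_sine_amplitude_two_reads_two(self):
        # quarter-period delay embedding of a sin(.) traces a circle of
        # radius a: the half-diameter convention reports the amplitude
        fs, f = 1000.0, 20.0
        x = 2.0 * np.sin(2 * np.pi * f * np.arange(5000) / fs)
        ps = delay_embed(x, EmbeddingSpec(2, int(fs / f / 4)))
        dens, amp, weighted, _ = nlts.recurrence_amplitude(
            ps, 0.1, Tmin=10, Tmax=80)
        period = int(round(fs / f))
        sel = np.abs(dens.T - period) <= 1
        assert amp[sel].max() == pytest.approx(2.0, rel=0.05)

    def test_amplitude_scales_linearly_with_signal(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 50)
        out = {}
        for scale in (1.0, 2.0):
            ps = delay_embed(scale * x, EmbeddingSpec(2, 12))
            dens, amp, _, _ = nlts.recurrence_amplitude(
                ps, 0.05 * scale, Tmin=10, Tmax=80)
            out[scale] = amp[np.argmax(dens.P)]
        assert out[2.0] == pytest.approx(2 * out[1.0], rel=1e-6)


@pytest.fixture(scope="module")
def sine_spectrum():
    ts = nlts.generate_compound_oscillation(3.0, 100.0, 20.0, ["sine"],
                                            noise_frac=0.08, seed=2)
    return nlts.sreps(ts, EmbeddingSpec(2, 8), Tmin=2, Tmax=100)


class TestSreps:
    def test_columns_are_probability_distributions(self, sine_spectrum):
        sums = sine_spectrum.P.sum(axis=0)
        nonempty = sine_spectrum.R.sum(axis=0) > 0
        assert np.allclose(sums[nonempty], 1.0)
        assert np.all(sine_spectrum.P >= 0)

    def test_band_meets_noise_regime_at_true_period(self, sine_spectrum):
        T, _ = nlts.dominant_period(sine_spectrum)
        assert abs(T - 33) <= 2

    def test_large_epsilon_shifts_mass_to_small_T(self, sine_spectrum):
        P = sine_spectrum.P
        meanT = (sine_spectrum.T[:, None] * P).sum(axis=0)
        nonempty = sine_spectrum.R.sum(axis=0) > 0
        # mean period at the largest scales well below the band period
        assert meanT[nonempty][-1] < meanT[nonempty].max() - 5
        # dominant band drifts monotonically (within 1 sample) as eps grows
        band = [sine_spectrum.T[np.argmax(P[:, g])]
                for g in range(30, 100, 10)]
        assert np.all(np.diff(band) <= 1)


class TestTras:
    def test_window_count_arithmetic(self, rng):
        x = rng.standard_normal(1000)
        spec = nlts.tras(x, EmbeddingSpec(2, 1), 50.0, window_len=200,
                         overlap=0.5, Tmax=50)
        assert spec.axis2.size == (1000 - 200) // 100 + 1

    def test_stationary_sine_constant_band(self):
        x = np.sin(2 * np.pi * np.arange(4000) / 40)
        spec = nlts.tras(x, EmbeddingSpec(2, 10), 25.0, window_len=400,
                         Tmin=5, Tmax=90)
        peaks = [spec.T[np.argmax(spec.P[:, w])]
                 for w in range(spec.axis2.size)]
        assert np.ptp(peaks) <= 2
        assert abs(np.mean(peaks) - 40) <= 3

    def test_window_too_short_to_embed_fails(self, rng):
        with pytest.raises(ValueError):
            nlts.tras(rng.standard_normal(500), EmbeddingSpec(5, 30), 50.0,
                      window_len=100)
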