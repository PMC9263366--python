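"""Surrogate-data generation and nonparametric statistics.

Surrogate series realize the null hypothesis of a linear (possibly
Gaussian-rescaled) stochastic process: value shuffling, block shuffling,
phase randomization (exact amplitude-spectrum conservation) and iterative
amplitude-adjusted phase randomization (exact value-distribution
conservation with spectrum matching).  On top of these, the time-reversal
asymmetry test for nonlinearity, a surrogate Z test for arbitrary
statistics, and two nonparametric group tests (Monte-Carlo permutation and
cluster-based permutation) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as _norm

from .embedding import TimeSeries, _series, autocorrelation_time

__all__ = [
    "SurrogateEnsemble",
    "TestResult",
    "ClusterResult",
    "make_surrogates",
    "time_reversal_statistic",
    "surrogate_z_test",
    "monte_carlo_test",
    "cluster_permutation_test",
]


@dataclass
class SurrogateEnsemble:
    """n_surr realizations of a surrogate null for one series."""

    realizations: np.ndarray     # (n_surr, N)
    method: str
    seed: int
    n_iterations: int | None = None


@dataclass
class TestResult:
    observed: float
    surrogate_stats: np.ndarray | None
    z: float | None
    p: float
    significant: bool
    alpha: float = 0.05


@dataclass
class ClusterResult:
    clusters: list               # list of (start, end) inclusive sample indices
    masses: np.ndarray
    p_values: np.ndarray
    threshold: np.ndarray
    t_obs: np.ndarray


def _phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized copy with the amplitude spectrum conserved exactly."""
    n = x.size
    X = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, X.size)
    rot = np.exp(1j * phases)
    rot[0] = 1.0                      # keep DC
    if n % 2 == 0:
        rot[-1] = 1.0                 # keep the Nyquist bin real
    return np.fft.irfft(X * rot, n=n)


def _aaft_one(x: np.ndarray, rng: np.random.Generator, tol: float,
              max_iter: int) -> tuple[np.ndarray, int]:
    """Iterative amplitude-adjusted phase randomization of one realization."""
    n = x.size
    sorted_x = np.sort(x)
    amp = np.abs(np.fft.rfft(x))
    s = _phase_randomize(x, rng)
    prev_disc = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # Rank-sort the surrogate onto the original value distribution.
        ranks = np.argsort(np.argsort(s))
        s = sorted_x[ranks]
        # Impose the original amplitude spectrum.
        S = np.fft.rfft(s)
        mag = np.abs(S)
        S = np.where(mag > 0, S / np.where(mag > 0, mag, 1.0), 1.0) * amp
        s2 = np.fft.irfft(S, n=n)
        disc = np.linalg.norm(np.abs(np.fft.rfft(sorted_x[np.argsort(np.argsort(s2))])) - amp) / np.linalg.norm(amp)
        s = s2
        if abs(prev_disc - disc) < tol:
            break
        prev_disc = disc
    # Final rank sort: value distribution conserved exactly.
    ranks = np.argsort(np.argsort(s))
    return sorted_x[ranks], it


def make_surrogates(ts: TimeSeries | np.ndarray, method: str = "ft",
                    n: int = 100, seed: int = 0, block_len: int | None = None,
                    tol: float = 1e-4, max_iterations: int = 100
                    ) -> SurrogateEnsemble:
    """Generate a surrogate ensemble for a series.

    Methods: ``shuffle`` (value permutation; conserves the value multiset),
    ``block_shuffle`` (permutes blocks of ``block_len`` samples, default the
    autocorrelation time), ``ft`` (phase randomization; conserves the
    amplitude spectrum exactly) and ``aaft`` (iterative amplitude-adjusted
    phase randomization; conserves the value distribution exactly while
    matching the spectrum, stopping when the relative spectral discrepancy
    changes by less than ``tol`` or after ``max_iterations``).
    """
    x = _series(ts)
    if n < 1:
        raise ValueError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    N = x.size
    out = np.empty((n, N))
    iters = None
    if method == "shuffle":
        for i in range(n):
            out[i] = rng.permutation(x)
    elif method == "block_shuffle":
        if block_len is None:
            block_len = autocorrelation_time(x)
        n_blocks = int(np.ceil(N / block_len))
        for i in range(n):
            order = rng.permutation(n_blocks)
            parts = [x[b * block_len:(b + 1) * block_len] for b in order]
            out[i] = np.concatenate(parts)[:N]
    elif method == "ft":
        for i in range(n):
            out[i] = _phase_randomize(x, rng)
    elif method == "aaft":
        iters = 0
        for i in range(n):
            out[i], it = _aaft_one(x, rng, tol, max_iterations)
            iters = max(iters, it)
    else:
        raise ValueError(f"unknown surrogate method: {method!r}")
    return SurrogateEnsemble(out, method, seed, iters)


def time_reversal_statistic(ts: TimeSeries | np.ndarray, dt: int = 1) -> float:
    """Time-reversal asymmetry statistic Q = <(x_t - x_{t-dt})^3>.

    Q quantifies the sharpness of a signal's transitions backward in time;
    it vanishes for time-reversible (e.g. linear Gaussian) processes and is
    strongly signed for asymmetric waveforms such as sawtooths.
    """
    x = _series(ts)
    if dt < 1:
        raise ValueError("dt must be at least 1")
    if x.size <= dt:
        raise ValueError("series must be longer than dt")
    return float(np.mean((x[dt:] - x[:-dt]) ** 3))


def surrogate_z_test(ts: TimeSeries | np.ndarray, statistic_fn,
                     ensemble: SurrogateEnsemble, alpha: float = 0.05
                     ) -> TestResult:
    """Two-sided surrogate Z test of an arbitrary statistic.

    Z = (observed - mean(surrogates)) / SD(surrogates); the null is rejected
    when |Z| exceeds the two-sided normal quantile at ``alpha`` (1.96 at the
    5% level), with p taken from the standard normal tail.
    """
    obs = float(statistic_fn(_series(ts)))
    surr = np.array([statistic_fn(s) for s in ensemble.realizations])
    sd = surr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero surrogate variance: Z undefined")
    z = (obs - surr.mean()) / sd
    p = float(2.0 * _norm.sf(abs(z)))
    return TestResult(obs, surr, float(z), p, bool(abs(z) > _norm.ppf(1 - alpha / 2)),
                      alpha)


def monte_carlo_test(sampleA, sampleB, statistic="mean_difference",
                     n_perm: int = 1000, seed: int = 0, alpha: float = 0.05
                     ) -> TestResult:
    """Two-sided Monte-Carlo permutation test between two samples.

    Labels are permuted ``n_perm`` times; the p-value carries the +1
    correction, p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1), and is
    therefore never exactly zero.
    """
    a = np.asarray(_series(sampleA), dtype=float)
    b = np.asarray(_series(sampleB), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if statistic == "mean_difference":
        stat = lambda u, v: u.mean() - v.mean()
    elif callable(statistic):
        stat = statistic
    else:
        raise ValueError(f"unknown statistic: {statistic!r}")
    obs = float(stat(a, b))
    pooled = np.concatenate([a, b])
    na = a.size
    rng = np.random.default_rng(seed)
    count = 0
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        perm_stats[i] = stat(perm[:na], perm[na:])
        if abs(perm_stats[i]) >= abs(obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(obs, perm_stats, None, float(p), bool(p < alpha), alpha)


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1) / a.shape[0]
    vb = b.var(axis=0, ddof=1) / b.shape[0]
    denom = np.sqrt(va + vb)
    return np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)


def _clusters_from_mask(mask: np.ndarray):
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def cluster_permutation_test(condA: np.ndarray, condB: np.ndarray,
                             threshold: float | np.ndarray | None = None,
                             n_perm: int = 1000, seed: int = 0,
                             alpha: float = 0.05) -> ClusterResult:
    """Cluster-based permutation test between two trial sets (trials x samples).

    A pointwise Welch t statistic is thresholded (by default at the 97.5th
    percentile of its own per-sample permutation distribution of |t|);
    contiguous suprathreshold samples form clusters scored by the sum of
    their t values, and each cluster's p-value compares its |mass| against
    the permutation null of the maximum |cluster mass|.  With no
    suprathreshold samples the cluster list is empty and the global p is 1.
    """
    a = np.asarray(condA, dtype=float)
    b = np.asarray(condB, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("conditions must be 2-D with matching sample counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    na = a.shape[0]
    n_tot = pooled.shape[0]
    t_obs = _welch_t(a, b)

    perm_t = np.empty((n_perm, a.shape[1]))
    for i in range(n_perm):
        order = rng.permutation(n_tot)
        perm_t[i] = _welch_t(pooled[order[:na]], pooled[order[na:]])
    if threshold is None:
        thr = np.quantile(np.abs(perm_t), 0.975, axis=0)
    else:
        thr = np.broadcast_to(np.asarray(threshold, dtype=float), t_obs.shape)

    def cluster_masses(t: np.ndarray):
        cl = _clusters_from_mask(np.abs(t) > thr)
        return cl, np.array([t[s:e + 1].sum() for s, e in cl])

    clusters, masses = cluster_masses(t_obs)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        _, m = cluster_masses(perm_t[i])
        if m.size:
            null_max[i] = np.abs(m).max()
    if clusters:
        p = np.array([(1 + np.sum(null_max >= abs(m))) / (n_perm + 1)
                      for m in masses])
    else:
        p = np.array([])
    return ClusterResult(clusters, masses, p, np.asarray(thr), t_obs)
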