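"""Dynamic invariants: correlation dimension, Lyapunov exponents, unstable
periodic orbits and detrended fluctuation analysis.

The correlation sum follows Grassberger-Procaccia with a Theiler window; the
largest Lyapunov exponent is estimated by either the Kantz (average over an
epsilon-neighborhood) or the Rosenstein (single nearest neighbor) divergence
curve; period-one unstable periodic orbits of map data are located by a
local-linearization transform whose random perturbations disperse
non-periodic points while fixed points accumulate density on the phase-space
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .embedding import EmbeddingSpec, PhaseSpace, TimeSeries, _series, delay_embed

__all__ = [
    "CorrelationCurve",
    "DivergenceCurve",
    "UpoResult",
    "correlation_sum",
    "correlation_dimension",
    "propose_fit_range",
    "lyapunov_curve",
    "lyapunov_fit",
    "upo_transform",
    "upo_significance",
    "dfa",
]


@dataclass
class CorrelationCurve:
    """Correlation sums C(eps) per embedding dimension with fitted slopes."""

    epsilons: np.ndarray
    C: dict                      # dim -> correlation sums
    fit_range: tuple[float, float] | None = None
    D2: dict = field(default_factory=dict)   # dim -> fitted slope


@dataclass
class DivergenceCurve:
    """Mean log-distance of neighbor pairs per iteration step."""

    iterations: np.ndarray
    delta: np.ndarray
    fs: float | None = None
    fit_range: tuple[int, int] | None = None
    lam_per_sample: float | None = None
    lam_per_second: float | None = None


@dataclass
class UpoResult:
    """Diagonal density of the period-one orbit transform."""

    bin_centers: np.ndarray
    density: np.ndarray          # normalized: sums to 1 over bins * width
    mode: float
    n_transforms: int
    z: float | None = None
    p: float | None = None


def _chebyshev_chunk(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Max-norm distances between every row of ``a`` and of ``b``."""
    d = np.abs(a[:, None, 0] - b[None, :, 0])
    for c in range(1, a.shape[1]):
        np.maximum(d, np.abs(a[:, None, c] - b[None, :, c]), out=d)
    return d


def correlation_sum(ps: PhaseSpace, epsilons: np.ndarray | None = None,
                    theiler: int = 0, chunk: int = 512) -> CorrelationCurve:
    """Grassberger-Procaccia correlation sum C(eps) with Theiler exclusion.

    C(eps) is the fraction of admissible state pairs (temporal separation
    greater than ``theiler``) closer than eps under the maximum norm; by
    construction it is non-decreasing in eps and reaches 1 at the attractor
    diameter.  Defaults to 30 log-spaced eps between 1% and 100% of the
    diameter.
    """
    states = np.asarray(ps.states, dtype=np.float32)
    n = states.shape[0]
    diam = ps.diameter("maximum")
    if epsilons is None:
        epsilons = np.geomspace(0.01 * diam, diam, 30)
    epsilons = np.asarray(epsilons, dtype=float)
    n_pairs = 0
    counts = np.zeros(epsilons.size, dtype=np.int64)
    edges = np.concatenate([[0.0], epsilons])
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = _chebyshev_chunk(states[start:stop], states)
        rows = np.arange(start, stop)[:, None]
        cols = np.arange(n)[None, :]
        admissible = cols - rows > theiler      # j > i + w: each pair once
        dv = d[admissible]
        n_pairs += dv.size
        hist, _ = np.histogram(dv, bins=edges)
        counts += np.cumsum(hist)
    if n_pairs < 2:
        raise ValueError("fewer than 2 admissible pairs after Theiler exclusion")
    return CorrelationCurve(epsilons, {ps.spec.dim: counts / n_pairs})


def propose_fit_range(x: np.ndarray, y: np.ndarray,
                      slope_var: float = 0.15, min_points: int = 3):
    """Longest contiguous interval of (x, y) where the local slope is stable.

    Local slopes between consecutive points must stay within ``slope_var``
    (relative spread) of the window mean.  Returns an index pair
    ``(i0, i1)`` (inclusive); used to pick scaling regions for the
    correlation-dimension and Lyapunov fits, which the eye would otherwise
    choose.
    """
    ok = np.isfinite(y)
    s = np.diff(y[ok]) / np.diff(x[ok])
    idx = np.flatnonzero(ok)
    best = None
    for i in range(s.size):
        for j in range(i + min_points - 1, s.size):
            w = s[i: j + 1]
            m = np.mean(w)
            if m == 0 or (w.max() - w.min()) > slope_var * abs(m):
                break
            best_len = 0 if best is None else best[1] - best[0]
            if j - i > best_len or best is None:
                best = (i, j)
    if best is None:
        raise ValueError("no stable scaling region found")
    return int(idx[best[0]]), int(idx[best[1] + 1])


def correlation_dimension(curve: CorrelationCurve,
                          fit_range: tuple[float, float] | None = None) -> dict:
    """Least-squares slope of log C vs log eps per embedding dimension.

    ``fit_range`` is an (eps_lo, eps_hi) interval; if omitted, the longest
    stable-slope region of each curve is used.  At least 3 points with C > 0
    must fall inside the range.
    """
    out = {}
    log_eps = np.log(curve.epsilons)
    for dim, C in curve.C.items():
        C = np.asarray(C, dtype=float)
        with np.errstate(divide="ignore"):
            log_C = np.where(C > 0, np.log(C), -np.inf)
        if fit_range is None:
            i0, i1 = propose_fit_range(log_eps, np.where(C > 0, log_C, np.nan))
            sel = np.zeros(C.size, bool)
            sel[i0: i1 + 1] = True
        else:
            sel = (curve.epsilons >= fit_range[0]) & (curve.epsilons <= fit_range[1])
        sel &= C > 0
        if sel.sum() < 3:
            raise ValueError("fit range must contain at least 3 points with C > 0")
        slope = np.polyfit(log_eps[sel], log_C[sel], 1)[0]
        out[dim] = float(slope)
    curve.D2.update(out)
    curve.fit_range = fit_range
    return out


def lyapunov_curve(ps: PhaseSpace, algorithm: str = "kantz",
                   epsilon: float | None = None, iterations: int = 10,
                   theiler: int = 0, max_references: int | None = None,
                   seed: int = 0) -> DivergenceCurve:
    """Divergence curve delta(dt) for the largest-Lyapunov-exponent estimate.

    ``kantz``: delta(dt) averages, over reference states, the log of the
    *mean* distance between the reference's future and the futures of all
    neighbors within ``epsilon`` (default 5% of the attractor diameter).
    ``rosenstein``: the single nearest neighbor per reference is followed
    instead.  References whose neighborhood is empty are skipped; if all are
    skipped this is an error.
    """
    states = ps.states
    n = ps.n_states
    last = n - 1 - iterations
    if last < 1:
        raise ValueError("series too short for the requested iterations")
    diam = ps.diameter("maximum")
    refs = np.arange(last + 1)
    if max_references is not None and refs.size > max_references:
        rng = np.random.default_rng(seed)
        refs = np.sort(rng.choice(refs, size=max_references, replace=False))
    dts = np.arange(iterations + 1)
    tree = cKDTree(states[: last + 1])
    sums = np.zeros(iterations + 1)
    n_used = 0
    if algorithm == "kantz":
        if epsilon is None:
            epsilon = 0.05 * diam
        lists = tree.query_ball_point(states[refs], r=epsilon, p=np.inf)
        for ri, lst in enumerate(lists):
            i = refs[ri]
            j = np.asarray(lst, dtype=np.intp)
            j = j[np.abs(j - i) > theiler]
            if j.size == 0:
                continue
            fut = states[j[:, None] + dts[None, :]]          # (m, it+1, d)
            ref = states[i + dts][None, :, :]
            d = np.abs(fut - ref).max(axis=2)                # max norm
            sums += np.log(d.mean(axis=0))
            n_used += 1
    elif algorithm == "rosenstein":
        kq = min(last + 1, 2 * theiler + 2)
        dist, idx = tree.query(states[refs], k=kq, p=np.inf)
        for ri in range(refs.size):
            i = refs[ri]
            sel = np.abs(idx[ri] - i) > theiler
            if not np.any(sel):
                continue
            j = idx[ri][sel][0]
            d = np.abs(states[j + dts] - states[i + dts]).max(axis=1)
            d = np.maximum(d, 1e-300)
            sums += np.log(d)
            n_used += 1
    else:
        raise ValueError(f"unknown Lyapunov algorithm: {algorithm!r}")
    if n_used == 0:
        raise ValueError("every reference state had an empty neighborhood")
    return DivergenceCurve(dts, sums / n_used, fs=ps.fs)


def lyapunov_fit(curve: DivergenceCurve,
                 fit_range: tuple[int, int] = (1, 10)) -> float:
    """Slope of delta(dt) over ``fit_range`` (inclusive, in iteration steps).

    The slope is the largest Lyapunov exponent per sample; when the sampling
    rate is known it is also stored per second.  Fitting across a flat
    saturation region yields a value near zero - choose the linear region.
    """
    lo, hi = fit_range
    sel = (curve.iterations >= lo) & (curve.iterations <= hi)
    sel &= np.isfinite(curve.delta)
    if sel.sum() < 2:
        raise ValueError("fit range must contain at least 2 finite points")
    lam = float(np.polyfit(curve.iterations[sel], curve.delta[sel], 1)[0])
    curve.fit_range = (lo, hi)
    curve.lam_per_sample = lam
    curve.lam_per_second = lam * curve.fs if curve.fs else None
    return lam


def _upo_pass(x: np.ndarray, xn: np.ndarray, slopes: np.ndarray,
              kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One randomized transform repetition; returns fixed-point estimates."""
    u = rng.uniform(-kappa, kappa, size=x.size)
    sd = np.std(x)
    s = slopes + u * (xn - x) / sd
    denom = 1.0 - s
    ok = np.abs(denom) > 1e-8
    return ((xn - s * x) / np.where(ok, denom, np.nan))[ok]


def upo_transform(ts: TimeSeries | np.ndarray, n_transforms: int = 100,
                  kappa_scale: float | None = None, k_neighbors: int = 10,
                  n_bins: int = 400, seed: int = 0) -> UpoResult:
    """Detect period-one unstable periodic orbits of one-dimensional map data.

    The series is viewed as successor pairs (x_n, x_{n+1}).  For every point
    a local slope is fitted by least squares over its ``k_neighbors`` nearest
    pairs and mapped to the fixed-point estimate
    ``x* = (x_{n+1} - s x_n) / (1 - s)``.  A fresh random perturbation of the
    slope (scale ``kappa_scale``, default 0.1*SD, weighted by the local
    displacement so it vanishes at true fixed points) is applied on each of
    the ``n_transforms`` repetitions: fixed points accumulate in the
    histogram of x* along the diagonal while unrelated points disperse.
    """
    xall = _series(ts)
    x, xn = xall[:-1], xall[1:]
    if kappa_scale is None:
        kappa_scale = 0.1 * float(np.std(xall))
    pairs = np.column_stack([x, xn])
    tree = cKDTree(pairs)
    k = min(k_neighbors + 1, len(x))
    _, idx = tree.query(pairs, k=k)
    slopes = np.empty(x.size)
    for i in range(x.size):
        nb = idx[i]
        xs, ys = x[nb], xn[nb]
        vx = xs - xs.mean()
        denom = np.dot(vx, vx)
        slopes[i] = np.dot(vx, ys - ys.mean()) / denom if denom > 0 else 0.0
    lo, hi = float(xall.min()), float(xall.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    width = edges[1] - edges[0]
    counts = np.zeros(n_bins)
    rng = np.random.default_rng(seed)
    kappa = kappa_scale / float(np.std(xall))
    for _ in range(n_transforms):
        est = _upo_pass(x, xn, slopes, kappa, rng)
        est = est[(est >= lo) & (est <= hi)]
        counts += np.histogram(est, bins=edges)[0]
    total = counts.sum()
    if total == 0:
        raise ValueError("UPO transform produced no in-range fixed-point estimates")
    density = counts / (total * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[np.argmax(density)])
    return UpoResult(centers, density, mode, n_transforms)


def upo_significance(ts: TimeSeries | np.ndarray, n_surrogates: int = 100,
                     surrogate_method: str = "aaft", alpha: float = 0.05,
                     seed: int = 0, **upo_kwargs):
    """Surrogate test of the UPO diagonal density peak.

    The observed peak density is compared against the distribution of peak
    densities of surrogate series (same transform, same parameters); the
    returned result carries Z = (obs - mean) / SD and a two-sided normal p.
    """
    from scipy.stats import norm as _norm

    from .surrogates import make_surrogates

    x = _series(ts)
    obs = upo_transform(x, seed=seed, **upo_kwargs)
    ens = make_surrogates(x, method=surrogate_method, n=n_surrogates, seed=seed + 1)
    peaks = np.empty(n_surrogates)
    for i in range(n_surrogates):
        peaks[i] = upo_transform(ens.realizations[i], seed=seed + 2 + i,
                                 **upo_kwargs).density.max()
    sd = peaks.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate surrogate peak distribution (zero variance)")
    z = (obs.density.max() - peaks.mean()) / sd
    obs.z = float(z)
    obs.p = float(2 * _norm.sf(abs(z)))
    return obs, bool(abs(z) > _norm.ppf(1 - alpha / 2))


def dfa(ts: TimeSeries | np.ndarray, scales: np.ndarray | None = None,
        detrend_order: int = 1):
    """Detrended fluctuation analysis: F(s) and the scaling exponent alpha.

    The centered series is integrated, split into non-overlapping windows of
    each scale (taken from both ends to use all samples), detrended per
    window with a polynomial of ``detrend_order``, and the RMS fluctuation is
    recorded; alpha is the log-log slope.  White noise gives alpha ~ 0.5, a
    random walk ~ 1.5.  Scales above N/4 are excluded with a warning.
    """
    import warnings

    x = _series(ts)
    n = x.size
    if np.ptp(x) == 0.0:
        raise ValueError("constant series: DFA fluctuations are zero")
    y = np.cumsum(x - x.mean())
    if scales is None:
        lo = max(detrend_order + 2, 16)
        scales = np.unique(np.geomspace(lo, n // 4, 12).astype(int))
    scales = np.asarray(scales, dtype=int)
    if np.any(scales < detrend_order + 2):
        raise ValueError("minimum scale must be at least detrend_order + 2")
    if np.any(scales > n // 4):
        warnings.warn("scales above N/4 excluded", RuntimeWarning, stacklevel=2)
        scales = scales[scales <= n // 4]
    F = np.empty(scales.size)
    t = {}
    for si, s in enumerate(scales):
        n_win = n // s
        if s not in t:
            t[s] = np.arange(s)
        rms = []
        for segset in (y[: n_win * s].reshape(n_win, s),
                       y[n - n_win * s:].reshape(n_win, s)):
            coef = np.polynomial.polynomial.polyfit(t[s], segset.T, detrend_order)
            fit = np.polynomial.polynomial.polyval(t[s], coef)
            rms.append(np.mean((segset - fit) ** 2, axis=1))
        F[si] = np.sqrt(np.mean(np.concatenate(rms)))
    alpha = float(np.polyfit(np.log(scales), np.log(F), 1)[0])
    return scales, F, alpha
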