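"""Delay embedding and embedding-parameter selection.

Implements Takens-style delay reconstruction of a scalar series, exact
neighbor search in the reconstructed phase-space (the shared contract used by
all downstream estimators), and the two classic parameter-selection routes:
the deterministic one (auto-mutual information for the delay, false nearest
neighbors for the dimension) and the stochastic one (the Ragwitz prediction
criterion, which co-optimizes both on a local-predictor error grid).

Index convention: 0-based; a state's index is the index of its *last*
coordinate, so ``states[k, j] = x[k + j*tau]`` and the state at row ``k``
describes time ``k + (dim-1)*tau``.  Predictions at horizon ``dt`` therefore
read the sample ``dt`` steps after a state's last coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TimeSeries",
    "EmbeddingSpec",
    "PhaseSpace",
    "NeighborStructure",
    "FnnParams",
    "delay_embed",
    "find_neighbors",
    "autocorrelation_time",
    "auto_mutual_information",
    "false_nearest_neighbors",
    "ragwitz_optimize",
    "nonlinear_predict",
    "space_time_separation",
    "optimize_embedding",
]


@dataclass
class TimeSeries:
    """A sampled real-valued signal with an optional sampling rate (Hz)."""

    values: np.ndarray
    fs: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must all be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension ``dim`` and delay ``tau`` (samples)."""

    dim: int
    tau: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1 or self.tau < 1:
            raise ValueError("dim and tau must be positive integers")


@dataclass
class PhaseSpace:
    """Delay-embedded state matrix (n_states x dim) plus its embedding spec."""

    states: np.ndarray
    spec: EmbeddingSpec
    source_length: int
    fs: float | None = None

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def dim(self) -> int:
        return self.states.shape[1]

    def diameter(self, norm: str = "maximum") -> float:
        """Attractor diameter: the largest pairwise state distance.

        Under the maximum norm this is simply the widest per-coordinate
        range, which is exact and O(n).  For the Euclidean norm the
        coordinate-range bound is used (exact for axis-aligned extents,
        an upper bound otherwise); all defaults in this package use the
        maximum norm.
        """
        rng = self.states.max(axis=0) - self.states.min(axis=0)
        if norm == "maximum":
            return float(rng.max())
        return float(np.sqrt(np.sum(rng ** 2)))


@dataclass
class NeighborStructure:
    """Per-reference neighbor index lists from an exact phase-space search."""

    reference_indices: np.ndarray
    neighbors: list
    mode: str                 # "radius" or "count"
    value: float              # epsilon (data units) or k
    norm: str = "maximum"
    theiler: int = 0


def _series(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    return np.asarray(x, dtype=float)


def delay_embed(ts: TimeSeries | np.ndarray, spec: EmbeddingSpec,
                fs: float | None = None) -> PhaseSpace:
    """Delay-embed a scalar series: ``states[k, j] = x[k + j*tau]``.

    With ``dim == 1`` the states are the series itself.  Raises a
    ``ValueError`` naming the minimum length if the series is too short.
    """
    x = _series(ts)
    if isinstance(ts, TimeSeries) and fs is None:
        fs = ts.fs
    n = x.size
    need = (spec.dim - 1) * spec.tau + 1
    if n < need:
        raise ValueError(
            f"series of length {n} is too short to embed with dim={spec.dim}, "
            f"tau={spec.tau}; at least {need} samples are required")
    n_states = n - (spec.dim - 1) * spec.tau
    cols = [x[j * spec.tau: j * spec.tau + n_states] for j in range(spec.dim)]
    states = np.column_stack(cols)
    return PhaseSpace(states, spec, source_length=n, fs=fs)


def _minkowski_p(norm: str) -> float:
    if norm == "maximum":
        return np.inf
    if norm == "euclidean":
        return 2.0
    raise ValueError(f"unknown norm: {norm!r}")


def find_neighbors(ps: PhaseSpace, mode: str = "radius", value: float = 1.0,
                   norm: str = "maximum", theiler: int = 0) -> NeighborStructure:
    """Exact neighbor sets in phase-space with Theiler exclusion.

    ``mode='radius'`` returns, per state, all states within ``value`` (same
    units as the data); ``mode='count'`` the ``value`` nearest states.  Pairs
    with temporal separation ``|i-j| <= theiler`` are never neighbors (this
    always excludes the self-pair).  Empty neighborhoods are allowed.
    """
    if theiler < 0:
        raise ValueError("theiler must be non-negative")
    n = ps.n_states
    p = _minkowski_p(norm)
    tree = cKDTree(ps.states)
    refs = np.arange(n)
    out: list[np.ndarray] = []
    if mode == "radius":
        if value <= 0:
            raise ValueError("radius must be positive")
        lists = tree.query_ball_point(ps.states, r=value, p=p, return_sorted=True)
        for i, lst in enumerate(lists):
            j = np.asarray(lst, dtype=np.intp)
            out.append(j[np.abs(j - i) > theiler])
    elif mode == "count":
        k = int(value)
        if k < 1:
            raise ValueError("neighbor count must be at least 1")
        # Over-query so that Theiler-excluded hits can be discarded.
        kq = min(n, k + 2 * theiler + 1)
        _, idx = tree.query(ps.states, k=kq, p=p)
        idx = np.atleast_2d(idx)
        for i in range(n):
            j = idx[i]
            j = j[np.abs(j - i) > theiler]
            out.append(j[:k].astype(np.intp))
    else:
        raise ValueError(f"unknown neighbor mode: {mode!r}")
    return NeighborStructure(refs, out, mode, float(value), norm, theiler)


def autocorrelation_time(ts: TimeSeries | np.ndarray) -> int:
    """First zero crossing (in samples) of the autocorrelation function.

    If no crossing occurs within N/2 lags, N/10 is returned.
    """
    x = _series(ts)
    x = x - x.mean()
    n = x.size
    max_lag = n // 2
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("constant series has no autocorrelation time")
    for lag in range(1, max_lag + 1):
        if np.dot(x[:-lag], x[lag:]) <= 0.0:
            return lag
    return max(1, n // 10)


def auto_mutual_information(ts: TimeSeries | np.ndarray, max_lag: int,
                            estimator: str = "binned", bins: int | str = "auto",
                            k: int = 4) -> tuple[np.ndarray, int | None]:
    """Auto-mutual information AMI(lag) for lags 0..max_lag, plus its first minimum.

    AMI(lag) is the mutual information between the series and its lag-shifted
    copy; AMI(0) equals the marginal entropy under the same discretization.
    The first minimum is the smallest lag that is a strict local minimum of
    the curve (``None`` if there is none) and is the classic delay choice for
    phase-space reconstruction.
    """
    from . import infotheory as it

    x = _series(ts)
    n = x.size
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    if np.ptp(x) == 0.0:
        raise ValueError("constant series: mutual information undefined")
    if estimator == "binned":
        nb = it.freedman_diaconis_bins(x) if bins == "auto" else int(bins)
        edges = np.linspace(x.min(), x.max(), nb + 1)
        ami = np.empty(max_lag + 1)
        ami[0] = it.entropy_binned(x, bins=edges).value
        for lag in range(1, max_lag + 1):
            ami[lag] = it.mutual_information(
                x[:-lag], x[lag:], estimator="binned", bins=edges).value
    elif estimator == "knn":
        ami = np.empty(max_lag + 1)
        ami[0] = it.entropy_knn(x, k=k).value
        for lag in range(1, max_lag + 1):
            ami[lag] = it.mutual_information(
                x[:-lag], x[lag:], estimator="ksg", k=k).value
    else:
        raise ValueError(f"unknown AMI estimator: {estimator!r}")
    first_min: int | None = None
    look = 5    # guard against single-lag dips from binning artifacts
    for lag in range(1, max_lag):
        ahead = ami[lag + 1: min(lag + 1 + look, max_lag + 1)]
        if ami[lag] < ami[lag - 1] and ahead.size and ami[lag] < ahead.min():
            first_min = lag
            break
    return ami, first_min


@dataclass
class FnnParams:
    """Kennel false-nearest-neighbor thresholds and dimension range.

    ``Rtol`` flags neighbors whose separation grows disproportionately when
    one more delay coordinate is added; ``Atol`` (in units of the series SD)
    flags neighbors that end up far apart on the scale of the attractor.
    """

    Rtol: float = 10.0
    Atol: float = 2.0
    dims: tuple[int, ...] = tuple(range(1, 10))

    def __post_init__(self) -> None:
        if self.Rtol <= 0 or self.Atol <= 0:
            raise ValueError("Rtol and Atol must be positive")


def false_nearest_neighbors(ts: TimeSeries | np.ndarray, tau: int,
                            params: FnnParams | None = None, theiler: int = 0,
                            drop_threshold: float = 0.01
                            ) -> tuple[np.ndarray, int | None]:
    """False-nearest-neighbor fraction per embedding dimension.

    For each candidate dimension ``d`` the nearest neighbor of every state is
    located in the d-dimensional reconstruction (maximum norm, Theiler
    exclusion) and declared *false* if adding the (d+1)-th coordinate either
    increases the pair distance by more than ``Rtol`` times its d-dimensional
    value, or stretches it beyond ``Atol`` times the series SD.  The
    suggested dimension is the lowest with a fraction below
    ``drop_threshold``.
    """
    if params is None:
        params = FnnParams()
    x = _series(ts)
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("constant series: FNN criterion degenerate")
    dims = tuple(params.dims)
    fractions = np.empty(len(dims))
    for di, d in enumerate(dims):
        ps_hi = delay_embed(x, EmbeddingSpec(d + 1, tau))
        lo = ps_hi.states[:, :-1]      # d-dimensional part
        extra = ps_hi.states[:, -1]    # the added coordinate, one delay ahead
        tree = cKDTree(lo)
        kq = min(lo.shape[0], 2 * theiler + 2)
        dist, idx = tree.query(lo, k=kq, p=np.inf)
        n_false = 0
        n_valid = 0
        for i in range(lo.shape[0]):
            sel = np.abs(idx[i] - i) > theiler
            if not np.any(sel):
                continue
            j = idx[i][sel][0]
            dlo = dist[i][sel][0]
            dd = abs(extra[i] - extra[j])
            n_valid += 1
            # exact recurrences (up to fp noise) are true neighbors
            tiny = 1e-10 * sd
            if dlo < tiny:
                if dd > tiny:
                    n_false += 1
                continue
            dhi = max(dlo, dd)
            if dd / dlo > params.Rtol or dhi > params.Atol * sd:
                n_false += 1
        fractions[di] = n_false / n_valid if n_valid else np.nan
    suggested: int | None = None
    for di, d in enumerate(dims):
        if np.isfinite(fractions[di]) and fractions[di] < drop_threshold:
            suggested = d
            break
    return fractions, suggested


def nonlinear_predict(ps: PhaseSpace, epsilon: float, horizon: int = 1,
                      query_indices: np.ndarray | None = None,
                      theiler: int = 0, norm: str = "maximum"):
    """Local-constant (zeroth-order) phase-space prediction.

    The forecast for a query state is the mean of the ``horizon``-step
    futures of all states within ``epsilon``; queries with empty
    neighborhoods are skipped and counted.  Returns
    ``(predictions, rmspe, n_skipped)`` where predictions forecast the scalar
    sample ``horizon`` steps after each query state's last coordinate.
    """
    x_future_source = ps.states[:, -1]
    n = ps.n_states
    last_valid = n - 1 - horizon
    if last_valid < 0:
        raise ValueError("horizon exceeds the available states")
    if query_indices is None:
        query_indices = np.arange(last_valid + 1)
    query_indices = np.asarray(query_indices)
    if np.any(query_indices > last_valid):
        raise ValueError("query index has no future at this horizon")
    p = _minkowski_p(norm)
    tree = cKDTree(ps.states[: last_valid + 1])
    preds = np.full(query_indices.size, np.nan)
    actual = x_future_source[query_indices + horizon]
    n_skipped = 0
    lists = tree.query_ball_point(ps.states[query_indices], r=epsilon, p=p)
    for qi, lst in enumerate(lists):
        i = query_indices[qi]
        j = np.asarray(lst, dtype=np.intp)
        j = j[np.abs(j - i) > theiler]
        if j.size == 0:
            n_skipped += 1
            continue
        preds[qi] = x_future_source[j + horizon].mean()
    ok = np.isfinite(preds)
    if not np.any(ok):
        rmspe = np.nan
    else:
        rmspe = float(np.sqrt(np.mean((preds[ok] - actual[ok]) ** 2)))
    return preds, rmspe, n_skipped


def _knn_predict_rmspe(x: np.ndarray, dim: int, tau: int, k: int,
                       horizon: int, theiler: int) -> float:
    """RMSPE of a k-nearest-neighbor local-constant predictor (Ragwitz cell)."""
    need = (dim - 1) * tau + 1 + horizon
    if x.size < need + k + 1:
        return np.nan
    ps = delay_embed(x, EmbeddingSpec(dim, tau))
    n = ps.n_states
    last_valid = n - 1 - horizon
    states = ps.states[: last_valid + 1]
    tree = cKDTree(states)
    kq = min(states.shape[0], k + 2 * theiler + 1)
    _, idx = tree.query(states, k=kq, p=np.inf)
    idx = np.atleast_2d(idx)
    future = ps.states[:, -1]
    se = []
    for i in range(states.shape[0]):
        j = idx[i]
        j = j[np.abs(j - i) > theiler][:k]
        if j.size == 0:
            continue
        pred = future[j + horizon].mean()
        se.append((pred - future[i + horizon]) ** 2)
    if not se:
        return np.nan
    return float(np.sqrt(np.mean(se)))


def ragwitz_optimize(ts: TimeSeries | np.ndarray,
                     dims: tuple[int, ...] | range | None = None,
                     taus: tuple[int, ...] | range | None = None,
                     k: int = 10, horizon: int = 1, theiler: int = 0):
    """Ragwitz criterion: co-optimize (dim, tau) by local prediction error.

    Every grid cell trains a k-nearest-neighbor local-constant predictor and
    scores it by root-mean-squared prediction error (RMSPE); the returned
    optimum is the argmin, with ties broken toward smaller dim, then smaller
    tau.  Defaults: dims 2..9 and taus spanning 10-100% of the
    autocorrelation time.  Cells whose neighborhoods are all empty are
    reported as NaN, not fatal.

    Returns ``(grid, dims, taus, (dim_opt, tau_opt))``.
    """
    x = _series(ts)
    if dims is None:
        dims = range(2, 10)
    if taus is None:
        act = autocorrelation_time(x)
        taus = sorted({max(1, int(round(f * act))) for f in np.linspace(0.1, 1.0, 10)})
    dims = tuple(dims)
    taus = tuple(taus)
    if not dims or not taus:
        raise ValueError("dims and taus ranges must be nonempty")
    grid = np.full((len(dims), len(taus)), np.nan)
    for a, d in enumerate(dims):
        for b, t in enumerate(taus):
            grid[a, b] = _knn_predict_rmspe(x, d, t, k, horizon, theiler)
    if not np.any(np.isfinite(grid)):
        raise ValueError("all Ragwitz grid cells are empty")
    flat = np.where(np.isfinite(grid), grid, np.inf)
    a, b = np.unravel_index(np.argmin(flat), grid.shape)  # C-order: smaller dim, then tau
    return grid, dims, taus, (dims[a], taus[b])


def space_time_separation(ps: PhaseSpace, fractions=(0.25, 0.5, 0.75),
                          max_dt: int | None = None, norm: str = "maximum",
                          plateau_window: int = 5, slope_tol: float = 0.01):
    """Space-time separation curves and a suggested Theiler window.

    For each temporal separation ``dt`` the requested quantiles of the
    spatial distance between state pairs ``(i, i+dt)`` are computed.  The
    suggested Theiler window is the first ``dt`` at which the median curve
    plateaus (slope over a ``plateau_window``-sample window below
    ``slope_tol`` of the attractor diameter per sample).

    Returns ``(dts, curves, suggested)`` with ``curves`` of shape
    (len(fractions), len(dts)).
    """
    fractions = tuple(fractions)
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1)")
    n = ps.n_states
    if max_dt is None:
        max_dt = min(n - 2, 100)
    dts = np.arange(1, max_dt + 1)
    curves = np.empty((len(fractions), dts.size))
    for di, dt in enumerate(dts):
        diff = np.abs(ps.states[:-dt] - ps.states[dt:])
        if norm == "maximum":
            d = diff.max(axis=1)
        else:
            d = np.sqrt((diff ** 2).sum(axis=1))
        curves[:, di] = np.quantile(d, fractions)
    med = curves[np.searchsorted(fractions, 0.5) if 0.5 in fractions else len(fractions) // 2]
    diam = ps.diameter(norm)
    suggested = int(dts[-1])
    w = plateau_window
    for i in range(dts.size - w):
        slope = (med[i + w] - med[i]) / w
        if abs(slope) < slope_tol * diam:
            suggested = int(dts[i])
            break
    return dts, curves, suggested


def optimize_embedding(ts: TimeSeries | np.ndarray, method: str = "deterministic",
                       max_lag: int | None = None,
                       fnn_params: FnnParams | None = None,
                       theiler: int = 0, **ragwitz_kwargs) -> EmbeddingSpec:
    """Choose embedding parameters for a series.

    ``method='deterministic'``: delay from the first minimum of the
    auto-mutual information, then dimension from the false-nearest-neighbor
    drop.  ``method='stochastic'``: joint Ragwitz prediction-error grid.
    """
    x = _series(ts)
    if method == "deterministic":
        if max_lag is None:
            max_lag = min(x.size // 2 - 1, 100)
        _, tau = auto_mutual_information(x, max_lag=max_lag)
        candidates = [t for t in (tau, autocorrelation_time(x)) if t is not None]
        dim = None
        for tau_c in candidates:
            _, dim = false_nearest_neighbors(x, tau_c, params=fnn_params,
                                             theiler=theiler)
            if dim is not None:
                return EmbeddingSpec(dim, tau_c)
        raise ValueError("FNN fraction never dropped below threshold")
    if method == "stochastic":
        _, _, _, (dim, tau) = ragwitz_optimize(x, theiler=theiler, **ragwitz_kwargs)
        return EmbeddingSpec(dim, tau)
    raise ValueError(f"unknown optimization method: {method!r}")
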