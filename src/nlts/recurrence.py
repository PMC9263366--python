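"""Recurrence matrices, RQA measures, recurrence-time densities and the
spatially- (SREPS) and time-resolved (TRAS) recurrence period/amplitude
spectra.

A state recurs when the trajectory re-enters its epsilon-neighborhood; the
recurrence time T is the length of the gap between leaving and re-entering,
which equals the number of adjacent vertical zeros between recurrence blocks
in the binary recurrence matrix.  SREPS resolves the recurrence-period
probability P(T) over a grid of neighborhood sizes (in % of the series SD),
eliminating the epsilon choice; TRAS resolves it over sliding windows, and
both attach a recurrence amplitude - the mean maximum phase-space diameter of
the recurrent trajectory segments at each period, reported as half-diameter
so a sinusoid of amplitude a reads ~a.

Recurrence-time extraction streams over reference columns in chunks (never
materializing the full n x n matrix), and distances are computed once and
shared across the whole epsilon grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import _chebyshev_chunk
from .embedding import EmbeddingSpec, PhaseSpace, TimeSeries, _series, delay_embed

__all__ = [
    "RecurrenceMatrix",
    "RecurrencePeriodDensity",
    "RecurrenceSpectrum",
    "RqaMeasures",
    "recurrence_matrix",
    "cross_recurrence",
    "joint_recurrence",
    "rqa_measures",
    "recurrence_times",
    "recurrence_amplitude",
    "sreps",
    "tras",
    "dominant_period",
]


@dataclass
class RecurrenceMatrix:
    """Thresholded pairwise-distance matrix (binary)."""

    M: np.ndarray
    mode: str                       # "epsilon" or "rate"
    value: float                    # eps (data units) or target rate (%)
    norm: str = "maximum"
    theiler: int = 0
    radii: np.ndarray | None = None  # per-point radii in rate mode

    @property
    def recurrence_rate(self) -> float:
        return float(self.M.mean())


@dataclass
class RecurrencePeriodDensity:
    """Histogram R(T) and probability P(T) of recurrence times in [Tmin, Tmax]."""

    T: np.ndarray
    R: np.ndarray
    P: np.ndarray
    Tmin: int
    Tmax: int

    @property
    def empty(self) -> bool:
        return self.R.sum() == 0


@dataclass
class RecurrenceSpectrum:
    """P(T, .) resolved over spatial scales (SREPS) or time windows (TRAS)."""

    T: np.ndarray
    axis2: np.ndarray               # eps grid (% SD) or window start indices
    kind: str                       # "sreps" or "tras"
    P: np.ndarray                   # (n_T, n_axis2)
    R: np.ndarray
    amplitude: np.ndarray | None = None         # half-diameter convention
    weighted_amplitude: np.ndarray | None = None
    diameter: np.ndarray | None = None          # raw mean segment diameters


@dataclass
class RqaMeasures:
    recurrence_rate: float
    determinism: float
    laminarity: float
    rpde: float
    generalized_autocorrelation: np.ndarray


def _pairwise(a: np.ndarray, b: np.ndarray, norm: str) -> np.ndarray:
    if norm == "maximum":
        return _chebyshev_chunk(a, b)
    d = (a[:, None, 0] - b[None, :, 0]) ** 2
    for c in range(1, a.shape[1]):
        d += (a[:, None, c] - b[None, :, c]) ** 2
    return np.sqrt(d)


def recurrence_matrix(ps: PhaseSpace, mode: str = "epsilon", value: float = 5.0,
                      norm: str = "maximum", theiler: int = 0) -> RecurrenceMatrix:
    """Binary recurrence matrix of a phase-space trajectory.

    ``mode='epsilon'``: M[i, j] = 1 iff dist(x_i, x_j) <= value (symmetric,
    unit diagonal for theiler=0).  ``mode='rate'``: each point receives its
    own radius, the distance to its ceil(rate% of admissible partners)-th
    neighbor, so the realized fill rate matches the target.  Entries with
    ``|i-j| <= theiler`` are cleared (the self-diagonal survives only with
    theiler=0).
    """
    D = _pairwise(ps.states, ps.states, norm)
    n = D.shape[0]
    radii = None
    if mode == "epsilon":
        if value <= 0:
            raise ValueError("epsilon must be positive")
        M = D <= value
    elif mode == "rate":
        if not 0 < value <= 100:
            raise ValueError("rate must lie in (0, 100]")
        off = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        admissible = off > theiler
        n_adm = admissible.sum(axis=1)
        if np.any(value / 100.0 * n_adm < 1.0):
            raise ValueError("target rate below 1/(n-1): no neighbors per point")
        kth = np.ceil(value / 100.0 * n_adm).astype(int)
        radii = np.empty(n)
        Dm = np.where(admissible, D, np.inf)
        srt = np.sort(Dm, axis=1)
        radii = srt[np.arange(n), kth - 1]
        M = D <= radii[:, None]
    else:
        raise ValueError(f"unknown recurrence mode: {mode!r}")
    if theiler > 0:
        off = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        M = M & (off > theiler)
    return RecurrenceMatrix(M.astype(bool), mode, float(value), norm, theiler, radii)


def cross_recurrence(psA: PhaseSpace, psB: PhaseSpace, epsilon: float,
                     norm: str = "maximum") -> RecurrenceMatrix:
    """Cross-recurrence matrix: M[i, j] = 1 iff dist(a_i, b_j) <= epsilon."""
    if psA.dim != psB.dim:
        raise ValueError("cross recurrence needs equal embedding dimensions")
    D = _pairwise(psA.states, psB.states, norm)
    return RecurrenceMatrix(D <= epsilon, "epsilon", float(epsilon), norm, 0)


def joint_recurrence(psA: PhaseSpace, psB: PhaseSpace, epsilonA: float,
                     epsilonB: float | None = None, norm: str = "maximum",
                     theiler: int = 0) -> RecurrenceMatrix:
    """Joint recurrence: elementwise product of the two auto-recurrence matrices."""
    if psA.n_states != psB.n_states:
        raise ValueError("joint recurrence needs equal trajectory lengths")
    if epsilonB is None:
        epsilonB = epsilonA
    mA = recurrence_matrix(psA, "epsilon", epsilonA, norm, theiler)
    mB = recurrence_matrix(psB, "epsilon", epsilonB, norm, theiler)
    return RecurrenceMatrix(mA.M & mB.M, "epsilon", float(epsilonA), norm, theiler)


def _line_lengths(mask: np.ndarray) -> np.ndarray:
    """Run lengths of True values in a 1-D boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def rqa_measures(rm: RecurrenceMatrix, lmin: int = 2, vmin: int = 2,
                 Tmin: int = 1, Tmax: int | None = None) -> RqaMeasures:
    """Classic recurrence-quantification summary measures.

    DET is the fraction of recurrence points lying on diagonal lines of
    length >= lmin (main diagonal excluded), LAM the fraction on vertical
    lines of length >= vmin, RPDE the normalized entropy of the
    recurrence-period density, and the generalized autocorrelation the mean
    of the matrix along each diagonal offset.
    """
    M = rm.M
    n = M.shape[0]
    if not M.any():
        raise ValueError("empty recurrence matrix: measures undefined")
    total = int(M.sum())
    # Diagonal lines (offsets != 0).
    diag_points_in_lines = 0
    gacf = np.empty(n)
    for off in range(n):
        d = np.diagonal(M, offset=off)
        gacf[off] = d.mean()
        if off == 0:
            continue
        for dd in (d, np.diagonal(M, offset=-off)):
            lengths = _line_lengths(np.asarray(dd))
            diag_points_in_lines += int(lengths[lengths >= lmin].sum())
    off_diag_total = total - int(np.trace(M))
    det = diag_points_in_lines / off_diag_total if off_diag_total else 0.0
    # Vertical lines.
    vert_points = 0
    for j in range(n):
        lengths = _line_lengths(M[:, j])
        vert_points += int(lengths[lengths >= vmin].sum())
    lam = vert_points / total
    # RPDE from vertical zero-gaps.
    if Tmax is None:
        Tmax = n - 1
    dens = _density_from_matrix(M, Tmin, Tmax)
    nz = dens.P[dens.P > 0]
    n_T = dens.T.size
    rpde = float(-(nz * np.log(nz)).sum() / np.log(n_T)) if nz.size and n_T > 1 else 0.0
    return RqaMeasures(rm.recurrence_rate, float(det), float(lam), rpde, gacf)


def _runs_from_mask(mask: np.ndarray, Tmin: int, Tmax: int):
    """Vertical zero-gap runs for a chunk of reference columns.

    ``mask`` has shape (n_refs, n_states); for each reference row the gaps
    between consecutive recurrence entries are the recurrence times.
    Returns (T, seg_start, seg_end) arrays for gaps with Tmin <= T <= Tmax,
    where [seg_start, seg_end] are the bounding recurrent states of the
    excursion.
    """
    rows, cols = np.nonzero(mask)
    if rows.size < 2:
        return (np.empty(0, int),) * 3
    same = np.diff(rows) == 0
    gap = np.diff(cols) - 1
    sel = same & (gap >= max(Tmin, 1)) & (gap <= Tmax)
    starts = cols[:-1][sel]
    ends = cols[1:][sel]
    return gap[sel], starts, ends


def _segment_diameters(states_ext: np.ndarray, starts: np.ndarray,
                       ends: np.ndarray) -> np.ndarray:
    """Max-norm diameter of states[start..end] per segment, vectorized.

    ``states_ext`` must carry one sentinel row appended so that ``end + 1``
    is always a valid reduceat index.  Under the maximum norm the diameter
    of a set equals the widest per-coordinate range, so segment-wise
    max/min reduceat suffices.
    """
    idx = np.empty(2 * starts.size, dtype=np.intp)
    idx[0::2] = starts
    idx[1::2] = ends + 1
    hi = np.maximum.reduceat(states_ext, idx, axis=0)[0::2]
    lo = np.minimum.reduceat(states_ext, idx, axis=0)[0::2]
    return (hi - lo).max(axis=1)


def _density_from_matrix(M: np.ndarray, Tmin: int, Tmax: int) -> RecurrencePeriodDensity:
    T_gaps, _, _ = _runs_from_mask(M.T, Tmin, Tmax)  # columns as references
    Ts = np.arange(Tmin, Tmax + 1)
    R = np.bincount(T_gaps - Tmin, minlength=Ts.size) if T_gaps.size else np.zeros(Ts.size, int)
    tot = R.sum()
    P = R / tot if tot else np.zeros_like(R, dtype=float)
    return RecurrencePeriodDensity(Ts, R.astype(int), P, Tmin, Tmax)


def recurrence_times(ps: PhaseSpace, epsilon: float, Tmin: int = 1,
                     Tmax: int | None = None, theiler: int = 0,
                     norm: str = "maximum", chunk: int = 1024,
                     with_amplitudes: bool = False):
    """Recurrence-time density P(T) of a trajectory at neighborhood size epsilon.

    For each reference state the gaps between successive recurrences into its
    epsilon-neighborhood (vertical zero-runs of the recurrence matrix) are
    histogrammed at one-sample resolution over [Tmin, Tmax].  Computed per
    reference column in chunks; the full matrix is never built.  With
    ``with_amplitudes=True`` the per-period mean segment diameter is also
    returned (see :func:`recurrence_amplitude`).
    """
    n = ps.n_states
    if Tmax is None:
        Tmax = n - 1
    if Tmin < 1 or Tmax >= n:
        raise ValueError("need 1 <= Tmin and Tmax < n_states")
    states = ps.states
    ext = np.vstack([states, states[-1:]])
    Ts = np.arange(Tmin, Tmax + 1)
    R = np.zeros(Ts.size, dtype=np.int64)
    diam_sum = np.zeros(Ts.size)
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        D = _pairwise(states[start:stop], states, norm)
        mask = D <= epsilon
        if theiler > 0:
            off = np.abs(np.arange(start, stop)[:, None] - np.arange(n)[None, :])
            mask &= off > theiler
        T_gaps, seg_s, seg_e = _runs_from_mask(mask, Tmin, Tmax)
        if T_gaps.size:
            R += np.bincount(T_gaps - Tmin, minlength=Ts.size)
            if with_amplitudes:
                d = _segment_diameters(ext, seg_s, seg_e)
                np.add.at(diam_sum, T_gaps - Tmin, d)
    tot = R.sum()
    P = R / tot if tot else np.zeros_like(R, dtype=float)
    dens = RecurrencePeriodDensity(Ts, R.astype(int), P, Tmin, Tmax)
    if not with_amplitudes:
        return dens
    with np.errstate(invalid="ignore"):
        mean_diam = np.where(R > 0, diam_sum / np.maximum(R, 1), 0.0)
    return dens, mean_diam


def recurrence_amplitude(ps: PhaseSpace, epsilon: float, Tmin: int = 1,
                         Tmax: int | None = None, theiler: int = 0,
                         norm: str = "maximum"):
    """Recurrence amplitude spectrum a(T) and its probability-weighted form.

    For every recurrence of period T the maximum phase-space diameter of its
    trajectory segment (between leaving and re-entering the neighborhood,
    endpoints included) is taken; a(T) averages these over the recurrences at
    that T and is reported under the half-diameter convention, so a sinusoid
    of amplitude a yields a(T) ~ a at its period.  The weighted spectrum
    a(T) * P(T) suppresses rare large-excursion periods.  Raw mean diameters
    are returned alongside.
    """
    dens, mean_diam = recurrence_times(ps, epsilon, Tmin, Tmax, theiler, norm,
                                       with_amplitudes=True)
    amp = 0.5 * mean_diam
    return dens, amp, amp * dens.P, mean_diam


def sreps(ts: TimeSeries | np.ndarray, spec: EmbeddingSpec,
          eps_grid: np.ndarray | None = None, Tmin: int = 1,
          Tmax: int | None = None, theiler: int = 0, norm: str = "maximum",
          chunk: int = 1024, with_amplitudes: bool = True) -> RecurrenceSpectrum:
    """Spatially-resolved recurrence period spectrum P(T, eps).

    The recurrence-time density is evaluated over a grid of neighborhood
    sizes expressed in percent of the series SD (default 1..100% in steps of
    1), normalizing each eps column separately.  Distances are computed once
    per reference chunk and reused for the entire grid.  For an oscillatory
    series the spectrum shows a noise-dominated regime at small eps, a
    continuous band whose crossing with that regime marks the true recurrence
    period, and a drift toward small T as eps engulfs the attractor.
    """
    x = _series(ts)
    ps = delay_embed(x, spec, fs=ts.fs if isinstance(ts, TimeSeries) else None)
    sd = float(np.std(x))
    if eps_grid is None:
        eps_grid = np.arange(1.0, 101.0)
    eps_grid = np.asarray(eps_grid, dtype=float)
    eps_abs = eps_grid / 100.0 * sd
    order = np.argsort(eps_abs)
    n = ps.n_states
    if Tmax is None:
        Tmax = n - 1
    Ts = np.arange(Tmin, Tmax + 1)
    R = np.zeros((Ts.size, eps_grid.size), dtype=np.int64)
    diam_sum = np.zeros((Ts.size, eps_grid.size))
    states = ps.states
    ext = np.vstack([states, states[-1:]])
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        D = _pairwise(states[start:stop], states, norm)
        if theiler > 0:
            off = np.abs(np.arange(start, stop)[:, None] - np.arange(n)[None, :])
            D[off <= theiler] = np.inf
        for gi in order:
            mask = D <= eps_abs[gi]
            T_gaps, seg_s, seg_e = _runs_from_mask(mask, Tmin, Tmax)
            if T_gaps.size:
                R[:, gi] += np.bincount(T_gaps - Tmin, minlength=Ts.size)
                if with_amplitudes:
                    d = _segment_diameters(ext, seg_s, seg_e)
                    np.add.at(diam_sum[:, gi], T_gaps - Tmin, d)
    totals = R.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, R / np.maximum(totals, 1), 0.0)
        mean_diam = np.where(R > 0, diam_sum / np.maximum(R, 1), 0.0)
    amp = 0.5 * mean_diam if with_amplitudes else None
    return RecurrenceSpectrum(Ts, eps_grid, "sreps", P, R,
                              amplitude=amp,
                              weighted_amplitude=None if amp is None else amp * P,
                              diameter=mean_diam if with_amplitudes else None)


def tras(ts: TimeSeries | np.ndarray, spec: EmbeddingSpec, epsilon_pct: float,
         window_len: int | None = None, overlap: float = 0.5, Tmin: int = 1,
         Tmax: int | None = None, theiler: int = 0, norm: str = "maximum",
         with_amplitudes: bool = True) -> RecurrenceSpectrum:
    """Time-resolved recurrence amplitude spectrum P(T, window).

    The series is cut into windows of ``window_len`` samples (default one
    tenth of the data) hopping by ``window_len * (1 - overlap)``; each window
    is embedded and its recurrence-time density computed at a fixed
    neighborhood size ``epsilon_pct`` (% of the SD of the whole analyzed
    series).  Because recurrence times ignore waveform shape, non-sinusoidal
    oscillations produce a single fundamental band without the harmonics a
    short-time Fourier transform would show.
    """
    x = _series(ts)
    N = x.size
    if window_len is None:
        window_len = N // 10
    if window_len > N:
        raise ValueError("window_len exceeds the data length")
    need = (spec.dim - 1) * spec.tau + 2
    if window_len < need:
        raise ValueError(
            f"window of {window_len} samples is too short to embed with "
            f"dim={spec.dim}, tau={spec.tau}")
    hop = max(1, int(round(window_len * (1.0 - overlap))))
    n_win = (N - window_len) // hop + 1
    states_per_win = window_len - (spec.dim - 1) * spec.tau
    if Tmax is None:
        Tmax = states_per_win - 1
    if Tmax >= states_per_win:
        raise ValueError("Tmax must be below the states per window")
    sd = float(np.std(x))
    eps_abs = epsilon_pct / 100.0 * sd
    Ts = np.arange(Tmin, Tmax + 1)
    R = np.zeros((Ts.size, n_win), dtype=np.int64)
    P = np.zeros((Ts.size, n_win))
    diam = np.zeros((Ts.size, n_win))
    starts = np.arange(n_win) * hop
    for wi, s0 in enumerate(starts):
        seg = x[s0: s0 + window_len]
        ps = delay_embed(seg, spec)
        if with_amplitudes:
            dens, mean_diam = recurrence_times(ps, eps_abs, Tmin, Tmax, theiler,
                                               norm, with_amplitudes=True)
            diam[:, wi] = mean_diam
        else:
            dens = recurrence_times(ps, eps_abs, Tmin, Tmax, theiler, norm)
        R[:, wi] = dens.R
        P[:, wi] = dens.P
    amp = 0.5 * diam if with_amplitudes else None
    return RecurrenceSpectrum(Ts, starts, "tras", P, R,
                              amplitude=amp,
                              weighted_amplitude=None if amp is None else amp * P,
                              diameter=diam if with_amplitudes else None)


def dominant_period(spectrum: RecurrenceSpectrum, min_recurrences: int = 50,
                    min_count_frac: float = 0.01, peak_factor: float = 5.0,
                    rel_height: float = 0.3):
    """Fundamental recurrence period of a spectrum's dominant band.

    Scanning the spatial scales from small to large, the first column with a
    meaningful number of recurrences (at least ``min_recurrences`` and
    ``min_count_frac`` of the best-filled column) whose peak probability
    exceeds ``peak_factor`` times the uniform level marks the crossing of
    the band with the small-eps noise regime - the best period estimate.
    Within that column the fundamental is the smallest-T local peak reaching
    ``rel_height`` of the column maximum, so combs of period multiples
    (returns that skip one or more cycles) resolve to their base period.

    Returns ``(T_fundamental, column_index)``.
    """
    n_T = spectrum.T.size
    uniform = 1.0 / n_T
    totals = spectrum.R.sum(axis=0)
    floor = max(min_recurrences, min_count_frac * totals.max())
    for gi in range(spectrum.axis2.size):
        col = spectrum.P[:, gi]
        if totals[gi] < floor:
            continue
        if col.max() < peak_factor * uniform:
            continue
        thresh = rel_height * col.max()
        for ti in range(n_T):
            left = col[ti - 1] if ti > 0 else -np.inf
            right = col[ti + 1] if ti < n_T - 1 else -np.inf
            if col[ti] >= thresh and col[ti] >= left and col[ti] >= right:
                return int(spectrum.T[ti]), gi
    raise ValueError("no column rises above the noise regime")
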