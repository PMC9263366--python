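"""Entropy, mutual information and active information storage.

Two estimator families are provided throughout: plug-in estimates on
equal-width bins (with a Freedman-Diaconis automatic bin choice and an
optional differential-entropy correction) and nearest-neighbor estimators
(Kozachenko-Leonenko for differential entropy, Kraskov-Stoegbauer-Grassberger
algorithm 1 for mutual information).  All values are reported in bits, and
every estimator also exposes a *local* (per-sample) variant whose mean equals
the global estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .embedding import EmbeddingSpec, TimeSeries, delay_embed

__all__ = [
    "InfoEstimate",
    "freedman_diaconis_bins",
    "entropy_binned",
    "entropy_knn",
    "mutual_information",
    "active_information_storage",
]

_LN2 = np.log(2.0)


@dataclass
class InfoEstimate:
    """A (global, local) information estimate in bits."""

    value: float
    local: np.ndarray | None = None
    estimator: str = "binned"
    params: dict = field(default_factory=dict)
    base: float = 2.0


def _arr(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    return np.asarray(x, dtype=float)


def freedman_diaconis_bins(x) -> int:
    """Freedman-Diaconis bin count: width 2*IQR*n^(-1/3), count ceil(range/width).

    Falls back to a Sturges-like rule (with a warning) when the IQR is zero.
    """
    x = _arr(x)
    n = x.size
    rng = float(np.ptp(x))
    if rng == 0.0:
        raise ValueError("constant data: binning undefined (zero range)")
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr == 0.0:
        warnings.warn("zero IQR; falling back to a Sturges-like bin count",
                      RuntimeWarning, stacklevel=2)
        return int(np.ceil(np.log2(n))) + 1
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    return max(2, int(np.ceil(rng / width)))


def _bin_edges(x: np.ndarray, bins) -> np.ndarray:
    if isinstance(bins, np.ndarray):
        return bins
    if bins == "auto":
        bins = freedman_diaconis_bins(x)
    bins = int(bins)
    if bins < 2:
        raise ValueError("at least 2 bins are required")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("constant data: binning undefined (zero range)")
    return np.linspace(lo, hi, bins + 1)


def _digitize(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def _discrete_mi_local(labels_x: np.ndarray, labels_y: np.ndarray):
    """Plug-in MI (bits) of two integer label sequences, with local values."""
    n = labels_x.size
    _, ix, cx = np.unique(labels_x, return_inverse=True, return_counts=True)
    _, iy, cy = np.unique(labels_y, return_inverse=True, return_counts=True)
    joint = np.stack([ix, iy], axis=1)
    _, ij, cj = np.unique(joint, axis=0, return_inverse=True, return_counts=True)
    local = (np.log2(cj[ij] / n) - np.log2(cx[ix] / n) - np.log2(cy[iy] / n))
    return float(local.mean()), local


def entropy_binned(x, bins="auto", differential: bool = False) -> InfoEstimate:
    """Plug-in Shannon entropy over equal-width bins, in bits.

    With ``differential=True`` the estimate is corrected by +log2(bin width)
    so it approximates the differential entropy of a continuous variable.
    Local values are the per-sample surprisals -log2 p(bin(x_i)).
    """
    x = _arr(x)
    edges = _bin_edges(x, bins)
    idx = _digitize(x, edges)
    counts = np.bincount(idx, minlength=edges.size - 1)
    p = counts / x.size
    local = -np.log2(p[idx])
    correction = 0.0
    if differential:
        correction = float(np.log2(edges[1] - edges[0]))
        local = local + correction
    return InfoEstimate(float(local.mean()), local, "binned",
                        {"bins": edges.size - 1, "differential": differential})


def _kth_distance(pts: np.ndarray, k: int, jitter_seed: int | None = 0):
    """Max-norm distance to each point's k-th neighbor (self excluded)."""
    n = pts.shape[0]
    if n <= k:
        raise ValueError("need more samples than neighbors")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    r = dist[:, -1]
    if np.any(r == 0.0):
        if jitter_seed is None:
            raise ValueError("duplicate points make the k-th distance zero")
        scale = 1e-10 * max(float(np.ptp(pts)), 1.0)
        rng = np.random.default_rng(jitter_seed)
        pts = pts + scale * rng.standard_normal(pts.shape)
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=k + 1, p=np.inf)
        r = dist[:, -1]
    return r, pts


def entropy_knn(x, k: int = 4, jitter_seed: int | None = 0) -> InfoEstimate:
    """Kozachenko-Leonenko differential entropy (bits) via k-th neighbor distances.

    Works for scalar series or (n, d) state arrays; the maximum norm is used,
    for which the d-ball of radius r has volume (2r)^d.  Exact duplicates are
    broken by an infinitesimal deterministic jitter (set ``jitter_seed=None``
    to make duplicates an error instead).
    """
    pts = _arr(x)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    r, _ = _kth_distance(pts, k, jitter_seed)
    local_nats = digamma(n) - digamma(k) + d * np.log(2.0 * r)
    local = local_nats / _LN2
    return InfoEstimate(float(local.mean()), local, "knn", {"k": k})


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int, jitter_seed: int | None):
    """KSG algorithm-1 mutual information (nats -> bits), with local values."""
    n = x.shape[0]
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    z = np.hstack([x, y])
    r, z = _kth_distance(z, k, jitter_seed)
    x = z[:, : x.shape[1]]
    y = z[:, x.shape[1]:]
    tree_x = cKDTree(x)
    tree_y = cKDTree(y)
    # Strictly-less-than counts, excluding the point itself.
    eps = np.nextafter(r, 0.0)
    nx = np.array(tree_x.query_ball_point(x, eps, p=np.inf, return_length=True)) - 1
    ny = np.array(tree_y.query_ball_point(y, eps, p=np.inf, return_length=True)) - 1
    local_nats = (digamma(k) + digamma(n)
                  - digamma(nx + 1) - digamma(ny + 1))
    local = local_nats / _LN2
    return float(local.mean()), local


def mutual_information(x, y, estimator: str = "binned", bins="auto",
                       k: int = 4, jitter_seed: int | None = 0) -> InfoEstimate:
    """Mutual information I(X;Y) in bits.

    ``estimator='binned'`` evaluates H(X)+H(Y)-H(X,Y) on an equal-width 2-D
    grid (``bins`` may be a count, 'auto', or an explicit edge array shared
    by both margins); ``estimator='ksg'`` uses the Kraskov et al. k-NN
    estimator (algorithm 1, maximum norm).
    """
    xv, yv = _arr(x), _arr(y)
    if xv.ndim == 1 and yv.ndim == 1 and xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if estimator == "binned":
        ex = _bin_edges(xv, bins)
        ey = _bin_edges(yv, bins)
        lx = _digitize(xv, ex)
        ly = _digitize(yv, ey)
        value, local = _discrete_mi_local(lx, ly)
        return InfoEstimate(value, local, "binned", {"bins": ex.size - 1})
    if estimator == "ksg":
        value, local = _ksg_mi(np.asarray(xv, float), np.asarray(yv, float),
                               k, jitter_seed)
        return InfoEstimate(value, local, "ksg", {"k": k})
    raise ValueError(f"unknown MI estimator: {estimator!r}")


def active_information_storage(ts, history: EmbeddingSpec | None = None,
                               estimator: str = "binned", bins="auto",
                               k: int = 4, jitter_seed: int | None = 0
                               ) -> InfoEstimate:
    """Active information storage: MI between the embedded past and the next sample.

    The past state at time t is the delay embedding
    ``(x[t-(d-1)tau], ..., x[t])``; AIS measures how much of the next
    sample's information is predictable from it.  Local AIS values are
    time-resolved (one per prediction) and average to the global value.
    """
    x = _arr(ts)
    if history is None:
        history = EmbeddingSpec(1, 1)
    ps = delay_embed(x, history)
    past = ps.states[:-1]
    offset = (history.dim - 1) * history.tau
    nxt = x[offset + 1:]
    if estimator == "binned":
        edges = _bin_edges(x, bins)
        lab_next = _digitize(nxt, edges)
        dig = _digitize(past.ravel(), edges).reshape(past.shape)
        # Encode each past state as a single integer label.
        nb = edges.size - 1
        lab_past = np.zeros(past.shape[0], dtype=np.int64)
        for c in range(past.shape[1]):
            lab_past = lab_past * nb + dig[:, c]
        value, local = _discrete_mi_local(lab_past, lab_next)
        return InfoEstimate(value, local, "binned", {"bins": nb, "history": history})
    if estimator in ("ksg", "knn"):
        value, local = _ksg_mi(past, np.asarray(nxt, float), k, jitter_seed)
        return InfoEstimate(value, local, "ksg", {"k": k, "history": history})
    raise ValueError(f"unknown AIS estimator: {estimator!r}")
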