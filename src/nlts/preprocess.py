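"""Preprocessing chain and plain-text file IO.

Preprocessing applies, in a fixed order, windowing, linear detrending,
optional zero-phase Butterworth filtering, and z-score normalization.
Normalization comes last so that neighborhood sizes expressed in percent of
the SD of the analyzed series refer to the post-filtering signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .embedding import TimeSeries

__all__ = [
    "ButterworthSpec",
    "PreprocessConfig",
    "preprocess",
    "read_timeseries",
    "write_results",
]


@dataclass
class ButterworthSpec:
    """Butterworth filter: order, cutoff(s) in Hz, type, bidirectional flag."""

    order: int = 4
    cutoff: float | tuple[float, float] = 20.0
    btype: str = "highpass"           # lowpass | highpass | bandpass | bandstop
    bidirectional: bool = True


@dataclass
class PreprocessConfig:
    window: tuple[float, float] | None = None   # seconds if fs known, else samples
    detrend: str = "none"                       # none | linear
    filter: ButterworthSpec | None = None
    normalize: str = "none"                     # none | zscore


def preprocess(ts: TimeSeries, cfg: PreprocessConfig) -> TimeSeries:
    """Apply the chain window -> detrend -> filter -> normalize.

    Bidirectional filtering (forward-backward) has zero phase shift.  Filter
    cutoffs at or above the Nyquist frequency are an error.
    """
    x = ts.values.copy()
    fs = ts.fs
    steps = []
    if cfg.window is not None:
        lo, hi = cfg.window
        if fs is not None:
            lo, hi = int(round(lo * fs)), int(round(hi * fs))
        else:
            lo, hi = int(lo), int(hi)
        if not 0 <= lo < hi <= x.size:
            raise ValueError("window outside the data extent")
        x = x[lo:hi]
        steps.append(f"window[{lo}:{hi}]")
    if cfg.detrend == "linear":
        x = _sig.detrend(x, type="linear")
        steps.append("detrend:linear")
    elif cfg.detrend != "none":
        raise ValueError(f"unknown detrend mode: {cfg.detrend!r}")
    if cfg.filter is not None:
        if fs is None:
            raise ValueError("filtering requires a sampling rate")
        spec = cfg.filter
        wn = np.atleast_1d(np.asarray(spec.cutoff, dtype=float))
        if np.any(wn >= fs / 2):
            raise ValueError("filter cutoff must be below the Nyquist frequency")
        sos = _sig.butter(spec.order, wn if wn.size > 1 else wn[0],
                          btype=spec.btype, fs=fs, output="sos")
        x = _sig.sosfiltfilt(sos, x) if spec.bidirectional else _sig.sosfilt(sos, x)
        steps.append(f"butter:{spec.btype}:{spec.order}@{spec.cutoff}"
                     + (":bidir" if spec.bidirectional else ""))
    if cfg.normalize == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValueError("constant signal cannot be z-scored")
        x = (x - x.mean()) / sd
        steps.append("zscore")
    elif cfg.normalize != "none":
        raise ValueError(f"unknown normalize mode: {cfg.normalize!r}")
    label = ts.label + ("|" + ",".join(steps) if steps else "")
    return TimeSeries(x, fs=fs, label=label)


def read_timeseries(path, fmt: str | None = None, fs: float | None = None,
                    channels=None) -> list[TimeSeries]:
    """Read one TimeSeries per numeric column from a CSV/TSV/whitespace file.

    A header row is auto-detected and used for channel labels.  Non-numeric
    cells raise a ``ValueError`` naming the offending row and column; ragged
    rows are also an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv"}.get(path.suffix.lower(), "plain")
    sep = {"csv": ",", "tsv": "\t", "plain": r"\s+"}[fmt]
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                          skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc

    def _numeric_row(row) -> bool:
        try:
            [float(v) for v in row]
            return True
        except (TypeError, ValueError):
            return False

    labels = None
    start = 0
    if not _numeric_row(raw.iloc[0]):
        labels = [str(v) for v in raw.iloc[0]]
        start = 1
    data = raw.iloc[start:].reset_index(drop=True)
    values = data.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = np.argwhere(values.isna().to_numpy() & ~data.isna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-numeric cell at row {r + start}, column {c} in {path}")
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {r + start}, column {c} in {path}")
    # numpy's parser is correctly rounded (full round-trip precision)
    arr = data.to_numpy(dtype=str).astype(np.float64)
    if channels is not None:
        arr = arr[:, list(channels)]
        if labels is not None:
            labels = [labels[c] for c in channels]
    out = []
    for c in range(arr.shape[1]):
        lbl = labels[c] if labels is not None else f"ch{c}"
        out.append(TimeSeries(arr[:, c], fs=fs, label=lbl))
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_results(path, results: dict) -> None:
    """Write a results mapping to JSON (scalars and arrays) at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, cls=_NumpyEncoder, indent=2)


def write_series(path, series: list[TimeSeries], fmt: str = "csv") -> None:
    """Write channels column-wise with a header of labels (full precision)."""
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    df = pd.DataFrame({(s.label or f"ch{i}"): s.values
                       for i, s in enumerate(series)})
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
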