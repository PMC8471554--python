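"""Pairwise time-domain Granger causality from multichannel time series.

For each ordered channel pair (i -> j) two nested autoregressions of channel
j are fitted by ordinary least squares: a restricted model on j's own p lags
and a full model adding p lags of channel i. The GC magnitude is the Geweke
log variance ratio ln(RSS_restricted / RSS_full) >= 0 and the edge's F
statistic is

    F = ((RSS_r - RSS_f) / p) / (RSS_f / (T_eff - 2p - 1)),   T_eff = T - p,

with (p, T_eff - 2p - 1) degrees of freedom. Edges failing the F critical
value at the chosen level are zeroed out, leaving a sparse GC map.

Scope notes: this is bivariate (pairwise) GC, not conditional multivariate
GC — each pair is tested in isolation. Channels are mean-centred before
fitting; no other preprocessing is applied. Multiple-comparison correction
is off by default (per-edge alpha), with Bonferroni available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import f as f_dist

from .gcmap import DataError, FormatError, GCMap

__all__ = [
    "Segment",
    "GCResult",
    "pairwise_gc",
    "significance_filter",
    "select_order",
    "load_segment",
    "save_segment",
]

_RSS_FLOOR = 1e-300  # treat smaller residual sums as numerically singular


@dataclass
class Segment:
    """C x T multichannel recording (C channels, T samples)."""

    data: np.ndarray
    labels: list[str]
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise FormatError(f"segment data must be 2-D, got shape {d.shape}")
        if np.isnan(d).any():
            raise DataError("segment contains NaN samples")
        labels = [str(x) for x in self.labels]
        if len(labels) != d.shape[0]:
            raise FormatError(f"{len(labels)} labels for {d.shape[0]} channels")
        if len(set(labels)) != len(labels):
            raise FormatError("channel labels must be unique")
        self.data = d
        self.labels = labels

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GCResult:
    """Dense pairwise GC magnitudes and F statistics for one segment."""

    gc: np.ndarray
    fstat: np.ndarray
    dof: tuple[int, int]
    order: int
    labels: list[str]


def _lag_matrix(x: np.ndarray, p: int) -> np.ndarray:
    """(T-p) x p design of lags 1..p of a 1-D series."""
    T = x.size
    return np.column_stack([x[p - lag : T - lag] for lag in range(1, p + 1)])


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def pairwise_gc(seg: Segment, order: int = 10) -> GCResult:
    """All ordered-pair GC magnitudes and F statistics at VAR order ``order``.

    Requires ``T > 3 * order + 1`` so the denominator degrees of freedom are
    positive. Numerically singular pairs (e.g. a constant channel) are set to
    gc = fstat = 0 with a warning rather than raising.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    C, T = seg.n_channels, seg.n_samples
    if T <= 3 * order + 1:
        raise ValueError(
            f"need T > 3*order + 1 samples (got T={T}, order={order})"
        )
    p = order
    data = seg.data - seg.data.mean(axis=1, keepdims=True)
    lags = [_lag_matrix(data[c], p) for c in range(C)]
    targets = [data[c][p:] for c in range(C)]
    dof = (p, (T - p) - 2 * p - 1)

    gc = np.zeros((C, C))
    fstat = np.zeros((C, C))
    degenerate = []
    for j in range(C):
        rss_r, rank_r = _rss(lags[j], targets[j])
        for i in range(C):
            if i == j:
                continue
            X_full = np.hstack([lags[j], lags[i]])
            rss_f, rank_f = _rss(X_full, targets[j])
            if rss_f <= _RSS_FLOOR or rss_r <= _RSS_FLOOR or rank_f < 2 * p:
                degenerate.append((seg.labels[i], seg.labels[j]))
                continue
            gc[i, j] = max(np.log(rss_r / rss_f), 0.0)
            fstat[i, j] = max(((rss_r - rss_f) / p) / (rss_f / dof[1]), 0.0)
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} channel pair(s) were numerically singular and "
            f"set to zero GC (first: {degenerate[0]})",
            RuntimeWarning,
            stacklevel=2,
        )
    return GCResult(gc, fstat, dof, p, list(seg.labels))


def significance_filter(
    res: GCResult, alpha: float = 0.05, *, bonferroni: bool = False
) -> GCMap:
    """Zero out edges whose F statistic misses the critical value at ``alpha``.

    Surviving edges keep their GC magnitude as weight. With ``bonferroni``
    the per-edge level is alpha / (N(N-1)).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n = res.gc.shape[0]
    level = alpha / (n * (n - 1)) if bonferroni and n > 1 else alpha
    crit = f_dist.ppf(1.0 - level, *res.dof)
    weights = np.where(res.fstat > crit, res.gc, 0.0)
    np.fill_diagonal(weights, 0.0)
    return GCMap(weights, list(res.labels))


def select_order(seg: Segment, max_order: int = 20) -> int:
    """AIC-minimizing VAR order over 1..max_order (summed univariate AR fits)."""
    C, T = seg.n_channels, seg.n_samples
    data = seg.data - seg.data.mean(axis=1, keepdims=True)
    best_order, best_aic = 1, np.inf
    for p in range(1, max_order + 1):
        if T <= 3 * p + 1:
            break
        t_eff = T - p
        aic = 0.0
        for c in range(C):
            rss, _ = _rss(_lag_matrix(data[c], p), data[c][p:])
            aic += t_eff * np.log(max(rss, _RSS_FLOOR) / t_eff) + 2 * p
        if aic < best_aic:
            best_order, best_aic = p, aic
    return best_order


def load_segment(path: str | Path, sample_rate: float | None = None) -> Segment:
    """Read a segment CSV: channels as columns, header row of channel labels."""
    lines = [ln for ln in Path(path).read_text().strip().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: segment file needs a header and data rows")
    delim = "\t" if "\t" in lines[0] else ","
    labels = [tok.strip() for tok in lines[0].split(delim)]
    try:
        rows = [[float(tok) for tok in ln.split(delim)] for ln in lines[1:]]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample ({exc})") from exc
    data = np.array(rows, dtype=float).T  # stored samples-as-rows -> C x T
    return Segment(data, labels, sample_rate)


def save_segment(seg: Segment, path: str | Path) -> None:
    """Write a segment CSV (channels as columns, header of labels)."""
    out = [",".join(seg.labels)]
    for row in seg.data.T:
        out.append(",".join(f"{x:.17g}" for x in row))
    Path(path).write_text("\n".join(out) + "\n")
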