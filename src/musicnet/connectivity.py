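"""Static and dynamic functional-connectivity construction from ROI time series.

The static path mirrors the standard weighted-network recipe: pairwise Pearson
correlation over the full run, per-edge significance tests (t with T-2 df)
with Benjamini-Hochberg FDR across the N(N-1)/2 unique edges, zeroing of
non-surviving and negative edges, and optional binarization for degree.

The dynamic path slides a fixed-length rectangular window (default 60 s) in
steps of one TR across each run separately and vectorizes the upper triangle
of each windowed correlation matrix (row-major order, diagonal excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "WindowSeries",
    "static_fc",
    "edge_significance_filter",
    "zero_negatives",
    "binarize",
    "sliding_window_fc",
    "vectorize_upper",
    "devectorize_upper",
    "read_roi_tsv",
    "write_matrix_tsv",
]


@dataclass
class RoiTimeSeries:
    """T x N matrix of parcel signals with its sampling interval."""

    values: np.ndarray
    tr_seconds: float
    parcel_names: list[str] | None = None
    subject_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("time series must be T x N with T >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.parcel_names is None:
            self.parcel_names = [f"parcel_{i}" for i in range(self.values.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    weights: np.ndarray
    kind: str  # raw_pearson | fdr_thresholded | nonnegative | binary
    n_timepoints_used: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.weights = W

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]


@dataclass
class WindowSeries:
    """Edge-vectorized sliding-window correlations for one subject x condition."""

    windows: np.ndarray  # W x E, E = N(N-1)/2 upper triangle, row-major
    window_start_index: np.ndarray  # sample index of each window start
    window_length_samples: int
    step_samples: int
    tr_seconds: float
    n_parcels: int
    subject_id: str | None = None
    condition: str | None = None

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def window_center_seconds(self) -> np.ndarray:
        """Time of each window's center from run start (for segment mapping)."""
        centers = self.window_start_index + (self.window_length_samples - 1) / 2.0
        return centers * self.tr_seconds


def vectorize_upper(W: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (diagonal excluded) edge vector."""
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    return W[iu]


def devectorize_upper(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix, zero diagonal."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    W[iu] = v
    return W + W.T


def _corr_zero_variance_safe(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    sd = X.std(axis=0)
    flagged = np.nonzero(sd == 0)[0].tolist()
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 0.0)
    return R, flagged


def static_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Full-run pairwise Pearson correlation matrix, diagonal zeroed."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for static FC")
    R, flagged = _corr_zero_variance_safe(ts.values)
    flags = [f"zero_variance_parcel:{i}" for i in flagged]
    return ConnectivityMatrix(R, "raw_pearson", ts.n_timepoints, flags=flags)


def correlation_pvalues(R: np.ndarray, T: int) -> np.ndarray:
    """Two-sided p for each correlation against 0, t with T-2 df.

    |r| = 1 maps to p = 0 (the edge is always retained).
    """
    r = np.clip(R, -1.0, 1.0)
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    t = np.zeros_like(r)
    t[interior] = r[interior] * np.sqrt((T - 2) / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t[interior]), df=T - 2)
    return p


def edge_significance_filter(
    fc: ConnectivityMatrix, q: float = 0.05
) -> ConnectivityMatrix:
    """Per-edge t-tests against zero with BH-FDR across all unique edges.

    Non-surviving edges are zeroed; survivors keep their (signed) weight.
    """
    if fc.kind != "raw_pearson":
        raise ValueError("significance filter applies to raw Pearson matrices")
    T = fc.n_timepoints_used
    n = fc.n_parcels
    p_edges = vectorize_upper(correlation_pvalues(fc.weights, T))
    from .groupstats import bh_fdr  # local import to avoid cycle

    _, survives = bh_fdr(p_edges, q=q)
    w = vectorize_upper(fc.weights) * survives
    return ConnectivityMatrix(
        devectorize_upper(w, n), "fdr_thresholded", T, flags=list(fc.flags)
    )


def zero_negatives(fc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise max(w, 0) — the standard prerequisite for Q and efficiency."""
    return ConnectivityMatrix(
        np.maximum(fc.weights, 0.0), "nonnegative", fc.n_timepoints_used,
        flags=list(fc.flags),
    )


def binarize(fc: ConnectivityMatrix) -> ConnectivityMatrix:
    """1 where weight > 0, else 0 (degree ignores weights)."""
    if fc.weights.min() < 0:
        raise ValueError("binarize expects a non-negative matrix")
    return ConnectivityMatrix(
        (fc.weights > 0).astype(float), "binary", fc.n_timepoints_used,
        flags=list(fc.flags),
    )


def sliding_window_fc(
    ts: RoiTimeSeries, window_s: float = 60.0, step_tr: int = 1
) -> WindowSeries:
    """Sliding-window Pearson correlation, one edge vector per window.

    Windows never span run boundaries: this operates on a single run; pool
    the resulting WindowSeries across runs/conditions afterwards.
    """
    L = int(round(window_s / ts.tr_seconds))
    if L < 3:
        raise ValueError("window too short for correlation")
    T = ts.n_timepoints
    if T < L:
        raise ValueError(f"series length {T} shorter than window {L}")
    starts = np.arange(0, T - L + 1, step_tr)
    E = ts.n_parcels * (ts.n_parcels - 1) // 2
    out = np.empty((len(starts), E))
    for w, s0 in enumerate(starts):
        R, _ = _corr_zero_variance_safe(ts.values[s0 : s0 + L])
        out[w] = vectorize_upper(R)
    return WindowSeries(
        windows=out,
        window_start_index=starts,
        window_length_samples=L,
        step_samples=step_tr,
        tr_seconds=ts.tr_seconds,
        n_parcels=ts.n_parcels,
        subject_id=ts.subject_id,
        condition=ts.condition,
    )


def read_roi_tsv(path, tr_seconds: float, subject_id=None, condition=None) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        df.to_numpy(float), tr_seconds, list(df.columns), subject_id, condition
    )


def write_matrix_tsv(path, W: np.ndarray, names: list[str] | None = None) -> None:
    n = W.shape[0]
    names = names or [f"parcel_{i}" for i in range(n)]
    pd.DataFrame(W, index=names, columns=names).to_csv(path, sep="\t")
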