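"""Recurring dynamic-connectivity brain states via k-means.

Sliding-window edge vectors pooled over all subjects and both listening
conditions are clustered with k-means (squared Euclidean distance on raw edge
vectors).  The number of states is selected by the convergence of four
validity indices — an elbow criterion on within-cluster squared distance,
mean silhouette, Calinski-Harabasz, and Davies-Bouldin — combined by majority
vote (ties to the smallest k).

States are canonically ordered: state 0 is the centroid with the higher
modularity after negative-zeroing, so "state 0 = segregated, state 1 =
integrated" holds across runs.  Downstream metrics: per-subject state
frequency, per-state window-averaged graph summaries, 60-s segment dominance,
and the Pearson correlation between segment-wise audio entropy and
modular-state occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from . import graphmetrics
from .connectivity import WindowSeries, devectorize_upper
from .audiofeat import SegmentEntropyProfile
from .groupstats import StatResult

__all__ = [
    "StateModel",
    "pool_windows",
    "select_k",
    "cluster_windows",
    "state_frequency",
    "state_graph_summary",
    "segment_dominance",
    "entropy_state_correlation",
]


@dataclass
class StateModel:
    k: int
    centroids: np.ndarray  # k x E
    labels: pd.DataFrame  # subject, condition, window_index, center_s, state
    inertia: float
    n_parcels: int
    seed: int
    n_replicates: int
    validity: pd.DataFrame | None = None
    flags: list[str] | None = None


def pool_windows(series: list[WindowSeries]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack windows from all subjects x conditions; keep their identity."""
    mats = []
    rows = []
    for ws in series:
        mats.append(ws.windows)
        centers = ws.window_center_seconds()
        for w in range(ws.n_windows):
            rows.append(
                {
                    "subject": ws.subject_id,
                    "condition": ws.condition,
                    "window_index": w,
                    "center_s": centers[w],
                }
            )
    return np.vstack(mats), pd.DataFrame(rows)


def _fit_kmeans(X: np.ndarray, k: int, n_replicates: int, seed: int) -> KMeans:
    """Best-of-``n_replicates`` k-means; refits with a new sub-seed if a
    cluster comes up empty (bounded retries)."""
    for attempt in range(5):
        km = KMeans(
            n_clusters=k,
            n_init=n_replicates,
            random_state=(seed + 7919 * attempt) % (2**31 - 1),
        ).fit(X)
        if len(np.unique(km.labels_)) == k:
            return km
    raise RuntimeError(f"k-means produced an empty cluster for k={k}")


def _elbow_k(ks: list[int], inertias: list[float], total_ss: float) -> int:
    """Elbow on within-cluster squared distance: the k with the largest
    curvature (second difference) of the inertia curve, anchored at k=1
    where the inertia is the total sum of squares."""
    kk = np.array([1] + list(ks))
    ii = np.array([total_ss] + list(inertias))
    curv = ii[:-2] - 2 * ii[1:-1] + ii[2:]  # curvature at kk[1:-1]
    return int(kk[1:-1][np.argmax(curv)])


def select_k(
    windows: np.ndarray,
    k_range=range(2, 9),
    n_replicates: int = 20,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of states by four validity indices, majority vote.

    Returns the selected k and a table with, per candidate k: inertia,
    silhouette, Calinski-Harabasz, Davies-Bouldin, plus each index's vote.
    Ties break toward the smallest k.  A uniformly low silhouette
    (max < 0.1) flags "no state structure" in the table attrs.
    """
    ks = list(k_range)
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate ks")
    X = windows
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    rows = []
    for k in ks:
        km = _fit_kmeans(X, k, n_replicates, seed)
        rows.append(
            {
                "k": k,
                "inertia": km.inertia_,
                "silhouette": silhouette_score(X, km.labels_),
                "calinski_harabasz": calinski_harabasz_score(X, km.labels_),
                "davies_bouldin": davies_bouldin_score(X, km.labels_),
            }
        )
    tab = pd.DataFrame(rows)
    votes = {
        "elbow": _elbow_k(ks, tab["inertia"].tolist(), total_ss),
        "silhouette": int(tab.loc[tab["silhouette"].idxmax(), "k"]),
        "calinski_harabasz": int(tab.loc[tab["calinski_harabasz"].idxmax(), "k"]),
        "davies_bouldin": int(tab.loc[tab["davies_bouldin"].idxmin(), "k"]),
    }
    for name, k in votes.items():
        tab[f"vote_{name}"] = k
    counts = pd.Series(list(votes.values())).value_counts()
    best = counts.max()
    k_star = int(min(k for k, c in counts.items() if c == best))
    tab.attrs["votes"] = votes
    tab.attrs["no_state_structure"] = bool(tab["silhouette"].max() < 0.1)
    return k_star, tab


def _centroid_modularity(centroid: np.ndarray, n_parcels: int, seed: int) -> float:
    W = np.maximum(devectorize_upper(centroid, n_parcels), 0.0)
    return graphmetrics.louvain_partition(W, n_runs=10, seed=seed).quality_q


def cluster_windows(
    series: list[WindowSeries],
    k: int = 2,
    n_replicates: int = 50,
    seed: int = 0,
) -> StateModel:
    """Fit k-means to the pooled windows and canonically order the states.

    State ids are renumbered by decreasing centroid modularity, so state 0 is
    always the most segregated state.
    """
    X, meta = pool_windows(series)
    if k < 2:
        raise ValueError("k must be >= 2")
    km = _fit_kmeans(X, k, n_replicates, seed)
    n_parcels = series[0].n_parcels
    qs = [_centroid_modularity(km.cluster_centers_[j], n_parcels, seed) for j in range(k)]
    order = np.argsort(qs)[::-1]  # descending modularity
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    meta = meta.copy()
    meta["state"] = relabel[km.labels_]
    return StateModel(
        k=k,
        centroids=km.cluster_centers_[order],
        labels=meta,
        inertia=float(km.inertia_),
        n_parcels=n_parcels,
        seed=seed,
        n_replicates=n_replicates,
    )


def state_frequency(model: StateModel) -> pd.DataFrame:
    """Fraction of each subject x condition's windows spent in each state.

    Rows sum to 1 across states.
    """
    counts = (
        model.labels.groupby(["subject", "condition", "state"])
        .size()
        .unstack("state", fill_value=0)
        .reindex(columns=range(model.k), fill_value=0)
    )
    freq = counts.div(counts.sum(axis=1), axis=0)
    freq.columns = [f"state_{j}" for j in range(model.k)]
    return freq.reset_index()


def state_graph_summary(
    series: list[WindowSeries],
    model: StateModel,
    louvain_runs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per subject x state mean modularity Q and global efficiency.

    Each window's correlation matrix has its negatives zeroed, then Louvain Q
    and weighted global efficiency are computed; values are averaged over the
    subject's windows in each state.  Subjects contribute only to states they
    actually visited.
    """
    lab = model.labels.set_index(["subject", "condition", "window_index"])["state"]
    rows = []
    for ws in series:
        for w in range(ws.n_windows):
            state = lab.loc[(ws.subject_id, ws.condition, w)]
            W = np.maximum(devectorize_upper(ws.windows[w], ws.n_parcels), 0.0)
            part = graphmetrics.louvain_partition(W, n_runs=louvain_runs, seed=seed)
            e_glob, _ = graphmetrics.global_efficiency(W)
            rows.append(
                {
                    "subject": ws.subject_id,
                    "condition": ws.condition,
                    "state": int(state),
                    "modularity_q": part.quality_q,
                    "global_efficiency": e_glob,
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["subject", "state"])[["modularity_q", "global_efficiency"]]
        .mean()
        .reset_index()
    )


def segment_dominance(
    model: StateModel, segment_length_s: float = 60.0
) -> pd.DataFrame:
    """State occupancy per 60-s segment, pooled over subjects.

    A window belongs to the segment containing its center.  Returns one row
    per condition x segment with each state's occupancy (rows sum to 1) and
    the dominant state.
    """
    lab = model.labels.copy()
    lab["segment"] = (lab["center_s"] // segment_length_s).astype(int)
    occ = (
        lab.groupby(["condition", "segment", "state"])
        .size()
        .unstack("state", fill_value=0)
        .reindex(columns=range(model.k), fill_value=0)
    )
    occ = occ.div(occ.sum(axis=1), axis=0)
    occ.columns = [f"state_{j}" for j in range(model.k)]
    occ["dominant_state"] = occ.to_numpy().argmax(axis=1)
    return occ.reset_index()


def entropy_state_correlation(
    dominance: pd.DataFrame,
    entropy_by_condition: dict[str, SegmentEntropyProfile],
    state: int = 0,
) -> StatResult:
    """Pearson r between segment audio entropy and a state's occupancy.

    Segments of all conditions are pooled (two 5-min pieces give n = 10
    pairs); p is two-sided from t with n-2 df.  ``state`` defaults to the
    modular state 0, for which the planted coupling predicts anticorrelation.
    """
    xs, ys = [], []
    for cond, prof in entropy_by_condition.items():
        sub = dominance[dominance["condition"] == cond].sort_values("segment")
        n = min(len(sub), len(prof.entropies))
        xs.extend(prof.entropies[:n])
        ys.extend(sub[f"state_{state}"].to_numpy()[:n])
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 3:
        raise ValueError("need at least 3 paired segments")
    r, p = stats.pearsonr(x, y)
    return StatResult(r, len(x) - 2, p, r, "pearson_entropy_state", (len(x),))
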