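"""Unsupervised activation-trajectory recovery.

Pipeline: PCA (centered, no per-feature scaling, 45 components by default)
-> symmetric k-nearest-neighbor graph with cosine-distance edge weights ->
largest connected component -> pseudotime as the graph geodesic
(shortest-path) distance from the earliest-acquired cell, normalized to
[0, 1] -- plus a minimum spanning tree rooted at the same cell for
trajectory visualization.  Validation against real acquisition time uses
two-sided Spearman rank correlation at both the spectrum level and the
time-bin level (per-bin median pseudotime vs bin start time).

The geodesic scalar (rather than the MST path distance) is used because
the tree-path statistic is unstable where the cosine metric compresses
the late course of a trajectory: the tree there degenerates into a web
attached at an arbitrary entry point, so path distances stop tracking
progression even when the graph distances still do.  The graph, component,
root and tree construction are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .embedding import TimeBinning
from .spectra import SpectraSet

__all__ = [
    "PseudotimeConfig",
    "PseudotimeResult",
    "compute_pseudotime",
    "pseudotime_bins",
    "time_correlation",
]


@dataclass(frozen=True)
class PseudotimeConfig:
    n_pcs: int = 45
    k_neighbors: int = 30
    n_bins: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")


@dataclass
class PseudotimeResult:
    """Pseudotime tau in [0, 1] per spectrum; NaN outside the largest
    connected component of the kNN graph."""

    spectrum_ids: list[str]
    tau: np.ndarray
    in_component: np.ndarray  # bool mask
    tree_edges: list[tuple[int, int, float]]
    root_id: str
    times: np.ndarray


def compute_pseudotime(
    sset: SpectraSet, config: PseudotimeConfig = PseudotimeConfig()
) -> PseudotimeResult:
    """Compute graph pseudotime on preprocessed spectra with acquisition times.

    The root is the largest-component member with the minimum time_min
    (ties broken by lexicographically smallest spectrum_id); tau is the
    shortest-path distance from the root over cosine-distance edge weights,
    divided by the maximum such distance.  The rooted minimum spanning tree
    of the component is returned alongside for visualization.
    """
    n = len(sset)
    if n <= config.k_neighbors:
        raise ValueError("need more spectra than k_neighbors")
    times = sset.times()  # hard error if any spectrum lacks time
    X = sset.intensity_matrix()
    n_pcs = min(config.n_pcs, n - 1, sset.axis.n_channels)
    pca = PCA(n_components=n_pcs, random_state=config.seed)
    Z = pca.fit_transform(X)

    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1, metric="cosine")
    nn.fit(Z)
    dist, idx = nn.kneighbors(Z)
    rows = np.repeat(np.arange(n), config.k_neighbors)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    # cosine distance can be exactly 0 for (near-)duplicate points; keep
    # those edges traversable with a tiny positive weight
    vals = np.maximum(vals, 1e-12)
    G = csr_matrix((vals, (rows, cols)), shape=(n, n))
    G = G.maximum(G.T)  # symmetrize by union of directed neighbor sets

    n_comp, comp = connected_components(G, directed=False)
    sizes = np.bincount(comp)
    main = int(np.argmax(sizes))
    member = comp == main
    if sizes[main] < 0.1 * n:
        raise ValueError(
            f"largest kNN-graph component has {sizes[main]}/{n} spectra (< 10%); "
            "degenerate graph"
        )

    ids = sset.ids()
    cand = np.flatnonzero(member)
    t_min = times[cand].min()
    at_min = cand[times[cand] == t_min]
    root = int(min(at_min, key=lambda i: ids[i]))

    sub = G[member][:, member]
    local = np.flatnonzero(member)
    d = dijkstra(sub, directed=False, indices=int(np.searchsorted(local, root)))

    tau = np.full(n, np.nan)
    d_max = d.max()
    tau[member] = d / d_max if d_max > 0 else 0.0

    coo = minimum_spanning_tree(sub).tocoo()
    edges = [
        (int(local[i]), int(local[j]), float(v)) for i, j, v in zip(coo.row, coo.col, coo.data)
    ]
    return PseudotimeResult(
        spectrum_ids=ids,
        tau=tau,
        in_component=member,
        tree_edges=edges,
        root_id=ids[root],
        times=times,
    )


def pseudotime_bins(
    result: PseudotimeResult, coords: np.ndarray, n_bins: int = 12
) -> pd.DataFrame:
    """Centroids of equal-width pseudotime bins in an aligned 2-D embedding.

    The tau range [0, 1] is partitioned into ``n_bins`` equal-width
    intervals; each occupied bin contributes the mean coordinate of its
    members.  Empty bins are omitted but keep their count (0) in the frame.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(result.tau):
        raise ValueError("coords/pseudotime length mismatch")
    tau = result.tau
    member = result.in_component & np.isfinite(tau)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.searchsorted(edges, tau[member], side="right") - 1, 0, n_bins - 1)
    pts = coords[member]
    med_tau = tau[member]
    rows = []
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        row = {"bin": b, "tau_low": edges[b], "tau_high": edges[b + 1], "n": n}
        if n:
            mean = pts[mask].mean(axis=0)
            row.update({f"centroid_{i}": mean[i] for i in range(coords.shape[1])})
            row["median_tau"] = float(np.median(med_tau[mask]))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TimeCorrelation:
    spectrum_rho: float
    spectrum_p: float
    bin_rho: float | None
    bin_p: float | None
    bin_medians: dict[float, float]  # bin start time -> median tau


def time_correlation(
    result: PseudotimeResult, binning: TimeBinning = TimeBinning()
) -> TimeCorrelation:
    """Two-sided Spearman correlation of pseudotime with acquisition time.

    Spectrum level: over all largest-component members.  Bin level: per-bin
    median tau vs bin start time (requires >= 3 occupied bins; otherwise
    null with a warning).  Midrank handling of ties.
    """
    member = result.in_component
    rho, p = spearmanr(result.tau[member], result.times[member])
    bins = binning.assign(result.times)
    medians: dict[float, float] = {}
    for b, start in enumerate(binning.labels):
        mask = member & (bins == b)
        if mask.any():
            medians[float(start)] = float(np.median(result.tau[mask]))
    if len(medians) >= 3:
        starts = np.array(sorted(medians))
        med = np.array([medians[s] for s in starts])
        brho, bp = spearmanr(med, starts)
        bin_rho, bin_p = float(brho), float(bp)
    else:
        warnings.warn("fewer than 3 occupied time bins; bin-level correlation is null")
        bin_rho = bin_p = None
    return TimeCorrelation(
        spectrum_rho=float(rho),
        spectrum_p=float(p),
        bin_rho=bin_rho,
        bin_p=bin_p,
        bin_medians=medians,
    )
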