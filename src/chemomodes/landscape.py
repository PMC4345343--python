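"""Conformational-landscape clustering.

Two complementary clusterings of structural ensembles: gromos-style
leader clustering of a pairwise DRMS matrix at a fixed cutoff, and
density-peak clustering (local density rho, separation delta) of the 2D
(pe_1, pe_2) projection landscape, with per-cluster occupancy
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateDensityError,
    InsufficientDataError,
    ParameterError,
)
from .geometry import PairwiseMatrix

#: The DRMS clustering cutoff used for conformational families (nm).
DEFAULT_DRMS_CUTOFF_NM = 0.2


@dataclass
class ClusterResult:
    """Per-frame labels, cluster centers, and occupancy probabilities."""

    labels: np.ndarray  # (M,), -1 = halo/unassigned
    centers: np.ndarray  # frame/point indices of cluster centers
    probabilities: np.ndarray  # per-cluster fraction of assigned frames
    center_points: np.ndarray | None = None  # (k, 2) for landscape clustering
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def summary_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.center_points is not None:
                fh.write("cluster\tcenter_index\tcenter_pe1\tcenter_pe2\tprobability\n")
                for c, (idx, pt, p) in enumerate(zip(self.centers, self.center_points, self.probabilities)):
                    fh.write(f"{c}\t{idx}\t{pt[0]:.10g}\t{pt[1]:.10g}\t{p:.10g}\n")
            else:
                fh.write("cluster\tcenter_index\tprobability\n")
                for c, (idx, p) in enumerate(zip(self.centers, self.probabilities)):
                    fh.write(f"{c}\t{idx}\t{p:.10g}\n")


@dataclass
class DensityDelta:
    """Per-point local density rho and separation delta (decision-graph data)."""

    rho: np.ndarray
    delta: np.ndarray
    nearest_higher: np.ndarray  # index of nearest point of higher density, -1 for the global peak

    def decision_graph_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("point\trho\tdelta\n")
            for i, (r, d) in enumerate(zip(self.rho, self.delta)):
                fh.write(f"{i}\t{r:.10g}\t{d:.10g}\n")


# ---------------------------------------------------------------------------
# gromos-style DRMS clustering
# ---------------------------------------------------------------------------

def drms_cluster(m: PairwiseMatrix, cutoff: float = DEFAULT_DRMS_CUTOFF_NM) -> ClusterResult:
    """Leader clustering of a DRMS matrix at a fixed cutoff (nm).

    Repeatedly takes the unassigned frame with the most unassigned
    neighbors within the cutoff as a cluster center, assigns the
    neighborhood, and removes it; ties break toward the lower frame index,
    so the partition is deterministic.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    values = m.values
    n = values.shape[0]
    if n == 0:
        raise InsufficientDataError("empty pairwise matrix")
    within = values < cutoff
    np.fill_diagonal(within, True)
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cluster = 0
    while remaining.any():
        counts = (within & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the first (lowest index) maximum
        members = within[center] & remaining
        labels[members] = cluster
        centers.append(center)
        remaining &= ~members
        cluster += 1
    sizes = np.bincount(labels, minlength=cluster).astype(float)
    return ClusterResult(labels=labels, centers=np.array(centers),
                         probabilities=sizes / n, params={"cutoff": cutoff, "metric": m.metric})


# ---------------------------------------------------------------------------
# density-peak clustering of the 2D landscape
# ---------------------------------------------------------------------------

def choose_dc(points: np.ndarray, neighbor_frac: float = 0.02) -> float:
    """Kernel scale at which the mean neighbor count is ``neighbor_frac * M``
    (the usual 1-2% rule of thumb for density-peak clustering)."""
    d = pdist(np.asarray(points, float))
    if d.size == 0 or d.max() == 0:
        raise DegenerateDensityError("all points coincide; no length scale")
    return float(np.quantile(d[d > 0], neighbor_frac))


def _density_order(rho: np.ndarray) -> np.ndarray:
    """Indices by decreasing density; equal densities rank earlier index higher."""
    return np.lexsort((np.arange(rho.size), -rho))


def density_delta(points: np.ndarray, dc: float, kernel: str = "gaussian") -> DensityDelta:
    """Local density rho and distance-to-higher-density delta for each point.

    ``kernel="cutoff"`` counts neighbors closer than dc; ``"gaussian"``
    uses ``sum exp(-(d/dc)^2)``. The global density maximum is assigned
    delta = max pairwise distance. Density ties are broken by point index
    (the earlier point counts as denser), so delta > 0 whenever
    coordinates are distinct.
    """
    points = np.asarray(points, float)
    if points.ndim != 2:
        raise ParameterError("points must be an (M, d) array")
    m = points.shape[0]
    if m < 2:
        raise InsufficientDataError("density analysis needs at least two points")
    if dc <= 0:
        raise ParameterError(f"dc must be positive, got {dc}")
    dist = squareform(pdist(points))
    if dist.max() == 0:
        raise DegenerateDensityError("all points are identical")
    if kernel == "cutoff":
        rho = (dist < dc).sum(axis=1).astype(float) - 1.0  # exclude self
    elif kernel == "gaussian":
        rho = np.exp(-((dist / dc) ** 2)).sum(axis=1) - 1.0
    else:
        raise ParameterError(f"unknown kernel {kernel!r}")
    order = _density_order(rho)
    delta = np.empty(m)
    nearest = np.full(m, -1, dtype=int)
    delta[order[0]] = dist.max()
    for rank in range(1, m):
        i = order[rank]
        higher = order[:rank]
        j = higher[np.argmin(dist[i, higher])]
        delta[i] = dist[i, j]
        nearest[i] = j
    return DensityDelta(rho=rho, delta=delta, nearest_higher=nearest)


def density_peak_cluster(
    points: np.ndarray,
    dc: float | None = None,
    kernel: str = "gaussian",
    n_centers: int | None = None,
    rho_min: float | None = None,
    delta_min: float | None = None,
    halo: bool = False,
) -> ClusterResult:
    """Density-peak clustering of 2D landscape points.

    Centers are either the ``n_centers`` points with the largest
    gamma = rho * delta, or all points with rho >= rho_min and
    delta >= delta_min. Every other point inherits the label of its
    nearest higher-density neighbor, processed in decreasing density
    order. With ``halo`` enabled, points whose density falls below the
    highest border density of their cluster are marked -1.
    """
    points = np.asarray(points, float)
    m = points.shape[0]
    if dc is None:
        dc = choose_dc(points)
    dd = density_delta(points, dc, kernel=kernel)
    if n_centers is not None:
        if n_centers < 1 or n_centers > m:
            raise ParameterError(f"n_centers {n_centers} outside 1..{m}")
        gamma = dd.rho * dd.delta
        centers = np.sort(np.argsort(-gamma, kind="stable")[:n_centers])
    elif rho_min is not None and delta_min is not None:
        centers = np.nonzero((dd.rho >= rho_min) & (dd.delta >= delta_min))[0]
        if centers.size == 0:
            raise ParameterError("no points satisfy the (rho_min, delta_min) thresholds")
    else:
        raise ParameterError("specify n_centers or both rho_min and delta_min")
    labels = np.full(m, -1, dtype=int)
    for c, idx in enumerate(centers):
        labels[idx] = c
    order = _density_order(dd.rho)
    for i in order:
        if labels[i] < 0:
            labels[i] = labels[dd.nearest_higher[i]]
    if halo and centers.size > 1:
        dist = squareform(pdist(points))
        border = np.zeros(centers.size)
        for i in range(m):
            for j in range(i + 1, m):
                if labels[i] != labels[j] and dist[i, j] < dc:
                    rho_b = 0.5 * (dd.rho[i] + dd.rho[j])
                    border[labels[i]] = max(border[labels[i]], rho_b)
                    border[labels[j]] = max(border[labels[j]], rho_b)
        assigned = labels.copy()
        for i in range(m):
            if dd.rho[i] < border[labels[i]]:
                assigned[i] = -1
        labels = assigned
    n_assigned = int((labels >= 0).sum())
    sizes = np.bincount(labels[labels >= 0], minlength=centers.size).astype(float)
    return ClusterResult(
        labels=labels,
        centers=centers,
        probabilities=sizes / max(n_assigned, 1),
        center_points=points[centers],
        params={"dc": dc, "kernel": kernel, "n_centers": n_centers,
                "rho_min": rho_min, "delta_min": delta_min, "halo": halo},
    )


def cluster_probabilities(
    c: ClusterResult, grouping: Sequence[Sequence[int]] | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-cluster occupancy fractions and optional sums over cluster groups."""
    probs = np.asarray(c.probabilities, float)
    if grouping is None:
        return probs, None
    totals = np.empty(len(grouping))
    for g, ids in enumerate(grouping):
        ids = np.asarray(list(ids), int)
        if np.any(ids < 0) or np.any(ids >= probs.size):
            raise ParameterError(f"grouping {g} names unknown cluster ids {ids.tolist()}")
        totals[g] = probs[ids].sum()
    return probs, totals
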