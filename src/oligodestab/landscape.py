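"""Two-dimensional free-energy landscapes and RMSD-based clustering.

The landscape is the Boltzmann inversion of the 2D histogram of two reaction
coordinates (here beta-sheet content and radius of gyration):

    dG(x, y) = -kT ln[ P(x, y) / Pmax ]

so the most populated bin sits at dG = 0 exactly and empty bins are +inf.
kB = 0.0019872 kcal/(mol K); the default temperature is 310 K.

Clustering is k-medoids (PAM) on the pairwise C-alpha RMSD matrix of frames
superposed onto the first frame.  k-medoids on the same metric replaces the
self-organizing-map clustering some MD packages ship: with a fixed seed it
is deterministic, and the medoid is a well-defined representative (the
member minimizing summed RMSD to its cluster).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Trajectory
from .order import superpose_trajectory

KB = 0.0019872  # kcal / (mol K)


@dataclass
class Basin:
    x_center: float
    y_center: float
    depth: float  # dG at the minimum, kcal/mol


@dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    delta_g: np.ndarray
    kt: float
    basins: list[Basin] = field(default_factory=list)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def build_fel(x_series: np.ndarray, y_series: np.ndarray,
              bins: tuple[int, int] = (40, 40),
              temperature: float = 310.0) -> FELGrid:
    """Histogram two reaction-coordinate series (range padded by 2% of the
    span on each side) and Boltzmann-invert to a free-energy surface."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("series must be equal-length and non-empty")

    def padded_range(v, nbins):
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            return (lo - 0.5, hi + 0.5), 1
        pad = 0.02 * (hi - lo)
        return (lo - pad, hi + pad), nbins

    (xr, nx) = padded_range(x, bins[0])
    (yr, ny) = padded_range(y, bins[1])
    if nx == 1 and ny == 1:
        warnings.warn("both reaction coordinates have zero variance; "
                      "the landscape degenerates to a single bin")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=(nx, ny),
                                              range=(xr, yr))
    kt = KB * temperature
    with np.errstate(divide="ignore"):
        # "+ 0.0" maps the -0.0 of the most populated bin onto plain 0.0
        delta_g = np.where(counts > 0,
                           -kt * np.log(counts / counts.max()) + 0.0,
                           np.inf)
    return FELGrid(x_edges, y_edges, counts, delta_g, kt)


def find_basins(grid: FELGrid, min_separation_bins: int = 3,
                max_depth: float = np.inf) -> list[Basin]:
    """Local minima of the free-energy surface over the 8-neighborhood.

    Candidates with dG above ``max_depth`` are dropped; the rest are greedily
    filtered so kept basins are at least ``min_separation_bins`` apart in bin
    space, deepest first (ties broken toward lower x, then lower y).  The
    global minimum is always first.  The basin list is also stored on the
    grid.
    """
    g = grid.delta_g
    nx, ny = g.shape
    candidates = []
    for i in range(nx):
        for j in range(ny):
            v = g[i, j]
            if not np.isfinite(v) or v > max_depth:
                continue
            neighborhood = g[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if v <= neighborhood.min():
                candidates.append((v, grid.x_centers[i], grid.y_centers[j], i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    kept: list[tuple] = []
    for cand in candidates:
        if all(np.hypot(cand[3] - k[3], cand[4] - k[4]) >= min_separation_bins
               for k in kept):
            kept.append(cand)
    basins = [Basin(x, y, v) for v, x, y, _, _ in kept]
    grid.basins = basins
    return basins


@dataclass
class ClusterResult:
    labels: np.ndarray        # per analyzed frame
    occupancies: np.ndarray   # fraction per cluster, sums to 1
    representatives: np.ndarray  # original frame index per cluster (medoid)
    k: int
    frame_indices: np.ndarray  # analyzed (strided) original frame indices


def pairwise_rmsd_matrix(traj: Trajectory, selection: np.ndarray,
                         stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise C-alpha RMSD between frames superposed onto frame 1."""
    work = traj
    if not traj.superposed:
        work, _ = superpose_trajectory(traj, selection)
    idx = np.arange(0, len(work), stride)
    coords = np.stack([work.frames[i].coordinates[selection] for i in idx])
    n = coords.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = coords[i + 1:] - coords[i]
        d[i, i + 1:] = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return d + d.T, idx


def _k_medoids(dist: np.ndarray, k: int, seed: int,
               max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """PAM-style k-medoids: greedy BUILD initialization (deterministic, ties
    to the lowest frame index) followed by alternating assignment/update."""
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance; each next medoid
    # maximizes the resulting cost reduction
    medoids_list = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids_list) < k:
        nearest = dist[:, medoids_list].min(axis=1)
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids_list] = -1.0
        medoids_list.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids_list))
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels, medoids


def cluster_frames(traj: Trajectory, selection: np.ndarray | None = None,
                   k: int = 3, seed: int = 0, stride: int = 1
                   ) -> ClusterResult:
    """k-medoids clustering of frames on the pairwise RMSD matrix.

    Deterministic for a fixed seed.  If the distance matrix is degenerate
    (identical frames) some clusters may come out empty; this is reported
    with a warning rather than hidden.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if selection is None:
        selection = np.flatnonzero(traj.topology.calpha_mask)
    dist, frame_idx = pairwise_rmsd_matrix(traj, selection, stride)
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} analyzed frames")
    labels, medoids = _k_medoids(dist, k, seed)
    occupancies = np.array([(labels == c).mean() for c in range(k)])
    if np.any(occupancies == 0):
        warnings.warn("degenerate clustering: at least one cluster is empty "
                      "(identical or near-identical frames)")
    return ClusterResult(labels=labels, occupancies=occupancies,
                         representatives=frame_idx[medoids], k=k,
                         frame_indices=frame_idx)


def stability_over_k(traj: Trajectory, selection: np.ndarray | None = None,
                     k_list: tuple[int, ...] = (3, 4, 5), seed: int = 0,
                     stride: int = 1) -> dict:
    """Occupancy vectors (sorted descending) for several cluster counts, plus
    the cumulative occupancy of the top two classes per k."""
    out = {"k": [], "occupancies": [], "top2_cumulative": []}
    for k in k_list:
        res = cluster_frames(traj, selection, k=k, seed=seed, stride=stride)
        occ = np.sort(res.occupancies)[::-1]
        out["k"].append(k)
        out["occupancies"].append(occ)
        out["top2_cumulative"].append(float(occ[:2].sum()))
    return out
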