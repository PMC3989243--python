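"""Global order and fluctuation metrics.

Implements the nematic order parameter P2 over chain end-to-end vectors, the
ordered/disordered classification at the 0.5 cutoff, Kabsch least-squares
superposition with RMSD, chain-averaged per-residue RMSF, and the radius of
gyration.

The director is taken as the principal eigenvector of the ordering tensor

    Q = (1/N) sum_i (3/2 u_i u_i^T - 1/2 I),

whose largest eigenvalue equals P2 = (1/N) sum_i (3/2 (u_i . d)^2 - 1/2).
This is the standard liquid-crystal estimator: it maximizes P2 over all unit
directors and keeps it in [0, 1] (up to the -1/2 floor for pathological
planar arrangements, which the eigen-construction avoids for generic data).
u_i is the unit vector from the first to the last C-alpha of chain i.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Frame, Topology, Trajectory

#: Ordered/disordered boundary for the mean nematic order parameter.
P2_CUTOFF = 0.5


@dataclass
class DirectorResult:
    p2: float
    director: np.ndarray
    chain_vectors: np.ndarray
    n_chains: int


@dataclass
class FrameMetrics:
    rmsd: float
    rg: float
    time: float


def chain_end_to_end_vectors(frame: Frame, top: Topology) -> np.ndarray:
    """Unit vectors from first-residue C-alpha to last-residue C-alpha per chain."""
    vectors = []
    for chain in top.chains:
        mask = (top.chain_ids == chain) & top.calpha_mask
        res = top.residue_indices[mask]
        if res.size == 0:
            raise ValueError(f"chain {chain} has no C-alpha atoms")
        idx = np.flatnonzero(mask)
        first = idx[np.argmin(res)]
        last = idx[np.argmax(res)]
        if res.min() == res.max():
            raise ValueError(f"chain {chain} has a single residue; no end-to-end vector")
        v = frame.coordinates[last] - frame.coordinates[first]
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise ValueError(f"chain {chain} has coincident terminal C-alpha atoms")
        vectors.append(v / n)
    return np.array(vectors)


def nematic_p2(frame: Frame, top: Topology) -> DirectorResult:
    """Nematic order parameter of the chain end-to-end vectors."""
    u = chain_end_to_end_vectors(frame, top)
    return nematic_p2_from_vectors(u)


def nematic_p2_from_vectors(u: np.ndarray) -> DirectorResult:
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    n = u.shape[0]
    q = 1.5 * (u.T @ u) / n - 0.5 * np.eye(3)
    evals, evecs = np.linalg.eigh(q)
    p2 = float(evals[-1])
    director = evecs[:, -1]
    return DirectorResult(p2=p2, director=director, chain_vectors=u, n_chains=n)


def p2_series(traj: Trajectory) -> np.ndarray:
    return np.array([nematic_p2(f, traj.topology).p2 for f in traj.frames])


def classify_order(p2_values: Sequence[float],
                   cutoff: float = P2_CUTOFF) -> tuple[str, float, float]:
    """Label a P2 series ordered/disordered by its mean (strict inequality).

    Returns ``(label, mean, sd)``; sd is the plain population standard
    deviation over the series (the error bar of the mean-P2 bar plots).
    """
    values = np.asarray(p2_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty P2 series")
    mean = float(values.mean())
    sd = float(values.std())
    label = "ordered" if mean > cutoff else "disordered"
    return label, mean, sd


def superpose(mobile: Frame, reference: Frame,
              selection: np.ndarray) -> tuple[Frame, float]:
    """Optimal rigid-body superposition (Kabsch, no reflection).

    The rotation/translation minimizing the RMSD over ``selection`` is
    applied to *all* atoms of ``mobile``; the returned RMSD is the minimized
    value over the selection.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    x = mobile.coordinates[selection]
    y = reference.coordinates[selection]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile.coordinates - xc) @ rot.T + yc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[selection] - y) ** 2, axis=1))))
    return Frame(moved, mobile.time), rmsd


def superpose_trajectory(traj: Trajectory, selection: np.ndarray | None = None,
                         reference_frame: int = 0) -> tuple[Trajectory, np.ndarray]:
    """Fit every frame onto a reference frame; returns the fitted trajectory
    (flagged ``superposed``) and the per-frame RMSD series."""
    top = traj.topology
    if selection is None:
        selection = np.flatnonzero(top.calpha_mask)
    ref = traj.frames[reference_frame]
    fitted, rmsds = [], []
    for f in traj.frames:
        g, r = superpose(f, ref, selection)
        fitted.append(g)
        rmsds.append(r)
    out = Trajectory(top, fitted, timestep=traj.timestep, superposed=True)
    return out, np.array(rmsds)


def rmsd_series(traj: Trajectory, selection: np.ndarray | None = None,
                reference_frame: int = 0) -> np.ndarray:
    """Per-frame C-alpha RMSD to the reference frame after optimal fitting."""
    _, rmsds = superpose_trajectory(traj, selection, reference_frame)
    return rmsds


def rmsf_per_residue_chain_averaged(traj: Trajectory) -> np.ndarray:
    """Per-residue C-alpha RMSF about the time-mean position, averaged over
    chains at equal residue index.  Requires a superposed trajectory."""
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if not traj.superposed:
        raise ValueError("trajectory is not superposed; fit frames onto a "
                         "reference first (superpose_trajectory)")
    top = traj.topology
    ca = np.flatnonzero(top.calpha_mask)
    coords = traj.coordinate_array()[:, ca, :]
    mean = coords.mean(axis=0)
    rmsf_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    residues = top.residue_indices[ca]
    unique = np.unique(residues)
    out = np.zeros(unique.size)
    for i, r in enumerate(unique):
        out[i] = rmsf_atom[residues == r].mean()
    return out


def radius_of_gyration(frame: Frame, selection: np.ndarray,
                       mass_weighted: bool = False,
                       masses: np.ndarray | None = None) -> float:
    """Radius of gyration sqrt(sum w |r - rbar|^2 / sum w) over a selection."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection for radius of gyration")
    x = frame.coordinates[selection]
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted=True requires masses")
        w = np.asarray(masses, dtype=float)[selection]
    else:
        w = np.ones(selection.size)
    center = (x * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((x - center) ** 2, axis=1)).sum() / w.sum()))


def rg_series(traj: Trajectory, selection: np.ndarray | None = None,
              mass_weighted: bool = False) -> np.ndarray:
    top = traj.topology
    if selection is None:
        selection = np.flatnonzero(top.calpha_mask)
    return np.array([radius_of_gyration(f, selection, mass_weighted, top.masses)
                     for f in traj.frames])
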