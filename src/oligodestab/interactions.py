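"""Geometric hydrogen bonds, ligand contacts, pi-stacking and pairwise energies.

The hydrogen-bond criterion is purely geometric: a donor-hydrogen-acceptor
triple is a bond iff the donor-acceptor distance is strictly less than 3.5 A
and the D-H-A angle is strictly greater than 150 degrees.  Donors are N/O
atoms carrying at least one covalent hydrogen; acceptors are N/O atoms;
intra-residue pairs are excluded.  Contacts use the same 3.5 A cutoff between
any ligand atom and protein heavy atoms (backbone and sidechain tallied
separately).

Interaction energies are plain pairwise Coulomb plus 12-6 Lennard-Jones
(Lorentz-Berthelot combining), both multiplied by the standard polynomial
switching function that turns the interaction off smoothly between 10 and
12 A.  No periodicity and no solvent term: this is a group-group gas-phase
energy of the kind trajectory-viewer plugins report.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import BACKBONE_H_NAMES, BACKBONE_NAMES, Frame, Topology, Trajectory

HBOND_DISTANCE_CUTOFF = 3.5   # A, donor...acceptor, strict
HBOND_ANGLE_CUTOFF = 150.0    # degrees, D-H-A, strict
CONTACT_CUTOFF = 3.5          # A
COULOMB_CONSTANT = 332.0636   # kcal A / (mol e^2)


class HBond(NamedTuple):
    donor: int      # heavy-atom index
    hydrogen: int
    acceptor: int
    distance: float  # donor...acceptor, A
    angle: float     # D-H-A, degrees


@dataclass
class HBondMap:
    """Residue-pair backbone H-bond counts for one chain pair, normalized so
    the largest cell equals 1 (skipped and flagged when the map is empty)."""

    chain_x: str
    chain_y: str
    matrix: np.ndarray          # (n_residues_x, n_residues_y), normalized
    raw_counts: np.ndarray
    all_zero: bool


@dataclass
class ContactProfile:
    residues: list[tuple[str, int]]
    backbone_probability: np.ndarray
    sidechain_probability: np.ndarray
    backbone_mean_contacts: np.ndarray
    sidechain_mean_contacts: np.ndarray
    important_backbone: list[tuple[str, int]]
    important_sidechain: list[tuple[str, int]]


@dataclass
class EnergyTrace:
    vdw: np.ndarray
    electrostatic: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.vdw + self.electrostatic

    @property
    def mean(self) -> float:
        return float(self.total.mean())

    @property
    def sd(self) -> float:
        return float(self.total.std())


def _donor_pairs(top: Topology) -> list[tuple[int, int]]:
    """(donor heavy atom, hydrogen) pairs from the covalent parentage map."""
    pairs = []
    for h, parent in top.covalent_h_parents.items():
        if top.elements[parent] in ("N", "O"):
            pairs.append((parent, h))
    return sorted(pairs)


def detect_hbonds(frame: Frame, top: Topology, scope: str = "all",
                  distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                  angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> list[HBond]:
    """All directional (D, H, A) triples satisfying the geometric criterion.

    ``scope="backbone"`` restricts both donor and acceptor to protein
    backbone atoms.  Refuses to run on hydrogen-free topologies, since the
    criterion is defined through the covalent hydrogen.
    """
    if not np.any(top.hydrogen_mask):
        raise ValueError(
            "topology contains no hydrogens: the geometric H-bond criterion "
            "needs explicit amide/hydroxyl hydrogens (hydrogen reconstruction "
            "is out of scope; supply a protonated structure)")
    if scope not in ("all", "backbone"):
        raise ValueError(f"unknown scope {scope!r}")

    pairs = _donor_pairs(top)
    acceptor_mask = np.isin(top.elements, ["N", "O"])
    if scope == "backbone":
        acceptor_mask &= top.backbone_mask
        pairs = [(d, h) for d, h in pairs if top.backbone_mask[d]]
    acceptors = np.flatnonzero(acceptor_mask)
    if not pairs or acceptors.size == 0:
        return []

    coords = frame.coordinates
    tree = cKDTree(coords[acceptors])
    donor_idx = np.array([d for d, _ in pairs])
    h_idx = np.array([h for _, h in pairs])
    neighbor_lists = tree.query_ball_point(coords[donor_idx],
                                           r=distance_cutoff)
    chain = top.chain_ids
    res = top.residue_indices
    out: list[HBond] = []
    for (d, h), neighbors in zip(pairs, neighbor_lists):
        if not neighbors:
            continue
        a_idx = acceptors[np.asarray(neighbors)]
        same_residue = (chain[a_idx] == chain[d]) & (res[a_idx] == res[d])
        a_idx = a_idx[~same_residue]
        if a_idx.size == 0:
            continue
        da = coords[a_idx] - coords[d]
        dist = np.linalg.norm(da, axis=1)
        keep = dist < distance_cutoff
        a_idx, dist = a_idx[keep], dist[keep]
        if a_idx.size == 0:
            continue
        # D-H-A angle is the angle at the hydrogen between H->D and H->A
        hd = coords[d] - coords[h]
        ha = coords[a_idx] - coords[h]
        cosang = (ha @ hd) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(hd) + 1e-30)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for a, dst, ang in zip(a_idx, dist, angle):
            if ang > angle_cutoff:
                out.append(HBond(int(d), int(h), int(a), float(dst), float(ang)))
    return out


def backbone_hbond_count_series(traj: Trajectory) -> np.ndarray:
    """Per-frame count of inter-chain backbone-backbone hydrogen bonds."""
    top = traj.topology
    chain = top.chain_ids
    counts = []
    for frame in traj.frames:
        bonds = detect_hbonds(frame, top, scope="backbone")
        counts.append(sum(1 for b in bonds if chain[b.donor] != chain[b.acceptor]))
    return np.array(counts)


def hbond_map(traj: Trajectory, chain_pair: tuple[str, str],
              frame_window: slice | None = None) -> HBondMap:
    """Time-summed backbone H-bond counts per residue pair of two chains,
    normalized so the largest cell is 1."""
    cx, cy = chain_pair
    if cx == cy:
        raise ValueError("hbond_map is defined for two distinct chains")
    top = traj.topology
    for c in (cx, cy):
        if c not in top.chains:
            raise ValueError(f"chain {c} not in topology")
    n = top.residues_per_chain
    res_min = int(top.residue_indices[top.protein_mask].min())
    counts = np.zeros((n, n))
    frames = traj.frames[frame_window] if frame_window else traj.frames
    chain = top.chain_ids
    res = top.residue_indices
    for frame in frames:
        for b in detect_hbonds(frame, top, scope="backbone"):
            cd, ca = chain[b.donor], chain[b.acceptor]
            if {cd, ca} != {cx, cy}:
                continue
            if cd == cx:
                i, j = res[b.donor] - res_min, res[b.acceptor] - res_min
            else:
                i, j = res[b.acceptor] - res_min, res[b.donor] - res_min
            counts[i, j] += 1
    all_zero = counts.max() == 0
    matrix = counts.copy() if all_zero else counts / counts.max()
    return HBondMap(cx, cy, matrix, counts, bool(all_zero))


def ligand_contacts(frame: Frame, top: Topology, ligand_molecule: int,
                    cutoff: float = CONTACT_CUTOFF,
                    include_protein_h: bool = False
                    ) -> set[tuple[str, int, str]]:
    """Residues in contact with one ligand copy.

    A residue is backbone-contacted if any of its backbone atoms lies within
    ``cutoff`` of any atom of the ligand copy, sidechain-contacted likewise;
    both flags may hold.  Protein hydrogens are excluded by default (heavy
    atoms only); all ligand atoms always count.
    """
    sets = _contacts_with_counts(frame, top, ligand_molecule, cutoff,
                                 include_protein_h)[0]
    return sets


def _contacts_with_counts(frame, top, ligand_molecule, cutoff,
                          include_protein_h):
    lig_idx = np.flatnonzero(top.molecule_ids == ligand_molecule)
    if lig_idx.size == 0 or not top.is_ligand_mask[lig_idx[0]]:
        raise ValueError(f"no ligand with molecule_id {ligand_molecule}")
    protein = top.protein_mask.copy()
    if not include_protein_h:
        protein &= ~top.hydrogen_mask
    pidx = np.flatnonzero(protein)
    tree = cKDTree(frame.coordinates[lig_idx])
    n_within = tree.query_ball_point(frame.coordinates[pidx], r=cutoff,
                                     return_length=True)
    contacted: set[tuple[str, int, str]] = set()
    pair_counts: dict[tuple[str, int, str], int] = {}
    bb = top.backbone_mask
    for i, cnt in zip(pidx, n_within):
        if cnt == 0:
            continue
        kind = "backbone" if bb[i] else "sidechain"
        key = (str(top.chain_ids[i]), int(top.residue_indices[i]), kind)
        contacted.add(key)
        pair_counts[key] = pair_counts.get(key, 0) + int(cnt)
    return contacted, pair_counts


def contact_profile(traj: Trajectory, ligand_ids: Iterable[int],
                    frame_window: slice | None = None,
                    probability_threshold: float = 0.1,
                    cutoff: float = CONTACT_CUTOFF,
                    include_protein_h: bool = False) -> ContactProfile:
    """Per-residue ligand-contact probabilities and mean atom-pair contact
    numbers over a frame window, plus the residues above the importance
    threshold (reported separately for backbone and sidechain)."""
    top = traj.topology
    frames = traj.frames[frame_window] if frame_window else traj.frames
    if not frames:
        raise ValueError("empty frame window")
    ligand_ids = list(ligand_ids)
    residues = sorted({(str(c), int(r)) for c, r in
                       zip(top.chain_ids[top.protein_mask],
                           top.residue_indices[top.protein_mask])})
    index = {key: i for i, key in enumerate(residues)}
    nres = len(residues)
    bb_hits = np.zeros(nres)
    sc_hits = np.zeros(nres)
    bb_counts = np.zeros(nres)
    sc_counts = np.zeros(nres)
    for frame in frames:
        frame_bb = np.zeros(nres, dtype=bool)
        frame_sc = np.zeros(nres, dtype=bool)
        for lig in ligand_ids:
            contacted, pair_counts = _contacts_with_counts(
                frame, top, lig, cutoff, include_protein_h)
            for (c, r, kind) in contacted:
                i = index[(c, r)]
                (frame_bb if kind == "backbone" else frame_sc)[i] = True
            for (c, r, kind), cnt in pair_counts.items():
                i = index[(c, r)]
                if kind == "backbone":
                    bb_counts[i] += cnt
                else:
                    sc_counts[i] += cnt
        bb_hits += frame_bb
        sc_hits += frame_sc
    nf = len(frames)
    bb_prob, sc_prob = bb_hits / nf, sc_hits / nf
    important_bb = [residues[i] for i in range(nres)
                    if bb_prob[i] > probability_threshold]
    important_sc = [residues[i] for i in range(nres)
                    if sc_prob[i] > probability_threshold]
    return ContactProfile(residues, bb_prob, sc_prob,
                          bb_counts / nf, sc_counts / nf,
                          important_bb, important_sc)


def hbond_occupancy(traj: Trajectory,
                    donor_key: tuple[str, int, str],
                    acceptor_key: tuple[str, int, str],
                    frame_window: slice | None = None,
                    scope: str = "all") -> float:
    """Fraction of window frames in which the specific donor-atom to
    acceptor-atom hydrogen bond (through any covalent hydrogen) is present."""
    top = traj.topology
    d = top.atom_index(*donor_key)
    a = top.atom_index(*acceptor_key)
    frames = traj.frames[frame_window] if frame_window else traj.frames
    hits = 0
    for frame in frames:
        bonds = detect_hbonds(frame, top, scope=scope)
        if any(b.donor == d and b.acceptor == a for b in bonds):
            hits += 1
    return hits / len(frames)


@dataclass
class StackingContact:
    ring_a: tuple[int, ...]
    ring_b: tuple[int, ...]
    geometry: str            # parallel | perpendicular | tilted
    centroid_distance: float
    interplanar_angle: float


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def pi_stacking(frame: Frame, rings_a: Sequence[Sequence[int]],
                rings_b: Sequence[Sequence[int]],
                max_centroid_distance: float = 5.5,
                parallel_max_angle: float = 30.0,
                perpendicular_min_angle: float = 60.0) -> list[StackingContact]:
    """Classify aromatic ring pairs as parallel / perpendicular / tilted
    stacking by centroid distance and interplanar angle."""
    for ring in list(rings_a) + list(rings_b):
        if len(ring) < 3:
            raise ValueError("a ring definition needs at least 3 atoms")
    out = []
    planes_a = [_ring_plane(frame.coordinates[np.asarray(r)]) for r in rings_a]
    planes_b = [_ring_plane(frame.coordinates[np.asarray(r)]) for r in rings_b]
    for ra, (ca, na) in zip(rings_a, planes_a):
        for rb, (cb, nb) in zip(rings_b, planes_b):
            d = float(np.linalg.norm(ca - cb))
            if d > max_centroid_distance:
                continue
            cosang = abs(float(na @ nb)) / (np.linalg.norm(na) * np.linalg.norm(nb))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if angle < parallel_max_angle:
                geometry = "parallel"
            elif angle > perpendicular_min_angle:
                geometry = "perpendicular"
            else:
                geometry = "tilted"
            out.append(StackingContact(tuple(ra), tuple(rb), geometry, d, angle))
    return out


def switching_function(r: np.ndarray | float, r_on: float = 10.0,
                       r_off: float = 12.0) -> np.ndarray | float:
    """Polynomial switch: 1 for r <= r_on, 0 for r >= r_off, C1-smooth between."""
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    s = ((off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2)) / (off2 - on2) ** 3
    s = np.where(r2 <= on2, 1.0, np.where(r2 >= off2, 0.0, s))
    return float(s) if s.ndim == 0 else s


def _require_params(top: Topology, indices: np.ndarray):
    missing = [f"{top.chain_ids[i]}:{top.residue_indices[i]}:{top.names[i]}"
               for i in indices
               if top.atoms[i].charge is None or top.atoms[i].lj_epsilon is None
               or top.atoms[i].lj_rmin_half is None]
    if missing:
        raise ValueError("missing charge/LJ parameters for atoms: "
                         + ", ".join(missing[:10])
                         + ("..." if len(missing) > 10 else ""))


def interaction_energy(traj: Trajectory | Frame, group_a: np.ndarray,
                       group_b: np.ndarray, top: Topology | None = None,
                       r_on: float = 10.0, r_off: float = 12.0) -> EnergyTrace:
    """Switched pairwise Coulomb + Lennard-Jones energy between two groups.

    Accepts a :class:`Trajectory` (per-frame trace) or a single
    :class:`Frame` with an explicit ``top``.  Charges in e, energies in
    kcal/mol; LJ uses Rmin/2 Lorentz-Berthelot combining.
    """
    if isinstance(traj, Trajectory):
        frames = traj.frames
        top = traj.topology
    else:
        if top is None:
            raise ValueError("a Topology is required with a single Frame")
        frames = [traj]
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        zero = np.zeros(len(frames))
        return EnergyTrace(zero, zero.copy())
    _require_params(top, group_a)
    _require_params(top, group_b)

    qa = np.array([top.atoms[i].charge for i in group_a])
    qb = np.array([top.atoms[i].charge for i in group_b])
    ea = np.array([top.atoms[i].lj_epsilon for i in group_a])
    eb = np.array([top.atoms[i].lj_epsilon for i in group_b])
    ra = np.array([top.atoms[i].lj_rmin_half for i in group_a])
    rb = np.array([top.atoms[i].lj_rmin_half for i in group_b])
    eps_ij = np.sqrt(ea[:, None] * eb[None, :])
    rmin_ij = ra[:, None] + rb[None, :]
    qq = qa[:, None] * qb[None, :]

    vdw, elec = [], []
    for frame in frames:
        xa = frame.coordinates[group_a]
        xb = frame.coordinates[group_b]
        diff = xa[:, None, :] - xb[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=2))
        r = np.maximum(r, 1e-6)
        s = switching_function(r, r_on, r_off)
        inv = rmin_ij / r
        lj = eps_ij * (inv ** 12 - 2.0 * inv ** 6)
        coul = COULOMB_CONSTANT * qq / r
        vdw.append(float((lj * s).sum()))
        elec.append(float((coul * s).sum()))
    return EnergyTrace(np.array(vdw), np.array(elec))
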