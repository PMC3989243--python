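"""Synthetic U-bend beta-sheet oligomer trajectories with controllable disorder.

The generator lays an idealized single-layer, parallel, in-register cross-beta
oligomer: every chain follows the amylin U-bend fold (beta-strand, turn,
beta-strand) traced in a plane, and chains are stacked along the fibril axis
at the cross-beta spacing.  Strand residues are built so that the inter-chain
amide-to-carbonyl geometry satisfies the geometric hydrogen-bond criterion by
construction (N...O = 2.9 A, donor-hydrogen-acceptor angle 180 deg); turn
residues point their carbonyls in-plane and therefore form no ladder.  The
representation is backbone (N, H, CA, C, O) plus one pseudo-sidechain atom
(CB) per non-glycine residue — enough for every analysis in this package
while staying cheap and exactly controllable.

Disorder is applied frame-wise and independently (ensemble statistics, no
dynamics): per-chain random rigid rotations degrade nematic order, targeted
displacement of donor amides breaks a chosen fraction of beta-ladder
hydrogen bonds, and terminal fraying displaces C-terminal residues of the
edge chains.  Rigid ligand copies can be anchored at a chosen surface
residue (tracking it frame by frame) or left free-floating.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, Frame, Topology, Trajectory, infer_h_parents

#: Amylin (hIAPP) 1-37 sequence as 3-letter codes.
HIAPP_SEQUENCE = (
    "LYS CYS ASN THR ALA THR CYS ALA THR GLN ARG LEU ALA ASN PHE LEU VAL "
    "HIS SER SER ASN ASN PHE GLY ALA ILE LEU SER SER THR ASN VAL GLY SER "
    "ASN THR TYR"
).split()

# Default partial charges (e) and Lennard-Jones parameters (kcal/mol, A,
# Rmin/2) for the reduced backbone representation; amide-group charges follow
# the usual protein force-field pattern and each residue is net neutral.
# Radii are compact (Rmin_ij ~ 2.4 A between heavy atoms) so that the
# 2.5-3.5 A surface-contact window used throughout the package falls on the
# attractive branch of the 12-6 potential.
_PROTEIN_PARAMS = {
    "N": (-0.04, 0.40, 1.20),
    "H": (0.03, 0.03, 0.20),
    "CA": (0.01, 0.45, 1.25),
    "C": (0.04, 0.45, 1.25),
    "O": (-0.04, 0.40, 1.15),
    "CB": (0.00, 0.50, 1.30),
}


@dataclass
class OligomerSpec:
    """Geometry of the ordered U-bend oligomer template.

    Residue ranges are inclusive and must partition ``1..n_residues``.
    ``interchain_spacing`` is the cross-beta stacking distance along the
    fibril axis; ``rise_per_residue`` the in-strand C-alpha spacing.
    """

    n_chains: int = 5
    n_residues: int = 37
    strand1: tuple[int, int] = (1, 17)
    turn: tuple[int, int] = (18, 27)
    strand2: tuple[int, int] = (28, 37)
    interchain_spacing: float = 4.8
    rise_per_residue: float = 3.4
    turn_width: float = 10.0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("an oligomer requires at least 2 chains")
        if (self.interchain_spacing <= 0 or self.rise_per_residue <= 0
                or self.turn_width <= 0):
            raise ValueError("spacings must be positive")
        s1, t, s2 = self.strand1, self.turn, self.strand2
        if not (s1[0] == 1 and s1[1] + 1 == t[0] and t[1] + 1 == s2[0]
                and s2[1] == self.n_residues):
            raise ValueError("strand1/turn/strand2 must partition 1..n_residues")

    @property
    def strand_residues(self) -> list[int]:
        return (list(range(self.strand1[0], self.strand1[1] + 1))
                + list(range(self.strand2[0], self.strand2[1] + 1)))

    @property
    def turn_residues(self) -> list[int]:
        return list(range(self.turn[0], self.turn[1] + 1))


@dataclass
class DisorderSpec:
    """Frame-wise disorder magnitudes.

    orientation_sigma:
        Std-dev (degrees) of an independent random rotation of each chain
        about its centroid; degrades nematic order and breaks in-register
        hydrogen bonding.
    fray_terminal:
        Number of C-terminal residues of each edge chain displaced off the
        lattice (terminal fraying).
    ladder_break_fraction:
        Fraction of the constructed inter-chain backbone H-bond geometries
        broken per frame by displacing the donor amide laterally.
    """

    orientation_sigma: float = 0.0
    fray_terminal: int = 0
    ladder_break_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ladder_break_fraction <= 1.0:
            raise ValueError("ladder_break_fraction must be in [0, 1]")
        if self.orientation_sigma < 0 or self.fray_terminal < 0:
            raise ValueError("disorder magnitudes must be non-negative")


@dataclass
class LigandPlacement:
    """Placement request for rigid ligand copies.

    ``site`` lists anchor residues as ``(chain_id, residue_index)``; ``None``
    places free-floating (diffusing) copies instead.  ``offset`` is the gap
    between the nearest ligand atom and the anchor surface.
    """

    template: "LigandTemplate | None" = None
    site: list[tuple[str, int]] | None = None
    offset: float = 3.0
    n_copies: int = 1


@dataclass
class LigandTemplate:
    """Rigid ligand atom set: names, elements, charges, LJ, local coordinates."""

    names: list[str]
    elements: list[str]
    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_rmin_half: np.ndarray
    coordinates: np.ndarray
    resname: str = "EGC"

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.coordinates = self.coordinates - self.coordinates.mean(axis=0)
        has_donor = any(e.upper() == "H" for e in self.elements)
        has_acceptor = any(e.upper() in ("O", "N") for e in self.elements)
        if not (has_donor and has_acceptor):
            raise ValueError("ligand template needs >=1 donor-capable and "
                             ">=1 acceptor-capable atom")


def default_ligand_template() -> LigandTemplate:
    """Three-ring rigid polyphenol caricature with hydroxyl donors.

    Two hydroxylated six-carbon rings joined by an ester-linked third ring,
    all near-planar — a stand-in with the donor/acceptor and aromatic-ring
    inventory the analyses need, not real ligand coordinates.
    """
    names, elements, coords = [], [], []
    charges, eps, rmin = [], [], []

    def ring(center, label_start, tilt=0.0):
        idx = []
        for k in range(6):
            ang = math.radians(60 * k + tilt)
            coords.append([center[0] + 1.4 * math.cos(ang),
                           center[1] + 1.4 * math.sin(ang),
                           center[2]])
            names.append(f"C{label_start + k}")
            elements.append("C")
            charges.append(0.0)
            eps.append(0.45)
            rmin.append(1.25)
            idx.append(len(names) - 1)
        return idx

    r1 = ring((0.0, 0.0, 0.0), 1)
    r2 = ring((4.9, 0.0, 0.0), 7)
    r3 = ring((2.45, 4.25, 0.3), 13)

    def hydroxyl(on_index, o_name, h_name, ring_center):
        c = np.array(coords[on_index])
        out = c - np.array(ring_center)
        out[2] = 0.0
        out = out / np.linalg.norm(out)
        o = c + 1.36 * out
        h = o + 0.97 * out
        for name, el, xyz, q, e, r in ((o_name, "O", o, -0.05, 0.40, 1.15),
                                       (h_name, "H", h, 0.05, 0.03, 0.20)):
            names.append(name)
            elements.append(el)
            coords.append(list(xyz))
            charges.append(q)
            eps.append(e)
            rmin.append(r)

    hydroxyl(r1[1], "O1", "HO1", (0.0, 0.0, 0.0))
    hydroxyl(r1[3], "O2", "HO2", (0.0, 0.0, 0.0))
    hydroxyl(r2[2], "O3", "HO3", (4.9, 0.0, 0.0))
    hydroxyl(r3[1], "O4", "HO4", (2.45, 4.25, 0.3))
    # ester oxygen bridging rings 1 and 2
    names.append("O5")
    elements.append("O")
    coords.append([2.45, 0.0, 0.0])
    charges.append(-0.04)
    eps.append(0.40)
    rmin.append(1.15)
    charges[r1[0]] += 0.02
    charges[r2[3]] += 0.02

    return LigandTemplate(names, elements, np.array(charges), np.array(eps),
                          np.array(rmin), np.array(coords))


@dataclass
class OligomerSystem:
    """Built template plus the construction bookkeeping the disorder transforms
    and the tests-as-ground-truth need."""

    topology: Topology
    frame: Frame
    spec: OligomerSpec
    #: (donor_chain_index, acceptor_chain_index, residue_index) per constructed
    #: inter-chain backbone H-bond.
    ladder_bonds: list[tuple[int, int, int]]
    #: in-plane outward normal per (chain, residue), shape (n_chains, n_residues, 3)
    residue_normals: np.ndarray


def _chain_path(spec: OligomerSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane C-alpha path plus tangent and outward normal per residue."""
    n = spec.n_residues
    rise = spec.rise_per_residue
    pos = np.zeros((n, 2))
    tan = np.zeros((n, 2))
    out = np.zeros((n, 2))

    s1_lo, s1_hi = spec.strand1
    t_lo, t_hi = spec.turn
    s2_lo, s2_hi = spec.strand2
    nt = t_hi - t_lo + 1
    # tight semicircular arc: the two antiparallel strands of the U sit
    # turn_width apart, like the sheet separation of real U-bend folds
    radius = spec.turn_width / 2.0
    x_end = (s1_hi - s1_lo) * rise
    center = np.array([x_end, radius])

    for r in range(s1_lo, s1_hi + 1):
        i = r - 1
        pos[i] = [(r - s1_lo) * rise, 0.0]
        tan[i] = [1.0, 0.0]
        out[i] = [0.0, -1.0]
    for k, r in enumerate(range(t_lo, t_hi + 1), start=1):
        i = r - 1
        theta = -math.pi / 2 + k * math.pi / (nt + 1)
        pos[i] = center + radius * np.array([math.cos(theta), math.sin(theta)])
        tan[i] = [-math.sin(theta), math.cos(theta)]
        out[i] = [math.cos(theta), math.sin(theta)]
    for r in range(s2_lo, s2_hi + 1):
        i = r - 1
        pos[i] = [x_end - (r - s2_lo) * rise, 2 * radius]
        tan[i] = [-1.0, 0.0]
        out[i] = [0.0, 1.0]
    return pos, tan, out


def build_ordered_oligomer(spec: OligomerSpec | None = None) -> OligomerSystem:
    """Build the perfectly ordered parallel in-register oligomer template."""
    spec = spec or OligomerSpec()
    if spec.n_chains > 26:
        raise ValueError("at most 26 chains (single-letter chain ids)")
    seq = _sequence_for(spec.n_residues)
    pos2d, tan2d, out2d = _chain_path(spec)
    strand = set(spec.strand_residues)

    atoms: list[AtomRecord] = []
    coords: list[list[float]] = []
    normals = np.zeros((spec.n_chains, spec.n_residues, 3))
    serial = 1
    for ci in range(spec.n_chains):
        chain_id = chr(ord("A") + ci)
        z = ci * spec.interchain_spacing
        for r in range(1, spec.n_residues + 1):
            i = r - 1
            resname = seq[i]
            p, t, o = pos2d[i], tan2d[i], out2d[i]
            normals[ci, i] = [o[0], o[1], 0.0]
            n_xy = p - 0.6 * t
            c_xy = p + 0.5 * t
            residue_atoms: list[tuple[str, str, list[float]]] = [
                ("N", "N", [n_xy[0], n_xy[1], z]),
                ("CA", "C", [p[0], p[1], z]),
                ("C", "C", [c_xy[0], c_xy[1], z]),
            ]
            if r in strand:
                # carbonyl O sits on the donor rail of the next chain:
                # colinear N-H...O along the fibril axis, N...O = 2.9 A
                residue_atoms.append(("O", "O", [n_xy[0], n_xy[1],
                                                 z + spec.interchain_spacing - 2.9]))
                residue_atoms.insert(1, ("H", "H", [n_xy[0], n_xy[1], z - 1.0]))
            else:
                o_xy = c_xy + 1.23 * o
                h_xy = n_xy + 1.00 * o
                residue_atoms.append(("O", "O", [o_xy[0], o_xy[1], z]))
                residue_atoms.insert(1, ("H", "H", [h_xy[0], h_xy[1], z]))
            if resname != "GLY":
                cb_xy = p + 1.5 * o
                residue_atoms.append(("CB", "C", [cb_xy[0], cb_xy[1], z]))
            for name, element, xyz in residue_atoms:
                q, e, rm = _PROTEIN_PARAMS[name]
                atoms.append(AtomRecord(
                    serial=serial, name=name, element=element, chain_id=chain_id,
                    residue_index=r, residue_name=resname,
                    charge=q, lj_epsilon=e, lj_rmin_half=rm))
                coords.append(xyz)
                serial += 1

    parents = infer_h_parents(atoms)
    top = Topology(atoms, parents)
    frame = Frame(np.array(coords), time=0.0)
    ladder = [(c + 1, c, r) for c in range(spec.n_chains - 1)
              for r in spec.strand_residues]
    return OligomerSystem(top, frame, spec, ladder, normals)


def _sequence_for(n_residues: int) -> list[str]:
    if n_residues == 37:
        return list(HIAPP_SEQUENCE)
    seq = (HIAPP_SEQUENCE * (n_residues // 37 + 1))[:n_residues]
    return seq


def expected_interchain_hbonds(spec: OligomerSpec) -> int:
    """Ground-truth inter-chain backbone H-bond count of the ordered template."""
    return (spec.n_chains - 1) * len(spec.strand_residues)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def generate_trajectory(system: OligomerSystem,
                        disorder: DisorderSpec | None = None,
                        n_frames: int = 1,
                        timestep: float = 1.0) -> Trajectory:
    """Generate a trajectory of independently perturbed copies of the template.

    With all disorder magnitudes zero every frame equals the base template.
    Fully deterministic for a fixed :attr:`DisorderSpec.seed`.
    """
    disorder = disorder or DisorderSpec()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    spec = system.spec
    top = system.topology
    rng = np.random.default_rng(disorder.seed)

    chain_atom_idx = [np.flatnonzero(top.chain_ids == chr(ord("A") + ci))
                      for ci in range(spec.n_chains)]
    amide_idx = {}  # (chain_index, residue) -> indices of N and H
    for ci in range(spec.n_chains):
        cid = chr(ord("A") + ci)
        for r in range(1, spec.n_residues + 1):
            mask = ((top.chain_ids == cid) & (top.residue_indices == r)
                    & np.isin(top.names, ["N", "H"]))
            amide_idx[(ci, r)] = np.flatnonzero(mask)
    residue_idx = {}
    for ci in range(spec.n_chains):
        cid = chr(ord("A") + ci)
        for r in range(1, spec.n_residues + 1):
            residue_idx[(ci, r)] = np.flatnonzero(
                (top.chain_ids == cid) & (top.residue_indices == r))

    frames = []
    n_bonds = len(system.ladder_bonds)
    for f in range(n_frames):
        coords = system.frame.coordinates.copy()
        # 1) ladder breakage: displace donor amide laterally off the rail
        if disorder.ladder_break_fraction > 0 and n_bonds:
            n_break = int(round(disorder.ladder_break_fraction * n_bonds))
            chosen = rng.choice(n_bonds, size=n_break, replace=False)
            for b in chosen:
                donor_chain, _, r = system.ladder_bonds[b]
                shift = 2.5 * system.residue_normals[donor_chain, r - 1]
                coords[amide_idx[(donor_chain, r)]] += shift
        # 2) terminal fraying on the two edge chains
        if disorder.fray_terminal > 0:
            for ci in (0, spec.n_chains - 1):
                for j in range(disorder.fray_terminal):
                    r = spec.n_residues - j
                    if r < 1:
                        break
                    base = 3.0 * system.residue_normals[ci, r - 1]
                    jitter = rng.normal(0.0, 1.5, size=3)
                    coords[residue_idx[(ci, r)]] += base + jitter
        # 3) per-chain random rigid rotation about the chain centroid
        if disorder.orientation_sigma > 0:
            sigma = math.radians(disorder.orientation_sigma)
            for ci in range(spec.n_chains):
                axis = rng.normal(size=3)
                angle = rng.normal(0.0, sigma)
                rot = _rotation_matrix(axis, angle)
                idx = chain_atom_idx[ci]
                centroid = coords[idx].mean(axis=0)
                coords[idx] = (coords[idx] - centroid) @ rot.T + centroid
        frames.append(Frame(coords, time=f * timestep))
    return Trajectory(top, frames, timestep=timestep)


def place_ligands(traj: Trajectory,
                  placement: LigandPlacement,
                  seed: int = 0,
                  max_retries: int = 120) -> Trajectory:
    """Insert rigid ligand copies into every frame of a trajectory.

    Anchored copies (``placement.site`` given) are positioned frame by frame
    just off the surface of the anchor residue: nearest ligand atom within
    the contact cutoff of an anchor atom but no closer than 2.5 A to any
    protein atom.  Free copies (``site=None``) are re-placed each frame at a
    random position outside the protein envelope (diffusing, no persistent
    contacts).  Copies never overlap each other below 2.5 A.
    """
    if placement.n_copies == 0:
        return traj
    template = placement.template or default_ligand_template()
    top = traj.topology
    rng = np.random.default_rng(seed)

    protein_idx = np.flatnonzero(top.protein_mask)
    if placement.site is not None:
        for chain_id, res in placement.site:
            if not np.any((top.chain_ids == chain_id)
                          & (top.residue_indices == res) & top.protein_mask):
                raise ValueError(f"anchor residue {chain_id}:{res} does not exist")
        anchor_idx = np.flatnonzero(
            np.any([(top.chain_ids == c) & (top.residue_indices == r)
                    for c, r in placement.site], axis=0) & top.protein_mask)
    else:
        anchor_idx = None

    next_mol = max([0] + [a.molecule_id for a in top.atoms]) + 1
    new_atoms = list(top.atoms)
    serial = max(a.serial for a in top.atoms) + 1
    lig_chain = "0"  # digits never collide with protein chain letters
    existing_lig_res = [a.residue_index for a in top.atoms
                        if a.is_ligand and a.chain_id == lig_chain]
    next_res = max([0] + existing_lig_res) + 1
    copy_rotations = [_rotation_matrix(rng.normal(size=3),
                                       rng.uniform(0, 2 * math.pi))
                      for _ in range(placement.n_copies)]
    for k in range(placement.n_copies):
        for name, element, q, e, rm in zip(template.names, template.elements,
                                           template.charges, template.lj_epsilon,
                                           template.lj_rmin_half):
            new_atoms.append(AtomRecord(
                serial=serial, name=name, element=element, chain_id=lig_chain,
                residue_index=next_res + k, residue_name=template.resname,
                is_ligand=True, molecule_id=next_mol + k,
                charge=float(q), lj_epsilon=float(e), lj_rmin_half=float(rm)))
            serial += 1
    parents = infer_h_parents(new_atoms)
    new_top = Topology(new_atoms, parents)

    n_t = len(template.names)
    new_frames = []
    placed_prev: list[np.ndarray | None] = [None] * placement.n_copies
    pose_cache: list[tuple | None] = [None] * placement.n_copies
    for frame in traj.frames:
        pcoords = frame.coordinates[protein_idx]
        tree = cKDTree(pcoords)
        centroid = pcoords.mean(axis=0)
        occupied: list[np.ndarray] = []
        lig_coords = np.zeros((placement.n_copies * n_t, 3))
        for k in range(placement.n_copies):
            if anchor_idx is not None:
                pos, pose = _place_anchored(frame.coordinates[anchor_idx],
                                            centroid, template,
                                            copy_rotations[k], tree,
                                            occupied, placement.offset, rng,
                                            max_retries,
                                            prev_pose=pose_cache[k])
                if pose is not None:
                    pose_cache[k] = pose
                if pos is None:
                    if placed_prev[k] is not None:
                        pos = placed_prev[k]
                    else:
                        site = placement.site
                        raise RuntimeError(
                            f"could not place ligand copy {k + 1} at site {site} "
                            f"after {max_retries} retries")
            else:
                pos = _place_free(centroid, pcoords, template, tree, occupied,
                                  rng, max_retries)
            placed_prev[k] = pos
            occupied.append(pos)
            lig_coords[k * n_t:(k + 1) * n_t] = pos
        new_frames.append(Frame(np.vstack([frame.coordinates, lig_coords]),
                                time=frame.time))
    return Trajectory(new_top, new_frames, timestep=traj.timestep,
                      superposed=traj.superposed)


def _min_dist_to(occupied: list[np.ndarray], pos: np.ndarray) -> float:
    if not occupied:
        return np.inf
    return min(float(np.min(np.linalg.norm(pos[:, None, :] - occ[None, :, :],
                                           axis=-1))) for occ in occupied)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        return _rotation_matrix(axis, math.pi)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1.0 + c)


def _place_anchored(anchor_coords, centroid, template, rotation, tree,
                    occupied, offset, rng, max_retries, prev_pose=None):
    """Tip-first placement: the template's most protruding atom is pointed at
    the anchor and the standoff is scanned for the gap closest to ``offset``
    that clears the protein (>= 2.5 A) while keeping an anchor atom within
    the contact cutoff."""
    aref = anchor_coords.mean(axis=0)
    # local surface normal: plane-fit the protein patch around the anchor and
    # take the low-variance axis, signed away from the local protein mass
    nearby = tree.query_ball_point(aref, r=10.0)
    patch = np.asarray(tree.data)[nearby] if nearby else None
    if patch is not None and patch.shape[0] >= 8:
        center = patch.mean(axis=0)
        _, _, vt = np.linalg.svd(patch - center)
        direction = vt[2]
        # sign: away from the protein bulk, not the (nearly coincident) patch
        if direction @ (aref - centroid) < 0:
            direction = -direction
    else:
        direction = aref - centroid
        norm = np.linalg.norm(direction)
        direction = (direction / norm if norm > 1e-9
                     else np.array([0.0, 0.0, 1.0]))
    base = template.coordinates @ rotation.T  # per-copy random spin
    tip = base[np.argmax(np.linalg.norm(base, axis=1))]
    for attempt in range(max_retries + 1):
        if attempt == 0 and prev_pose is not None:
            d_t, rot = prev_pose  # keep the pose coherent across frames
        elif attempt <= 1:
            d_t = direction
            rot = _rotation_between(tip, -d_t)
        else:  # tilt the approach inside a cone and respin
            d_t = direction + rng.normal(0.0, 0.35, size=3)
            d_t = d_t / np.linalg.norm(d_t)
            spin = _rotation_matrix(d_t, rng.uniform(0, 2 * math.pi))
            rot = spin @ _rotation_between(tip, -d_t)
        q = base @ rot.T
        best = None
        for s in np.arange(1.0, 16.0, 0.2):
            pos = aref + d_t * s + q
            d_protein, _ = tree.query(pos)
            if d_protein.min() < 2.5:
                continue
            d_anchor = np.min(np.linalg.norm(
                pos[:, None, :] - anchor_coords[None, :, :], axis=-1))
            if d_anchor > 3.45:
                break  # moving further out only widens the gap
            if _min_dist_to(occupied, pos) < 2.5:
                continue
            score = abs(d_anchor - offset)
            if best is None or score < best[0]:
                best = (score, pos)
        if best is not None:
            return best[1], (d_t, rot)
    return None, None


def _place_free(centroid, pcoords, template, tree, occupied, rng, max_retries):
    radius = float(np.max(np.linalg.norm(pcoords - centroid, axis=1)))
    rot0 = _rotation_matrix(rng.normal(size=3), rng.uniform(0, 2 * math.pi))
    for attempt in range(max_retries):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = radius + rng.uniform(4.0, 20.0) + attempt
        pos = centroid + direction * dist + template.coordinates @ rot0.T
        d_protein, _ = tree.query(pos)
        if d_protein.min() >= 2.5 and _min_dist_to(occupied, pos) >= 2.5:
            return pos
    raise RuntimeError("could not place a free ligand copy")
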