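"""Shared fixtures: small synthetic systems every module can analyze."""
from __future__ import annotations

import numpy as np
import pytest

from oligodestab import synth
from oligodestab.model import AtomRecord, Frame, Topology, Trajectory, infer_h_parents


@pytest.fixture(scope="session")
def ordered_pentamer():
    """Perfectly ordered 5-chain U-bend oligomer template."""
    return synth.build_ordered_oligomer(synth.OligomerSpec(n_chains=5))


@pytest.fixture(scope="session")
def ordered_dimer():
    return synth.build_ordered_oligomer(synth.OligomerSpec(n_chains=2))


def make_ca_chains(vectors: np.ndarray, length: float = 10.0) -> tuple[Topology, Frame]:
    """Minimal topology of one 2-residue C-alpha pair per chain, laid along
    the given direction vectors (for order-parameter tests)."""
    vectors = np.asarray(vectors, dtype=float)
    atoms, coords = [], []
    serial = 1
    for i, v in enumerate(vectors):
        chain = _chain_label(i)
        origin = np.array([3.0 * i, 0.0, 0.0])
        v = v / np.linalg.norm(v)
        for res, xyz in ((1, origin), (2, origin + length * v)):
            atoms.append(AtomRecord(serial=serial, name="CA", element="C",
                                    chain_id=chain, residue_index=res,
                                    residue_name="ALA"))
            coords.append(xyz)
            serial += 1
    return Topology(atoms), Frame(np.array(coords))


def _chain_label(i: int) -> str:
    # ASCII printable run long enough for thousands of chains is impossible
    # with single letters; chain ids only need uniqueness here
    alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
                "0123456789")
    label = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, len(alphabet))
        label = alphabet[rem] + label
    return label


def make_synthetic_helix(n_residues: int = 12) -> tuple[Topology, Frame]:
    """Backbone trace with an ideal i -> i+4 hydrogen-bond ladder.

    A synthetic stand-in: C=O vectors are pointed straight at the amide
    nitrogen four residues up so the geometric H-bond criterion holds by
    construction; it is not a physically proportioned alpha-helix.
    """
    ca = np.array([[2.3 * np.cos(np.radians(100 * i)),
                    2.3 * np.sin(np.radians(100 * i)),
                    1.5 * i] for i in range(n_residues)])
    n = ca + np.array([0.0, 0.0, -0.4])
    c = ca + np.array([0.0, 0.0, 0.4])
    o = np.zeros_like(ca)
    h = np.zeros_like(ca)
    for i in range(n_residues):
        if i + 4 < n_residues:
            u = n[i + 4] - c[i]
            o[i] = n[i + 4] - 2.9 * u / np.linalg.norm(u)
        else:
            o[i] = c[i] + np.array([0.0, 0.0, 1.23])
        if i - 4 >= 0:
            u = o[i - 4] - n[i]
            h[i] = n[i] + u / np.linalg.norm(u)
        else:
            radial = np.array([ca[i][0], ca[i][1], 0.0])
            h[i] = n[i] + radial / np.linalg.norm(radial)
    atoms, coords = [], []
    serial = 1
    for i in range(n_residues):
        for name, element, xyz in (("N", "N", n[i]), ("H", "H", h[i]),
                                   ("CA", "C", ca[i]), ("C", "C", c[i]),
                                   ("O", "O", o[i])):
            atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                    chain_id="A", residue_index=i + 1,
                                    residue_name="ALA"))
            coords.append(xyz)
            serial += 1
    top = Topology(atoms, infer_h_parents(atoms))
    return top, Frame(np.array(coords))


def make_hbond_fixture(n_triplets: int, seed: int, box: float = 18.0
                       ) -> tuple[Topology, Frame]:
    """Random soup of N-H donor pairs and O acceptors for detector tests."""
    rng = np.random.default_rng(seed)
    atoms, coords = [], []
    serial = 1
    for i in range(n_triplets):
        base = rng.uniform(0, box, size=3)
        npos = base
        hpos = base + rng.normal(0, 0.5, size=3)
        opos = rng.uniform(0, box, size=3)
        for name, element, xyz in (("N", "N", npos), ("H", "H", hpos),
                                   ("O", "O", opos)):
            atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                    chain_id="A", residue_index=i + 1,
                                    residue_name="GLY"))
            coords.append(xyz)
            serial += 1
    top = Topology(atoms, infer_h_parents(atoms))
    return top, Frame(np.array(coords))


def brute_force_hbonds(frame: Frame, top: Topology,
                       distance_cutoff: float = 3.5,
                       angle_cutoff: float = 150.0) -> set[tuple[int, int, int]]:
    """Independent O(n^2) oracle for the geometric H-bond criterion."""
    found = set()
    acceptors = [i for i in range(len(top))
                 if top.elements[i] in ("N", "O")]
    for hydrogen, donor in top.covalent_h_parents.items():
        if top.elements[donor] not in ("N", "O"):
            continue
        for a in acceptors:
            if (top.chain_ids[a] == top.chain_ids[donor]
                    and top.residue_indices[a] == top.residue_indices[donor]):
                continue
            d_vec = frame.coordinates[a] - frame.coordinates[donor]
            dist = float(np.linalg.norm(d_vec))
            if dist >= distance_cutoff:
                continue
            v1 = frame.coordinates[donor] - frame.coordinates[hydrogen]
            v2 = frame.coordinates[a] - frame.coordinates[hydrogen]
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if angle > angle_cutoff:
                found.add((donor, hydrogen, a))
    return found


def two_state_trajectory(system, n_a: int = 60, n_b: int = 40) -> Trajectory:
    """Trajectory alternating between an ordered and a disordered conformer
    (exact copies, so cluster occupancies are known exactly)."""
    frame_a = synth.generate_trajectory(
        system, synth.DisorderSpec(seed=1), 1).frames[0]
    frame_b = synth.generate_trajectory(
        system, synth.DisorderSpec(orientation_sigma=50, fray_terminal=6,
                                   ladder_break_fraction=0.6, seed=2),
        1).frames[0]
    frames = []
    for i in range(n_a + n_b):
        src = frame_a if i < n_a else frame_b
        frames.append(Frame(src.coordinates.copy(), float(i)))
    return Trajectory(system.topology, frames)
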