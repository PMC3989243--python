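"""STRIDE-like secondary-structure assignment from backbone hydrogen bonds.

The assignment follows the Kabsch-Sander hydrogen-bond topology, driven by
the geometric H-bond criterion of :mod:`oligodestab.interactions` (the
original STRIDE mixes in empirical dihedral propensities whose constants are
not published; exact parity with STRIDE is explicitly not a goal here).  The
output alphabet is the usual six letters:

    H  alpha-helix          (two consecutive i -> i+4 backbone H-bonds)
    G  3-10 helix           (two consecutive i -> i+3 backbone H-bonds)
    E  extended strand      (bridge residue in a ladder of >= 2)
    B  isolated bridge
    T  turn                 (single helical turn, or C-alpha(i)-C-alpha(i+3)
                             chain reversal below 7 A)
    C  coil                 (everything else)

with priority H > G > E > B > T > C on conflicts.  A bridge is a backbone
H-bond between residues of different chains or sequence-separated by more
than 4 within a chain; two bridges on adjacent residues whose partners are
adjacent (same partner chain, partner indices within 2) form a ladder.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import HBond, detect_hbonds
from .model import Frame, Topology, Trajectory

TURN_CA_DISTANCE = 7.0  # A, C-alpha(i)..C-alpha(i+3) chain-reversal fallback
_PRIORITY = {"H": 5, "G": 4, "E": 3, "B": 2, "T": 1, "C": 0}


@dataclass
class SSAssignment:
    """Per-frame, per-(chain, residue) labels over {H, G, E, B, T, C}."""

    labels: np.ndarray            # (n_frames, n_chains, n_residues), '<U1'
    chains: list[str]
    residue_indices: np.ndarray   # (n_residues,)
    times: np.ndarray


@dataclass
class SSContent:
    """Per-frame secondary-structure fractions and their window averages."""

    coil: np.ndarray
    turn: np.ndarray
    beta: np.ndarray
    helix: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        return {name: (float(series.mean()), float(series.std()))
                for name, series in (("coil", self.coil), ("turn", self.turn),
                                     ("beta", self.beta), ("helix", self.helix))}


def assign_secondary_structure(frame: Frame, top: Topology,
                               hbonds: Sequence[HBond] | None = None
                               ) -> np.ndarray:
    """Assign one label per (chain, residue) for a single frame.

    ``hbonds`` are backbone-scope H-bonds for the frame; they are detected on
    the fly when omitted.  Residues with missing backbone atoms are labelled
    C with a warning.
    """
    if hbonds is None:
        hbonds = detect_hbonds(frame, top, scope="backbone")
    chains = top.chains
    res_ids = np.unique(top.residue_indices[top.protein_mask])
    n_res = res_ids.size
    res_pos = {r: i for i, r in enumerate(res_ids)}
    chain_pos = {c: i for i, c in enumerate(chains)}
    labels = np.full((len(chains), n_res), "C", dtype="<U1")

    # --- index H-bonds by donor/acceptor residue ---------------------------
    turn3 = set()   # (chain, acceptor residue) with N-H(i+3) -> O(i)
    turn4 = set()
    bridges: dict[tuple[str, int], set[tuple[str, int]]] = {}
    cid, rid = top.chain_ids, top.residue_indices
    for b in hbonds:
        dc, dr = cid[b.donor], int(rid[b.donor])
        ac, ar = cid[b.acceptor], int(rid[b.acceptor])
        if dc == ac:
            sep = dr - ar
            if sep == 3:
                turn3.add((ac, ar))
            elif sep == 4:
                turn4.add((ac, ar))
            elif abs(sep) > 4:
                bridges.setdefault((dc, dr), set()).add((ac, ar))
                bridges.setdefault((ac, ar), set()).add((dc, dr))
        else:
            bridges.setdefault((dc, dr), set()).add((ac, ar))
            bridges.setdefault((ac, ar), set()).add((dc, dr))

    def put(chain, residue, label):
        ci, ri = chain_pos.get(chain), res_pos.get(residue)
        if ci is None or ri is None:
            return
        if _PRIORITY[label] > _PRIORITY[labels[ci, ri]]:
            labels[ci, ri] = label

    # --- helices: two consecutive turns ------------------------------------
    for chain in chains:
        for r in res_ids:
            if (chain, r) in turn4 and (chain, r + 1) in turn4:
                for k in range(1, 5):
                    put(chain, r + k, "H")
            if (chain, r) in turn3 and (chain, r + 1) in turn3:
                for k in range(1, 4):
                    put(chain, r + k, "G")

    # --- strands: ladders of adjacent bridges ------------------------------
    for (chain, r), partners in bridges.items():
        in_ladder = False
        for (pc, pr) in partners:
            for dr in (-1, 1):
                for (qc, qr) in bridges.get((chain, r + dr), ()):
                    if qc == pc and abs(qr - pr) <= 2:
                        in_ladder = True
        put(chain, r, "E" if in_ladder else "B")

    # --- turns --------------------------------------------------------------
    for (chain, r) in turn3 | turn4:
        span = 3 if (chain, r) in turn3 else 4
        for k in range(1, span):
            put(chain, r + k, "T")
    # geometric chain-reversal fallback
    ca = top.calpha_mask
    for chain in chains:
        mask = ca & (top.chain_ids == chain)
        idx = np.flatnonzero(mask)
        r_of = top.residue_indices[idx]
        order = np.argsort(r_of)
        idx, r_of = idx[order], r_of[order]
        pos_by_res = dict(zip(r_of.tolist(), idx.tolist()))
        for r in r_of:
            j = pos_by_res.get(r + 3)
            if j is None:
                continue
            d = np.linalg.norm(frame.coordinates[pos_by_res[r]]
                               - frame.coordinates[j])
            if d < TURN_CA_DISTANCE:
                put(chain, r + 1, "T")
                put(chain, r + 2, "T")

    # --- residues with missing backbone ------------------------------------
    needed = {"N", "CA", "C", "O"}
    present_names: dict[tuple[str, int], set[str]] = {}
    for a in top.atoms:
        if not a.is_ligand:
            present_names.setdefault((a.chain_id, a.residue_index),
                                     set()).add(a.name)
    for (chain, r), present in present_names.items():
        if not needed <= present:
            labels[chain_pos[chain], res_pos[r]] = "C"
            warnings.warn(f"residue {chain}:{r} is missing backbone atoms "
                          f"{sorted(needed - present)}; labelled C")
    return labels


def assign_trajectory(traj: Trajectory) -> SSAssignment:
    """Assign secondary structure for every frame of a trajectory."""
    top = traj.topology
    frames_labels = [assign_secondary_structure(f, top) for f in traj.frames]
    res_ids = np.unique(top.residue_indices[top.protein_mask])
    return SSAssignment(np.stack(frames_labels), top.chains, res_ids,
                        traj.times())


def beta_content(assignment: SSAssignment, include_bridges: bool = True,
                 frame_window: slice | None = None
                 ) -> tuple[np.ndarray, float, float]:
    """Per-frame beta fraction (#residues in {E, B} over all residues) plus
    mean and standard deviation over an optional frame window."""
    letters = ("E", "B") if include_bridges else ("E",)
    lab = assignment.labels
    per_frame = np.isin(lab, letters).reshape(lab.shape[0], -1).mean(axis=1)
    window = per_frame[frame_window] if frame_window else per_frame
    return per_frame, float(window.mean()), float(window.std())


def ss_content(assignment: SSAssignment) -> SSContent:
    lab = assignment.labels
    flat = lab.reshape(lab.shape[0], -1)
    return SSContent(
        coil=np.mean(flat == "C", axis=1),
        turn=np.mean(flat == "T", axis=1),
        beta=np.mean(np.isin(flat, ("E", "B")), axis=1),
        helix=np.mean(np.isin(flat, ("H", "G")), axis=1),
    )


def ss_timeline(assignment: SSAssignment) -> pd.DataFrame:
    """Long-format (time, chain, residue, label) table for raster plotting."""
    records = []
    for fi, t in enumerate(assignment.times):
        for ci, chain in enumerate(assignment.chains):
            for ri, r in enumerate(assignment.residue_indices):
                records.append((t, chain, int(r), assignment.labels[fi, ci, ri]))
    return pd.DataFrame.from_records(
        records, columns=["time", "chain", "residue", "label"])
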