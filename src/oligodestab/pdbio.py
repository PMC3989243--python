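"""Reading and writing multi-model PDB trajectories and CSV series tables.

Multi-model PDB is the required interchange dialect: each MODEL block is one
saved frame.  Parsing goes through Biopython's PDB parser; a light second
pass collects CONECT records (Biopython discards them) so that non-standard
hydrogen names can still be parented.
"""
from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .model import AtomRecord, Frame, Topology, Trajectory, infer_h_parents


def read_multimodel_pdb(path: str | Path,
                        ligand_resnames: Iterable[str] = (),
                        timestep: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Atoms whose residue name is in ``ligand_resnames`` are flagged as ligand
    atoms, with one ``molecule_id`` per contiguous ligand residue.  All models
    must contain the same atoms in the same order; a mismatch is rejected
    naming the offending model.
    """
    path = Path(path)
    ligand_resnames = {r.upper() for r in ligand_resnames}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython is chatty about nonstandard files
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))

    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no coordinate models found")

    def atom_keys(model):
        keys = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    keys.append((chain.id, residue.id[1], atom.get_name()))
        return keys

    ref_keys = atom_keys(models[0])
    for m in models[1:]:
        if atom_keys(m) != ref_keys:
            raise ValueError(
                f"{path}: MODEL {m.serial_num} does not match MODEL "
                f"{models[0].serial_num} atom-for-atom")

    records: list[AtomRecord] = []
    molecule_id = 0
    last_ligand_residue = None
    for chain in models[0]:
        for residue in chain:
            resname = residue.get_resname().strip().upper()
            is_ligand = resname in ligand_resnames
            if is_ligand:
                key = (chain.id, residue.id[1])
                if key != last_ligand_residue:
                    molecule_id += 1
                    last_ligand_residue = key
            for atom in residue:
                element = (atom.element or "").strip() or _guess_element(atom.get_name())
                records.append(AtomRecord(
                    serial=atom.serial_number if atom.serial_number else len(records) + 1,
                    name=atom.get_name(),
                    element=element,
                    chain_id=chain.id,
                    residue_index=residue.id[1],
                    residue_name=resname,
                    is_ligand=is_ligand,
                    molecule_id=molecule_id if is_ligand else 0,
                ))

    parents = infer_h_parents(records, _read_conect(path))
    top = Topology(records, parents)

    frames = []
    for i, model in enumerate(models):
        coords = np.array([atom.coord for chain in model
                           for residue in chain for atom in residue], dtype=float)
        frames.append(Frame(coords, time=i * timestep))
    return Trajectory(top, frames, timestep=timestep)


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _read_conect(path: Path) -> list[tuple[int, int]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CONECT"):
                fields = line[6:].split()
                if len(fields) >= 2:
                    base = int(fields[0])
                    for other in fields[1:]:
                        pairs.append((base, int(other)))
    return pairs


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    top = traj.topology
    with open(path, "w") as fh:
        for imodel, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            for i, a in enumerate(top.atoms):
                x, y, z = frame.coordinates[i]
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                record = "HETATM" if a.is_ligand else "ATOM  "
                fh.write(
                    f"{record}{a.serial % 100000:5d} {name}{'':1s}{a.residue_name:>3s} "
                    f"{a.chain_id}{a.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_series_table(rows: Sequence[Mapping[str, object]],
                       path: str | Path,
                       fieldnames: Sequence[str] | None = None) -> None:
    """Write keyed records as a comma-separated table with a header row.

    All rows must share one key set; ``fieldnames`` fixes the column order
    (and is required for an empty row list, where it supplies the header).
    """
    if rows:
        keys = list(rows[0].keys())
        for i, row in enumerate(rows[1:], start=1):
            if set(row.keys()) != set(keys):
                raise ValueError(f"row {i} keys {sorted(row)} differ from {sorted(keys)}")
        if fieldnames is None:
            fieldnames = keys
    elif fieldnames is None:
        raise ValueError("empty row list needs explicit fieldnames for the header")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(fieldnames))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
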