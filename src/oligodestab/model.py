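"""Core domain model: atoms, topologies, frames, trajectories and selections.

The containers here are deliberately light: a :class:`Topology` is an ordered
list of :class:`AtomRecord` plus cached numpy views of the columns every
analysis needs (names, chain ids, residue indices, ligand flags), and a
:class:`Frame` is nothing but a ``(n_atoms, 3)`` coordinate array in Angstrom
with a time stamp in picoseconds.  All analysis modules operate on these and
on plain integer index arrays produced by :meth:`Topology.select`.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

#: Backbone heavy-atom names (protein).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})
#: Amide / terminal hydrogen names mapped onto the backbone nitrogen.
BACKBONE_H_NAMES = frozenset({"H", "HN", "H1", "H2", "H3", "HT1", "HT2", "HT3"})

STANDARD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "CL": 35.45, "F": 18.998,
}


class SelectionError(ValueError):
    """Raised for malformed selection expressions; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class AtomRecord:
    """One atom of the system.

    ``molecule_id`` groups ligand copies: protein atoms carry 0, each rigid
    ligand copy carries its own id >= 1.  Charges are in elementary-charge
    units, Lennard-Jones parameters in kcal/mol and Angstrom (Rmin/2
    convention); both are optional and only required by the energy module.
    """

    serial: int
    name: str
    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    is_ligand: bool = False
    molecule_id: int = 0
    mass: float | None = None
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None

    def __post_init__(self):
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.is_ligand and self.molecule_id < 1:
            raise ValueError("ligand atoms require molecule_id >= 1")
        if not self.is_ligand and self.molecule_id != 0:
            raise ValueError("protein atoms must carry molecule_id == 0")
        if self.mass is None:
            self.mass = STANDARD_MASSES.get(self.element.upper(), 12.011)


class Topology:
    """Ordered atom list plus hydrogen parentage.

    Parameters
    ----------
    atoms:
        Atom records in file order.
    covalent_h_parents:
        Map from hydrogen atom index to the index of its bonded heavy atom.
        Hydrogens absent from this map are excluded from the hydrogen-bond
        donor search.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 covalent_h_parents: dict[int, int] | None = None):
        self.atoms = list(atoms)
        self.covalent_h_parents = dict(covalent_h_parents or {})
        self._validate()

    def _validate(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in topology")
            seen.add(key)
        n = len(self.atoms)
        for h, parent in self.covalent_h_parents.items():
            if not (0 <= h < n and 0 <= parent < n):
                raise ValueError("covalent_h_parents indices out of range")
            if self.atoms[h].element.upper() != "H":
                raise ValueError(f"atom {h} in covalent_h_parents is not a hydrogen")

    # -- cached column views -------------------------------------------------
    @cached_property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element.upper() for a in self.atoms])

    @cached_property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    @cached_property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    @cached_property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @cached_property
    def is_ligand_mask(self) -> np.ndarray:
        return np.array([a.is_ligand for a in self.atoms])

    @cached_property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms])

    @cached_property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    # -- structure-level properties -----------------------------------------
    @cached_property
    def chains(self) -> list[str]:
        """Protein chain ids in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if not a.is_ligand and a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @cached_property
    def ligand_molecule_ids(self) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if a.is_ligand and a.molecule_id not in out:
                out.append(a.molecule_id)
        return out

    @cached_property
    def residues_per_chain(self) -> int:
        if not self.chains:
            return 0
        c = self.chains[0]
        mask = (self.chain_ids == c) & ~self.is_ligand_mask
        return len(np.unique(self.residue_indices[mask]))

    def __len__(self) -> int:
        return len(self.atoms)

    # -- masks ---------------------------------------------------------------
    @cached_property
    def protein_mask(self) -> np.ndarray:
        return ~self.is_ligand_mask

    @cached_property
    def hydrogen_mask(self) -> np.ndarray:
        return self.elements == "H"

    @cached_property
    def backbone_mask(self) -> np.ndarray:
        """Protein backbone: N, CA, C, O plus the amide/terminal hydrogens."""
        bb = np.isin(self.names, sorted(BACKBONE_NAMES | BACKBONE_H_NAMES))
        return bb & self.protein_mask

    @cached_property
    def sidechain_mask(self) -> np.ndarray:
        return self.protein_mask & ~self.backbone_mask

    @cached_property
    def calpha_mask(self) -> np.ndarray:
        return (self.names == "CA") & self.protein_mask

    def atom_index(self, chain_id: str, residue_index: int, name: str) -> int:
        hits = np.flatnonzero((self.chain_ids == chain_id)
                              & (self.residue_indices == residue_index)
                              & (self.names == name))
        if hits.size == 0:
            raise KeyError(f"no atom ({chain_id}, {residue_index}, {name})")
        return int(hits[0])

    # -- selection language --------------------------------------------------
    def select(self, query: str) -> np.ndarray:
        """Evaluate a selection expression, returning topology-ordered indices.

        Grammar: terms joined by ``and`` / ``or`` (``and`` binds tighter),
        optionally negated with ``not``.  Terms: ``protein``, ``ligand``,
        ``backbone``, ``sidechain``, ``calpha``, ``all``, ``chain <id>``,
        ``residue <n>`` or ``residue <a>-<b>``, ``name <atom-name>``.
        """
        mask = _SelectionParser(self, query).parse()
        return np.flatnonzero(mask)


def select_atoms(top: Topology, query: str) -> np.ndarray:
    """Functional alias of :meth:`Topology.select`."""
    return top.select(query)


class _SelectionParser:
    _TOKEN_RE = re.compile(r"\S+")

    def __init__(self, top: Topology, query: str):
        self.top = top
        self.query = query
        self.tokens = [(m.group(0), m.start()) for m in self._TOKEN_RE.finditer(query)]
        self.pos = 0
        if not self.tokens:
            raise SelectionError("empty selection", 0)

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.query))

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        tok, at = self._peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek()[0] == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek()[0] == "and":
            self._next()
            mask = mask & self._term()
        return mask

    def _term(self) -> np.ndarray:
        top = self.top
        tok, at = self._next()
        if tok is None:
            raise SelectionError("expected a selection term", at)
        if tok == "not":
            return ~self._term()
        if tok == "all":
            return np.ones(len(top), dtype=bool)
        if tok == "protein":
            return top.protein_mask.copy()
        if tok == "ligand":
            return top.is_ligand_mask.copy()
        if tok == "backbone":
            return top.backbone_mask.copy()
        if tok == "sidechain":
            return top.sidechain_mask.copy()
        if tok == "calpha":
            return top.calpha_mask.copy()
        if tok == "chain":
            val, vat = self._next()
            if val is None:
                raise SelectionError("'chain' needs a chain id", vat)
            return top.chain_ids == val
        if tok == "name":
            val, vat = self._next()
            if val is None:
                raise SelectionError("'name' needs an atom name", vat)
            return top.names == val
        if tok == "residue":
            val, vat = self._next()
            if val is None:
                raise SelectionError("'residue' needs an index or range", vat)
            m = re.fullmatch(r"(\d+)(?:-(\d+))?", val)
            if not m:
                raise SelectionError(f"bad residue spec {val!r}", vat)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return (top.residue_indices >= lo) & (top.residue_indices <= hi)
        raise SelectionError(f"unknown selection term {tok!r}", at)


@dataclass
class Frame:
    """One saved configuration: coordinates in Angstrom, time in ps."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.time)


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``superposed`` records whether every frame has been least-squares fitted
    onto a common reference; fluctuation analyses refuse to run unless it is
    set (fluctuations without prior fitting mix rigid-body drift into the
    signal).
    """

    topology: Topology
    frames: list[Frame]
    timestep: float = 1.0
    superposed: bool = False

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def infer_h_parents(atoms: Sequence[AtomRecord],
                    conect_pairs: Iterable[tuple[int, int]] = (),
                    warn: bool = True) -> dict[int, int]:
    """Infer covalent hydrogen parentage from atom naming plus CONECT records.

    Naming rules, tried in order: amide/terminal names map to N; stripping the
    leading 'H' and matching an atom of the same residue (covers e.g. ligand
    'HO3' -> 'O3'); prefixing C/O/N/S onto the remainder ('HA' -> 'CA',
    'HB1' -> 'CB').  Hydrogens still unresolved fall back to CONECT; the rest
    are left unparented with a warning and are skipped as H-bond donors.
    """
    import warnings

    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(atoms):
        by_residue.setdefault((a.chain_id, a.residue_index), {})[a.name] = i
    serial_to_index = {a.serial: i for i, a in enumerate(atoms)}

    conect: dict[int, int] = {}
    for s1, s2 in conect_pairs:
        i1, i2 = serial_to_index.get(s1), serial_to_index.get(s2)
        if i1 is None or i2 is None:
            continue
        for h, other in ((i1, i2), (i2, i1)):
            if atoms[h].element.upper() == "H" and atoms[other].element.upper() != "H":
                conect[h] = other

    parents: dict[int, int] = {}
    unparented: list[str] = []
    for i, a in enumerate(atoms):
        if a.element.upper() != "H":
            continue
        siblings = by_residue[(a.chain_id, a.residue_index)]
        parent = None
        if a.name in BACKBONE_H_NAMES and "N" in siblings:
            parent = siblings["N"]
        if parent is None and len(a.name) > 1:
            rest = a.name[1:]
            candidates = [rest]
            for el in ("C", "O", "N", "S"):
                candidates.append(el + rest)
                candidates.append(el + rest.rstrip("0123456789"))
            for cand in candidates:
                j = siblings.get(cand)
                if j is not None and atoms[j].element.upper() != "H":
                    parent = j
                    break
        if parent is None:
            parent = conect.get(i)
        if parent is None:
            unparented.append(f"{a.chain_id}:{a.residue_index}:{a.name}")
        else:
            parents[i] = parent
    if unparented and warn:
        warnings.warn(
            "could not assign a covalent parent to hydrogen(s) "
            + ", ".join(unparented[:10])
            + ("..." if len(unparented) > 10 else "")
            + "; they are excluded from the H-bond donor search")
    return parents
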