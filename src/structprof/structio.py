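"""Atomic-structure I/O and selection.

This module establishes the conventions every geometric analysis in the
package relies on: author residue numbering (1-based, insertion codes folded
into an ordered residue key), ångström coordinates in a right-handed frame,
hydrogens parsed but flagged so geometry can exclude them, HETATM groups
(waters, lipids, ligands) flagged and excluded from protein-surface work by
default, and a single altloc policy (highest occupancy wins, ties broken by
altloc label order) so that every downstream number is computed on one
deterministic conformer.

Parsing and PDB encoding are delegated to :mod:`gemmi`; the in-memory model
is a light structure-of-arrays container tuned for the vectorised geometry in
the rest of the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import gemmi

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ResidueSelection",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "select",
]


class StructureError(ValueError):
    """Raised for unreadable, malformed, or unencodable structure data."""


class SelectionError(KeyError):
    """Raised when a selection resolves to nothing and emptiness is disallowed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom in author numbering.

    ``residue_number`` is the author-assigned sequence number; insertion
    codes are carried separately and folded into the residue ordering key.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    is_hydrogen: bool = False
    insertion_code: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite or malformed position for {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy {self.occupancy} outside [0, 1]")
        object.__setattr__(self, "position", pos)


@dataclass
class StructureModel:
    """An ordered atomic model as parallel arrays.

    ``symmetry_order`` records the point-group order of the assembly (4 for a
    C4-symmetric tetrameric channel); 1 means no assumed symmetry.
    """

    chain_ids: np.ndarray          # (n,) str
    residue_numbers: np.ndarray    # (n,) int, author numbering
    residue_names: np.ndarray      # (n,) str, 3-letter codes
    atom_names: np.ndarray         # (n,) str
    elements: np.ndarray           # (n,) str
    positions: np.ndarray          # (n, 3) float, Å
    occupancies: np.ndarray        # (n,) float
    is_hetero: np.ndarray          # (n,) bool
    is_hydrogen: np.ndarray        # (n,) bool
    insertion_codes: np.ndarray = None  # (n,) str
    symmetry_order: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        if n == 0:
            raise StructureError("empty structure model")
        if self.insertion_codes is None:
            self.insertion_codes = np.full(n, "", dtype=object)
        for name in ("chain_ids", "residue_names", "atom_names", "elements", "insertion_codes"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.is_hetero = np.asarray(self.is_hetero, dtype=bool)
        self.is_hydrogen = np.asarray(self.is_hydrogen, dtype=bool)
        if self.symmetry_order < 1:
            raise StructureError("symmetry_order must be >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates")

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[0])

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def residue_keys(self, protein_only: bool = True) -> list[tuple[str, int, str]]:
        """Ordered distinct (chain, residue_number, insertion_code) keys."""
        mask = ~self.is_hetero if protein_only else np.ones(self.n_atoms, bool)
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_ids[mask], self.residue_numbers[mask],
                           self.insertion_codes[mask]):
            seen.setdefault((c, int(r), i))
        return list(seen)

    @property
    def n_protein_residues(self) -> int:
        return len(self.residue_keys(protein_only=True))

    @property
    def n_non_hydrogen_atoms(self) -> int:
        return int(np.count_nonzero(~self.is_hydrogen))

    # -- derived views -------------------------------------------------

    def subset(self, mask: np.ndarray, allow_empty: bool = False) -> "StructureModel":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            if allow_empty:
                raise StructureError("StructureModel cannot be empty")
            raise SelectionError("selection matched no atoms")
        return StructureModel(
            chain_ids=self.chain_ids[mask],
            residue_numbers=self.residue_numbers[mask],
            residue_names=self.residue_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            positions=self.positions[mask],
            occupancies=self.occupancies[mask],
            is_hetero=self.is_hetero[mask],
            is_hydrogen=self.is_hydrogen[mask],
            insertion_codes=self.insertion_codes[mask],
            symmetry_order=self.symmetry_order,
            source_id=self.source_id,
        )

    def heavy(self, include_hetero: bool = False) -> "StructureModel":
        """Non-hydrogen atoms; by default protein only (HETATM excluded)."""
        mask = ~self.is_hydrogen
        if not include_hetero:
            mask &= ~self.is_hetero
        return self.subset(mask)

    def ca_mask(self) -> np.ndarray:
        return (self.atom_names == "CA") & ~self.is_hetero & ~self.is_hydrogen

    def ca_coords(self, chain: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(residue_numbers, coordinates) of Cα atoms, optionally one chain."""
        mask = self.ca_mask()
        if chain is not None:
            mask &= self.chain_ids == chain
        return self.residue_numbers[mask], self.positions[mask]

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                chain_id=self.chain_ids[i],
                residue_number=int(self.residue_numbers[i]),
                residue_name=self.residue_names[i],
                atom_name=self.atom_names[i],
                element=self.elements[i],
                position=self.positions[i].copy(),
                occupancy=float(self.occupancies[i]),
                is_hetero=bool(self.is_hetero[i]),
                is_hydrogen=bool(self.is_hydrogen[i]),
                insertion_code=self.insertion_codes[i],
            )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = self.subset(np.ones(self.n_atoms, bool))
        out.positions = self.positions @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return out


@dataclass(frozen=True)
class ResidueSelection:
    """A set of (chain_id, residue_number) keys, optionally atom-filtered."""

    items: frozenset
    atom_names: frozenset | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(sorted(self.items))

    def mask(self, model: StructureModel) -> np.ndarray:
        keys = {(c, int(r)) for c, r in self.items}
        mask = np.fromiter(
            ((c, int(r)) in keys for c, r in zip(model.chain_ids, model.residue_numbers)),
            dtype=bool, count=model.n_atoms,
        )
        if self.atom_names is not None:
            mask &= np.isin(model.atom_names, list(self.atom_names))
        return mask

    def validate(self, model: StructureModel) -> None:
        present = set(zip(model.chain_ids, (int(r) for r in model.residue_numbers)))
        missing = {(c, int(r)) for c, r in self.items} - present
        if missing:
            raise SelectionError(f"unresolvable residues: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_FORMATS = {"pdb", "mmcif"}


def read_structure(path: str | os.PathLike, format: str | None = None,
                   symmetry_order: int = 1) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM records are returned; HETATM records are flagged ``is_hetero``
    and hydrogens ``is_hydrogen``.  Alternate locations are resolved to the
    highest-occupancy conformer (ties by altloc label order).  Only the first
    model of a multi-model file is read.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureError(f"no such file: {path}")
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = "mmcif" if ext in ("cif", "mmcif") else "pdb"
    if format not in _FORMATS:
        raise StructureError(f"unknown format {format!r}; expected one of {sorted(_FORMATS)}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")

    rows: list[tuple] = []
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            # altloc resolution: per atom name keep max occupancy, tie -> label order
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ or (
                    atom.occ == prev.occ and (atom.altloc or " ") < (prev.altloc or " ")
                ):
                    by_name[atom.name] = atom
            for atom in res:
                chosen = by_name.get(atom.name)
                if chosen is not atom:
                    continue
                el = atom.element.name.upper()
                rows.append((
                    chain.name, res.seqid.num, res.seqid.icode.strip(), res.name,
                    atom.name, el, (atom.pos.x, atom.pos.y, atom.pos.z),
                    min(max(atom.occ, 0.0), 1.0), het, el in ("H", "D"),
                ))
    if not rows:
        raise StructureError(f"{path}: no atoms parsed")
    cols = list(zip(*rows))
    return StructureModel(
        chain_ids=np.array(cols[0], dtype=object),
        residue_numbers=np.array(cols[1], dtype=int),
        residue_names=np.array(cols[3], dtype=object),
        atom_names=np.array(cols[4], dtype=object),
        elements=np.array(cols[5], dtype=object),
        positions=np.array(cols[6], dtype=float),
        occupancies=np.array(cols[7], dtype=float),
        is_hetero=np.array(cols[8], dtype=bool),
        is_hydrogen=np.array(cols[9], dtype=bool),
        insertion_codes=np.array(cols[2], dtype=object),
        symmetry_order=symmetry_order,
        source_id=os.path.basename(path),
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select(model: StructureModel,
           chains: Sequence[str] | None = None,
           residue_range: tuple[int, int] | None = None,
           atom_names: Sequence[str] | None = None,
           exclude_hetero: bool = False,
           allow_empty: bool = False) -> StructureModel:
    """Subset a model, preserving order and author numbering.

    ``residue_range`` is inclusive and 1-based, matching how helix boundaries
    are quoted (e.g. the pore-lining S7b helix of BmGr9 spans 424-444).
    """
    mask = np.ones(model.n_atoms, dtype=bool)
    criteria = []
    if chains is not None:
        mask &= np.isin(model.chain_ids, list(chains))
        criteria.append(f"chains={list(chains)}")
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (model.residue_numbers >= lo) & (model.residue_numbers <= hi)
        criteria.append(f"residue_range={lo}-{hi}")
    if atom_names is not None:
        mask &= np.isin(model.atom_names, list(atom_names))
        criteria.append(f"atom_names={list(atom_names)}")
    if exclude_hetero:
        mask &= ~model.is_hetero
        criteria.append("exclude_hetero")
    if not mask.any() and not allow_empty:
        raise SelectionError(f"selection empty; criteria: {', '.join(criteria) or 'none'}")
    return model.subset(mask)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_structure(model: StructureModel, path: str | os.PathLike,
                    format: str = "pdb") -> None:
    """Write the model as a standard PDB file (one TER per chain).

    Coordinates survive a round trip to 1e-3 Å (the PDB field precision).
    """
    if format != "pdb":
        raise StructureError(f"unsupported output format {format!r}")
    if int(np.max(model.residue_numbers)) > 9999 or int(np.min(model.residue_numbers)) < -999:
        raise StructureError("residue_number does not fit the fixed-width PDB dialect")

    st = gemmi.Structure()
    st.name = model.source_id or "model"
    gm = gemmi.Model("1")
    chain_index: dict[str, int] = {}
    cur_chain = None
    cur_res = None
    cur_res_key = None
    # PDB records must be chain-contiguous; group atoms by chain, preserving
    # first-appearance chain order and within-chain atom order
    chain_rank = {c: k for k, c in enumerate(model.chains)}
    order = sorted(range(model.n_atoms),
                   key=lambda i: (chain_rank[model.chain_ids[i]], i))
    records = list(model.atoms())
    for idx in order:
        rec = records[idx]
        if cur_chain is None or rec.chain_id != cur_chain.name:
            if rec.chain_id not in chain_index:
                gm.add_chain(gemmi.Chain(rec.chain_id))
                chain_index[rec.chain_id] = len(chain_index)
            cur_chain = gm[chain_index[rec.chain_id]]
            cur_res = None
            cur_res_key = None
        key = (rec.residue_number, rec.insertion_code, rec.residue_name)
        if cur_res is None or cur_res_key != key:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_number, rec.insertion_code or " ")
            res.het_flag = "H" if rec.is_hetero else "A"
            cur_chain.add_residue(res)
            cur_res = cur_chain[-1]
            cur_res_key = key
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element.capitalize())
        atom.pos = gemmi.Position(*rec.position)
        atom.occ = rec.occupancy
        cur_res.add_atom(atom)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(os.fspath(path))
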