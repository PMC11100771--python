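"""Rigid-body and surface geometry on atomic models.

Superposition (Kabsch, proper rotations only), RMSD matrices, alignment-free
distance-difference matrices, Cα contact maps, Shrake-Rupley solvent-accessible
surface areas on a deterministic spiral point lattice, buried subunit
interfaces, opposing-residue cross distances, and neighbour searches.

All heavy-atom geometry uses the van der Waals radii table below
(``RADII_VERSION``); areas and pore/pocket dimensions are only comparable
between runs that share it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree, distance_matrix
from scipy.spatial.transform import Rotation

from .structio import ResidueSelection, SelectionError, StructureModel

log = logging.getLogger("structprof")

__all__ = [
    "VDW_RADII", "RADII_VERSION", "vdw_radius", "atom_radii",
    "GeometryError", "SuperpositionResult", "DistanceDifferenceMatrix",
    "ContactMap", "SasaResult",
    "superpose", "rmsd_matrix", "distance_difference", "contact_map",
    "sasa", "buried_area_per_subunit", "cross_distance", "neighbor_residues",
    "sphere_points",
]

# Bondi (1964) van der Waals radii, Å; P from Bondi's tabulation as commonly
# used for phospholipid phosphates.  Versioned because every area and
# clearance in the package depends on it.
RADII_VERSION = "bondi64-v1"
VDW_RADII: Mapping[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "SE": 1.90, "ZN": 1.39, "MG": 1.73, "NA": 2.27,
    "K": 2.75, "CA": 2.31, "FE": 1.70, "X": 1.70,
}


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric input."""


def vdw_radius(element: str) -> float:
    el = element.upper()
    if el not in VDW_RADII:
        raise GeometryError(f"no van der Waals radius for element {element!r} "
                            f"(radii table {RADII_VERSION})")
    return VDW_RADII[el]


def atom_radii(model: StructureModel) -> np.ndarray:
    return np.array([vdw_radius(e) for e in model.elements], dtype=float)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # 3-vector, Å
    rmsd: float               # Å, after transform
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinates (Kabsch).

    Returns the proper rotation R and translation t minimising
    ``|reference - (R·mobile + t)|`` and the post-transform RMSD.
    """
    mob = np.asarray(mobile, float).reshape(-1, 3)
    ref = np.asarray(reference, float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise GeometryError(f"paired lists differ in length: {mob.shape[0]} vs {ref.shape[0]}")
    n = mob.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 paired atoms")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: rank of either centred set < 2 is degenerate
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) coordinates")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - mob.mean(axis=0) @ R.T
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _paired_ca(model_a: StructureModel, model_b: StructureModel,
               pairing: Sequence[tuple] | None
               ) -> tuple[np.ndarray, np.ndarray, list]:
    """Cα coordinate pairs, either from an explicit (key_a, key_b) pairing or
    from the intersection of (chain, residue_number) keys.  Returns the
    coordinates plus the list of A-side keys used."""
    def ca_index(model):
        mask = model.ca_mask()
        idx = {}
        for i in np.flatnonzero(mask):
            idx.setdefault((model.chain_ids[i], int(model.residue_numbers[i])), i)
        return idx

    ia, ib = ca_index(model_a), ca_index(model_b)
    if pairing is None:
        pairs = [(k, k) for k in ia if k in ib]
    else:
        pairs = [(tuple(a), tuple(b)) for a, b in pairing]
    xa, xb = [], []
    for ka, kb in pairs:
        if ka not in ia or kb not in ib:
            raise GeometryError(f"unpaired entry: {ka} / {kb} lacks a Cα atom")
        xa.append(model_a.positions[ia[ka]])
        xb.append(model_b.positions[ib[kb]])
    return np.array(xa), np.array(xb), [ka for ka, _ in pairs]


def rmsd_matrix(models: Sequence[StructureModel],
                correspondence: Mapping[tuple[int, int], Sequence[tuple]] | None = None
                ) -> np.ndarray:
    """Symmetric matrix of pairwise superposition RMSDs over Cα atoms.

    ``correspondence[(i, j)]`` supplies the residue pairing for each model
    pair (e.g. derived from an alignment); without it, models are paired on
    shared (chain, residue_number) keys.
    """
    k = len(models)
    out = np.zeros((k, k), float)
    for i in range(k):
        for j in range(i + 1, k):
            pairing = None
            if correspondence is not None:
                pairing = correspondence.get((i, j))
                if pairing is None and (j, i) in correspondence:
                    pairing = [(b, a) for a, b in correspondence[(j, i)]]
            xa, xb, _ = _paired_ca(models[i], models[j], pairing)
            out[i, j] = out[j, i] = superpose(xa, xb).rmsd
    return out


# ---------------------------------------------------------------------------
# Distance-difference and contact maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceDifferenceMatrix:
    residue_labels: list
    values: np.ndarray   # |d_A(i,j) - d_B(i,j)|, Å

    @property
    def per_residue_score(self) -> np.ndarray:
        """Row mean — a superposition-free per-residue movement score."""
        return self.values.mean(axis=1)


def distance_difference(model_a: StructureModel, model_b: StructureModel,
                        shared_residues: Sequence[tuple] | None = None
                        ) -> DistanceDifferenceMatrix:
    """Alignment-free |ΔCα-distance| matrix over residues shared by A and B."""
    pairing = [(k, k) for k in shared_residues] if shared_residues is not None else None
    xa, xb, labels = _paired_ca(model_a, model_b, pairing)
    if xa.shape[0] < 2:
        raise GeometryError("need at least 2 shared residues")
    da = distance_matrix(xa, xa)
    db = distance_matrix(xb, xb)
    return DistanceDifferenceMatrix(residue_labels=labels, values=np.abs(da - db))


@dataclass(frozen=True)
class ContactMap:
    residue_labels: list
    contacts: np.ndarray   # symmetric bool
    cutoff: float
    atom_rule: str = "CA"
    n_skipped: int = 0     # residues lacking a Cα atom

    def index_of(self, chain: str, resnum: int) -> int:
        return self.residue_labels.index((chain, resnum))

    @property
    def density(self) -> float:
        n = self.contacts.shape[0]
        return float(self.contacts.sum()) / (n * (n - 1)) if n > 1 else 0.0


def contact_map(model: StructureModel, cutoff: float = 8.0,
                min_sequence_separation: int = 1, chain: str | None = None) -> ContactMap:
    """Boolean Cα-Cα contact map at the given cutoff (default 8 Å).

    Pairs closer than ``min_sequence_separation`` in residue numbering within
    the same chain are excluded.
    """
    sub = model if chain is None else model.subset(model.chain_ids == chain)
    mask = sub.ca_mask()
    if not mask.any():
        raise GeometryError("model has no Cα atoms")
    skipped = len(sub.residue_keys()) - int(mask.sum())
    if skipped:
        log.warning("contact_map: %d residues lack a Cα atom and were skipped", skipped)
    coords = sub.positions[mask]
    chains = sub.chain_ids[mask]
    resnums = sub.residue_numbers[mask]
    d = distance_matrix(coords, coords)
    contacts = d <= cutoff
    same_chain = chains[:, None] == chains[None, :]
    sep = np.abs(resnums[:, None] - resnums[None, :])
    contacts &= ~(same_chain & (sep < min_sequence_separation))
    np.fill_diagonal(contacts, False)
    labels = [(c, int(r)) for c, r in zip(chains, resnums)]
    return ContactMap(residue_labels=labels, contacts=contacts, cutoff=cutoff,
                      n_skipped=skipped)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


@dataclass(frozen=True)
class SasaResult:
    atom_areas: np.ndarray      # Å² per atom
    residue_keys: list          # (chain, resnum, icode)
    residue_areas: np.ndarray   # Å² per residue (sum of atom areas)
    probe_radius: float
    point_density: int

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def residue_area(self, chain: str, resnum: int) -> float:
        total = 0.0
        for k, a in zip(self.residue_keys, self.residue_areas):
            if k[0] == chain and k[1] == resnum:
                total += a
        return total


def sasa(model: StructureModel, probe_radius: float = 1.4,
         point_density: int = 960, include_hetero: bool = False) -> SasaResult:
    """Shrake-Rupley SASA on the spiral lattice (bit-stable, no RNG).

    Hydrogens are excluded; HETATM groups are excluded unless
    ``include_hetero``.  ``point_density`` is points per atom sphere.
    """
    heavy = model.heavy(include_hetero=include_hetero)
    radii = atom_radii(heavy) + probe_radius
    coords = heavy.positions
    n = coords.shape[0]
    pts = sphere_points(point_density)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n, float)
    for i in range(n):
        ri = radii[i]
        surface = coords[i] + ri * pts
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)]
            d2 = np.sum((surface[:, None, :] - nc[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nr ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri ** 2

    keys = heavy.residue_keys(protein_only=not include_hetero)
    key_index = {k: j for j, k in enumerate(keys)}
    res_areas = np.zeros(len(keys), float)
    for i in range(n):
        k = (heavy.chain_ids[i], int(heavy.residue_numbers[i]), heavy.insertion_codes[i])
        res_areas[key_index[k]] += areas[i]
    return SasaResult(atom_areas=areas, residue_keys=keys, residue_areas=res_areas,
                      probe_radius=probe_radius, point_density=point_density)


def buried_area_per_subunit(tetramer: StructureModel, subunit_chain: str,
                            regions: Mapping[str, tuple[int, int]] | None = None,
                            probe_radius: float = 1.4,
                            point_density: int = 960) -> dict:
    """Surface area of one subunit buried by assembly into the complex.

    Returns ``{"total": Å², "regions": {name: Å²}}`` where each region is an
    inclusive residue range on the subunit and the buried area is
    SASA(subunit alone) − SASA(subunit within complex), summed per region.
    """
    if subunit_chain not in tetramer.chains:
        raise SelectionError(f"chain {subunit_chain!r} not in model")
    if len(tetramer.chains) < 2:
        raise GeometryError("complex must contain at least 2 chains")
    if regions:
        spans = sorted(regions.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise GeometryError(f"overlapping region ranges {(a1, b1)} and {(a2, b2)}")

    from .structio import select as _select
    alone = _select(tetramer, chains=[subunit_chain], exclude_hetero=True)
    s_alone = sasa(alone, probe_radius, point_density)
    s_complex = sasa(tetramer, probe_radius, point_density)
    in_complex = {k: a for k, a in zip(s_complex.residue_keys, s_complex.residue_areas)
                  if k[0] == subunit_chain}
    per_res = {}
    for k, a in zip(s_alone.residue_keys, s_alone.residue_areas):
        per_res[k] = a - in_complex.get(k, 0.0)
    total = float(sum(per_res.values()))
    out = {"total": total, "regions": {}}
    if regions:
        for name, (lo, hi) in regions.items():
            out["regions"][name] = float(sum(a for (c, r, _), a in per_res.items()
                                             if lo <= r <= hi))
    return out


# ---------------------------------------------------------------------------
# Cross distances and neighbour searches
# ---------------------------------------------------------------------------

def cross_distance(model: StructureModel, residue_number: int,
                   atom_name: str = "CA", mode: str = "opposing") -> float:
    """Distance between symmetry-mate copies of one residue's atom.

    For a C4 assembly, ``opposing`` returns the mean of the two diagonal
    (chain i ↔ chain i+2) distances — the convention behind quoting the gate
    as an opposing Cα-Cα distance; ``adjacent`` returns the mean edge
    distance.  Diagonals and edges are identified from the pair-distance
    ordering, so no chain labelling convention is assumed.
    """
    mask = (model.atom_names == atom_name) & (model.residue_numbers == residue_number) \
        & ~model.is_hetero
    coords = model.positions[mask]
    chains = model.chain_ids[mask]
    if len(set(chains)) < 2:
        raise SelectionError(
            f"residue {residue_number} atom {atom_name} present in <2 chains")
    # one atom per chain (first occurrence)
    seen, keep = set(), []
    for i, c in enumerate(chains):
        if c not in seen:
            seen.add(c)
            keep.append(i)
    coords = coords[keep]
    m = coords.shape[0]
    d = distance_matrix(coords, coords)
    iu = np.triu_indices(m, 1)
    dists = np.sort(d[iu])
    if mode == "opposing":
        if m < 3:
            return float(dists[-1])
        n_diag = m // 2          # C4: 2 diagonals out of 6 pairs
        return float(dists[-n_diag:].mean())
    if mode == "adjacent":
        n_edge = m               # C4: 4 edges
        return float(dists[:n_edge].mean())
    raise GeometryError(f"unknown mode {mode!r}")


def neighbor_residues(model: StructureModel, around, cutoff: float,
                      include_hetero: bool = False) -> ResidueSelection:
    """Residues with any non-hydrogen atom within ``cutoff`` of the query group.

    ``around`` is a ResidueSelection or an explicit (m, 3) coordinate array
    (e.g. the atoms of a bound lipid).  Query residues themselves are not
    excluded; filter afterwards if needed.
    """
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    if isinstance(around, ResidueSelection):
        qmask = around.mask(model) & ~model.is_hydrogen
        query = model.positions[qmask]
    else:
        query = np.asarray(around, float).reshape(-1, 3)
    if query.shape[0] == 0:
        raise GeometryError("empty query group")
    heavy = model.heavy(include_hetero=include_hetero)
    tree = cKDTree(heavy.positions)
    hits = tree.query_ball_point(query, cutoff)
    idx = sorted({j for lst in hits for j in lst})
    items = {(heavy.chain_ids[j], int(heavy.residue_numbers[j])) for j in idx}
    return ResidueSelection(items=frozenset(items))
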