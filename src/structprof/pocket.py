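"""Grid-based ligand-binding pocket detection for a channel subunit.

A cell of a cubic grid (default 0.5 Å spacing, axes aligned with the channel
axis frame) is *open* if a probe sphere (default 1.4 Å) fits there without
touching any van der Waals surface, and *pocket-like* if it is additionally
enclosed by protein: at least 9 of 14 scan rays (6 axial + 8 diagonal) hit
protein within 12 Å.  Pockets are the 26-connected components of pocket-like
cells above a minimum volume; volume is exactly n_cells x spacing^3.  A
pocket is solvent accessible when its open-space component reaches bulk
solvent on the extracellular side of the grid, which is how an open sugar
pocket is distinguished from the occluded, membrane-facing cavity of an
odorant receptor.  Lining residues are those with a heavy atom within a
contact cutoff of the pocket and non-zero solvent accessibility with the
pocket treated as solvent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import GeometryError, atom_radii, sasa
from .pore import AxisFrame
from .structio import ResidueSelection, StructureModel

log = logging.getLogger("structprof")

__all__ = ["Pocket", "detect_pockets", "pocket_depth", "lining_residues",
           "pocket_delta"]

# 14 scan directions: 6 axial + 8 body diagonals (integer grid steps)
_RAY_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=int)


@dataclass
class Pocket:
    """One detected cavity.

    ``cells`` are world coordinates of occupied grid-cell centres; ``depth``
    is measured along the axis from the extracellular boundary plane to the
    deepest cell.
    """

    cells: np.ndarray                 # (n, 3) world coordinates
    cell_axis_coords: np.ndarray      # (n, 3) coordinates in the axis frame
    spacing: float
    volume: float                     # n_cells * spacing^3, Å^3
    depth: float                      # Å
    mouth_cells: np.ndarray           # subset of cells on the solvent interface
    accessibility: str                # "solvent_accessible" | "occluded"
    lining: ResidueSelection | None = None

    @property
    def n_cells(self) -> int:
        return int(self.cells.shape[0])


def _burn_spheres(blocked: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                  origin: np.ndarray, spacing: float) -> None:
    """Mark grid cells whose centre lies within radius of any sphere centre."""
    shape = np.array(blocked.shape)
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[k] + spacing * np.arange(lo[k], hi[k]) - c[k] for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        blocked[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r


def _enclosure_counts(occupied: np.ndarray, spacing: float,
                      ray_length: float) -> np.ndarray:
    """Per-cell count of the 14 scan rays that hit protein within ray_length.

    The occupied grid is dilated by one cell so that the single-cell-wide
    diagonal rays do not slip through voxelisation gaps at the surface.
    """
    occupied = ndimage.binary_dilation(occupied, structure=np.ones((3, 3, 3), bool))
    counts = np.zeros(occupied.shape, dtype=np.int8)
    for d in _RAY_DIRS:
        step_len = spacing * np.linalg.norm(d)
        n_steps = int(np.ceil(ray_length / step_len))
        hit = np.zeros(occupied.shape, dtype=bool)
        for k in range(1, n_steps + 1):
            shift = k * d
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            ok = True
            for ax in range(3):
                s = shift[ax]
                n = occupied.shape[ax]
                if abs(s) >= n:
                    ok = False
                    break
                if s > 0:
                    dst[ax], src[ax] = slice(0, n - s), slice(s, n)
                elif s < 0:
                    dst[ax], src[ax] = slice(-s, n), slice(0, n + s)
            if not ok:
                break
            hit[tuple(dst)] |= occupied[tuple(src)]
        counts += hit.astype(np.int8)
    return counts


def detect_pockets(subunit: StructureModel, axis: AxisFrame,
                   spacing: float = 0.5, probe: float = 1.4,
                   min_volume: float = 30.0,
                   enclosure_threshold: int = 9, ray_length: float = 12.0,
                   contact_cutoff: float = 4.5,
                   compute_lining: bool = True) -> list[Pocket]:
    """Detect cavities in one subunit, sorted by volume (largest first)."""
    if spacing <= 0 or probe <= 0:
        raise GeometryError("spacing and probe must be positive")
    heavy = subunit.heavy()
    radii = atom_radii(heavy)
    q = axis.to_frame(heavy.positions)          # work in the axis frame
    margin = float(radii.max() + probe + 2.0 * spacing)
    lo = q.min(axis=0) - margin
    hi = q.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    occupied = np.zeros(shape, dtype=bool)
    _burn_spheres(occupied, q, radii, lo, spacing)
    blocked = np.zeros(shape, dtype=bool)
    _burn_spheres(blocked, q, radii + probe, lo, spacing)
    open_cells = ~blocked

    counts = _enclosure_counts(occupied, spacing, ray_length)
    pocketlike = open_cells & (counts >= enclosure_threshold)
    if axis.outer_boundary_z is not None:
        # cells beyond the extracellular boundary plane are bulk solvent
        k_max = int(np.floor((axis.outer_boundary_z - lo[2]) / spacing))
        if k_max < shape[2] - 1:
            pocketlike[:, :, max(k_max + 1, 0):] = False

    structure26 = np.ones((3, 3, 3), dtype=bool)
    labels, n_comp = ndimage.label(pocketlike, structure=structure26)
    if n_comp == 0:
        return []

    # bulk-solvent component(s): open space touching the extracellular top
    open_labels, _ = ndimage.label(open_cells, structure=structure26)
    outer = axis.outer_boundary_z
    if outer is None:
        outer = float(q[:, 2].max())
    top_layer = open_labels[:, :, -1]
    bulk_ids = set(np.unique(top_layer[top_layer > 0]))

    grids = np.indices(shape)
    pockets: list[Pocket] = []
    comp_sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                    index=np.arange(1, n_comp + 1))
    for comp in np.argsort(comp_sizes)[::-1] + 1:
        n_cells = int(comp_sizes[comp - 1])
        volume = n_cells * spacing ** 3
        if volume < min_volume:
            break
        mask = labels == comp
        ijk = np.column_stack([g[mask] for g in grids])
        cell_q = lo + ijk * spacing
        cell_world = axis.from_frame(cell_q)

        # accessibility: does this component's open-space component reach bulk?
        comp_open_ids = set(np.unique(open_labels[mask])) - {0}
        accessible = bool(comp_open_ids & bulk_ids)

        depth = float(outer - cell_q[:, 2].min())
        # mouth: pocket cells 6-adjacent to open cells outside the pocket set
        interface = ndimage.binary_dilation(open_cells & ~pocketlike) & mask
        if interface.any():
            mouth = axis.from_frame(
                lo + np.column_stack([g[interface] for g in grids]) * spacing)
        else:
            mouth = np.empty((0, 3))
        pockets.append(Pocket(cells=cell_world, cell_axis_coords=cell_q,
                              spacing=spacing, volume=volume, depth=max(depth, 0.0),
                              mouth_cells=mouth,
                              accessibility="solvent_accessible" if accessible
                              else "occluded"))
    if compute_lining:
        for p in pockets:
            p.lining = lining_residues(p, subunit, contact_cutoff=contact_cutoff)
    return pockets


def pocket_depth(pocket: Pocket, axis: AxisFrame) -> float:
    """Axial distance from the extracellular boundary plane to the deepest cell."""
    if axis.outer_boundary_z is None:
        raise GeometryError("axis.outer_boundary_z is unset; configure the membrane planes")
    z = axis.axial(pocket.cells)
    return float(axis.outer_boundary_z - z.min())


def lining_residues(pocket: Pocket, subunit: StructureModel,
                    contact_cutoff: float = 4.5,
                    point_density: int = 240) -> ResidueSelection:
    """Residues facing the pocket.

    A residue lines the pocket when it has a heavy atom within
    ``contact_cutoff`` of a pocket cell and non-zero solvent-accessible area
    when the isolated subunit is probed (so the pocket interior counts as
    solvent).
    """
    heavy = subunit.heavy()
    tree = cKDTree(heavy.positions)
    hits = tree.query_ball_point(pocket.cells, contact_cutoff)
    idx = sorted({j for lst in hits for j in lst})
    candidates = {(heavy.chain_ids[j], int(heavy.residue_numbers[j])) for j in idx}
    s = sasa(subunit, point_density=point_density)
    exposed = {(c, r) for (c, r, _), a in zip(s.residue_keys, s.residue_areas) if a > 0.0}
    return ResidueSelection(items=frozenset(candidates & exposed))


def pocket_delta(pocket_a: Pocket, pocket_b: Pocket,
                 shared_frame: bool = True) -> dict:
    """Compare two pockets of superposed structures.

    Returns the signed volume change (B − A) and the lining-residue turnover.
    Caller must have superposed the structures into a shared frame.
    """
    if not shared_frame:
        raise GeometryError("pockets must be in a shared superposed frame")
    lining_a = set(pocket_a.lining) if pocket_a.lining else set()
    lining_b = set(pocket_b.lining) if pocket_b.lining else set()
    return {
        "volume_change": pocket_b.volume - pocket_a.volume,
        "depth_change": pocket_b.depth - pocket_a.depth,
        "lining_gained": sorted(lining_b - lining_a),
        "lining_lost": sorted(lining_a - lining_b),
    }
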