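"""Synthetic structures, alignments, and trees with known ground truth.

Every generator returns ``(object, truth)`` where ``truth`` is a plain dict
of the planted parameters, so each analysis stage has a recovery test that
needs no downloaded data.

``build_bundle`` emulates the architecture of a C4-symmetric
seven-transmembrane-channel tetramer at coarse resolution: a central pore
whose wall is a surface of revolution of pseudo-atoms with a configurable
clearance profile (wide vestibule, narrow hydrophobic gate), optional
lateral conduits drilled between subunits, and per-subunit body blocks with
an optional drilled ligand pocket of analytic volume.  Each wall residue
carries a Cα placed radially outside its pore-facing pseudo side chain, so
gate-residue cross distances and side-chain deletions behave like their
real-structure counterparts.  Atoms are carbon spheres (1.7 Å): geometry
algorithms need clearances, not chemistry.

``simulate_msa`` plants per-column conservation levels, six-class
composition targets, covarying column pairs (two-state mixtures), gap
structure, and per-sequence loop-length variation.  ``simulate_tree`` builds
a random rooted binary tree containing named clades as true monophyletic
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phylo import PhyloError, Tree, read_newick
from .seqprofile import (AA_ORDER, GAP, HEATMAP_CLASSES, AnnotatedAlignment,
                         HelixAnnotation)
from .structio import StructureModel

log = logging.getLogger("structprof")

__all__ = ["BundleSpec", "MsaSpec", "SpecError", "build_bundle",
           "build_slab_with_cavity", "simulate_msa", "simulate_tree"]

_R_ATOM = 1.70   # carbon vdW radius used by all generators


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Channel bundle
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Geometry plan for a synthetic symmetric channel.

    Clearance profile of the pore (Å of free radius): ``vestibule_radius``
    away from the gate, pinching linearly to ``gate_radius`` at ``gate_z``
    over ``gate_half_width``.  Setting ``gate_radius == vestibule_radius``
    yields an analytic cylinder.
    """

    symmetry_order: int = 4
    ring_spacing: float = 1.0       # Å between pore-wall rings along z
    n_ring_atoms: int = 12          # wall atoms per ring
    z_bottom: float = -18.0
    z_top: float = 6.0              # extracellular boundary
    vestibule_radius: float = 4.5
    gate_radius: float = 1.25
    gate_z: float = 3.0
    gate_half_width: float = 3.0
    ca_offset: float = 1.85         # Cα radial offset beyond the wall surface
    conduit_radius: float | None = None
    conduit_z: float = -10.0
    include_bodies: bool = True
    body_center_radius: float = 16.0
    body_size: tuple = (15.0, 15.0, 18.0)   # radial, tangential, vertical, Å
    body_spacing: float = 1.5
    pocket_size: tuple | None = None        # (wx, wy, depth) drilled from the top
    pocket_probe: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gate_radius <= 0 or self.vestibule_radius <= 0:
            raise SpecError("gate and vestibule radii must be positive")
        if self.gate_radius > self.vestibule_radius:
            raise SpecError("gate_radius cannot exceed vestibule_radius")
        if not self.z_bottom < self.gate_z <= self.z_top:
            raise SpecError("gate_z must lie within (z_bottom, z_top]")
        if self.symmetry_order < 2:
            raise SpecError("symmetry_order must be >= 2")
        if self.n_ring_atoms % self.symmetry_order:
            raise SpecError("n_ring_atoms must be divisible by symmetry_order")

    def clearance(self, z: float) -> float:
        pinch = max(0.0, 1.0 - abs(z - self.gate_z) / self.gate_half_width)
        return self.vestibule_radius - (self.vestibule_radius - self.gate_radius) * pinch


def _chain_name(i: int) -> str:
    return "ABCDEFGHIJKLMNOP"[i]


def build_bundle(spec: BundleSpec) -> tuple[StructureModel, dict]:
    """Build the synthetic channel; returns (model, ground-truth record)."""
    m = spec.symmetry_order
    per_chain = spec.n_ring_atoms // m
    rows = []   # (chain, resnum, resname, atomname, element, xyz)

    def add(chain, resnum, atomname, xyz):
        rows.append((chain, resnum, "ALA", atomname, "C", xyz))

    # --- pore wall -------------------------------------------------------
    zs = np.arange(spec.z_bottom, spec.z_top + 1e-9, spec.ring_spacing)
    gate_ring = int(np.argmin(np.abs(zs - spec.gate_z)))
    gate_residues = []
    conduit_angles = []
    if spec.conduit_radius is not None:
        conduit_angles = [(2 * np.pi / m) * c for c in range(m)]   # between subunits

    wall_res_per_ring = per_chain
    for ring, z in enumerate(zs):
        wall_r = spec.clearance(z) + _R_ATOM
        stagger = 0.5 * (ring % 2)
        for g in range(spec.n_ring_atoms):
            ang = 2 * np.pi * (g + stagger) / spec.n_ring_atoms
            chain = _chain_name(g // per_chain)
            slot = g % per_chain
            resnum = ring * wall_res_per_ring + slot + 1
            cb = np.array([wall_r * np.cos(ang), wall_r * np.sin(ang), z])
            ca_r = wall_r + spec.ca_offset
            ca = np.array([ca_r * np.cos(ang), ca_r * np.sin(ang), z])
            if spec.conduit_radius is not None:
                drilled = False
                for ca_ang in conduit_angles:
                    axis_pt = np.array([np.cos(ca_ang), np.sin(ca_ang), 0.0])
                    # drill: remove residues whose atoms sit on the radial line
                    for atom_xyz in (cb, ca):
                        p = atom_xyz - np.array([0.0, 0.0, spec.conduit_z])
                        t = max(p @ axis_pt, 0.0)
                        d = np.linalg.norm(p - t * axis_pt)
                        if d < spec.conduit_radius + _R_ATOM:
                            drilled = True
                            break
                    if drilled:
                        break
                if drilled:
                    continue
            add(chain, resnum, "CB", cb)
            add(chain, resnum, "CA", ca)
            if ring == gate_ring and resnum not in gate_residues:
                gate_residues.append(resnum)

    n_wall_res = len(zs) * wall_res_per_ring

    # --- subunit bodies with optional drilled pocket ---------------------
    pocket_wall_core: list = []
    pocket_wall_shell: list = []
    pocket_volume = pocket_depth_true = None
    if spec.include_bodies:
        bx, by, bz = spec.body_size
        sp = spec.body_spacing
        nx = 2 * int(round(bx / (2 * sp)))     # even -> lattice planes at k*sp
        ny = 2 * int(round(by / (2 * sp)))
        nz = int(round(bz / sp))
        erode = _R_ATOM + spec.pocket_probe
        eps = 1e-6
        if spec.pocket_size is not None:
            wx, wy, depth = spec.pocket_size
            # snap drill planes to the body lattice; truth uses realized dims
            hx = max(round((wx / 2.0 + erode) / sp), 1) * sp
            hy = max(round((wy / 2.0 + erode) / sp), 1) * sp
            dz = max(round((depth + erode) / sp), 2) * sp
            half_x, half_y = hx - erode, hy - erode
            depth_real = dz - erode
            if min(half_x, half_y, depth_real) <= 0:
                raise SpecError("pocket_size too small for the body lattice")
            cav_lo = np.array([-half_x, -half_y, spec.z_top - depth_real])
            cav_hi = np.array([half_x, half_y, spec.z_top])
            pocket_volume = float(4.0 * half_x * half_y * depth_real)
            pocket_depth_true = float(depth_real)
        for c in range(m):
            theta = (2 * np.pi / m) * (c + 0.5)
            rhat = np.array([np.cos(theta), np.sin(theta), 0.0])
            that = np.array([-np.sin(theta), np.cos(theta), 0.0])
            chain = _chain_name(c)
            resnum = 1000
            for i in range(nx + 1):
                for j in range(ny + 1):
                    for k in range(nz + 1):
                        resnum += 1
                        lr = (i - nx / 2.0) * sp
                        lt = (j - ny / 2.0) * sp
                        lz = spec.z_top - k * sp
                        if spec.pocket_size is not None:
                            if (abs(lr) < hx - eps and abs(lt) < hy - eps
                                    and lz > spec.z_top - dz + eps):
                                continue
                        xyz = (spec.body_center_radius * rhat + lr * rhat
                               + lt * that + np.array([0.0, 0.0, lz]))
                        if spec.conduit_radius is not None:
                            blocked = False
                            for ca_ang in conduit_angles:
                                axis_pt = np.array([np.cos(ca_ang),
                                                    np.sin(ca_ang), 0.0])
                                p = xyz - np.array([0.0, 0.0, spec.conduit_z])
                                t_par = max(p @ axis_pt, 0.0)
                                if (np.linalg.norm(p - t_par * axis_pt)
                                        < spec.conduit_radius + _R_ATOM):
                                    blocked = True
                                    break
                            if blocked:
                                continue
                        add(chain, resnum, "CA", xyz)

        if spec.pocket_size is not None:
            # lining truth over every chain-A atom (body and pore wall alike),
            # in the local frame of chain A's cavity box
            theta0 = (2 * np.pi / m) * 0.5
            rhat0 = np.array([np.cos(theta0), np.sin(theta0), 0.0])
            that0 = np.array([-np.sin(theta0), np.cos(theta0), 0.0])
            core_set, shell_set = set(), set()
            for chain, resnum, _, _, _, xyz in rows:
                if chain != _chain_name(0):
                    continue
                pt = np.array([xyz @ rhat0 - spec.body_center_radius,
                               xyz @ that0, xyz[2]])
                d = _box_distance(pt, cav_lo, cav_hi)
                # core: body-lattice atoms looking straight into the cavity
                # (pore-wall atoms near the box can be buried by the body face)
                if d <= 3.6 and resnum > 1000 and _faces_box(pt, cav_lo, cav_hi):
                    core_set.add((chain, resnum))
                if d <= 5.5:
                    shell_set.add((chain, resnum))
            pocket_wall_core = sorted(core_set)
            pocket_wall_shell = sorted(shell_set)

    model = _rows_to_model(rows, symmetry_order=m, source_id="synthetic-bundle")
    gate_wall_r = spec.clearance(zs[gate_ring]) + _R_ATOM
    truth = {
        "axis_direction": (0.0, 0.0, 1.0),
        "axis_origin": (0.0, 0.0, 0.0),
        "outer_boundary_z": spec.z_top,
        "inner_boundary_z": spec.z_bottom,
        "gate_radius": spec.gate_radius,
        "gate_diameter": 2.0 * spec.gate_radius,
        "gate_z": float(zs[gate_ring]),
        "gate_residues": gate_residues,
        "gate_ca_ring_radius": gate_wall_r + spec.ca_offset,
        "gate_opposing_ca_distance": 2.0 * (gate_wall_r + spec.ca_offset),
        "clearance_profile": {float(z): spec.clearance(z) for z in zs},
        "conduit_radius": spec.conduit_radius,
        "conduit_z": spec.conduit_z,
        "pocket_volume": pocket_volume,
        "pocket_depth": pocket_depth_true,
        "pocket_wall_core": pocket_wall_core,
        "pocket_wall_shell": pocket_wall_shell,
        "n_wall_residues_per_chain": n_wall_res,
    }
    return model, truth


def _box_distance(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    """Euclidean distance from a point to an axis-aligned box."""
    d = np.maximum(np.maximum(lo - p, 0.0), p - hi)
    return float(np.linalg.norm(d))


def _faces_box(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> bool:
    """True when the nearest box point lies on a face interior (not an edge or
    corner), i.e. the atom's exposed cap looks straight into the cavity."""
    d = np.maximum(np.maximum(lo - p, 0.0), p - hi)
    return int(np.count_nonzero(d > 1e-9)) == 1


def build_slab_with_cavity(cavity_dims: tuple = (10.0, 10.0, 6.0),
                           spacing: float = 1.5, probe: float = 1.4,
                           open_top: bool = True) -> tuple[StructureModel, dict]:
    """A single-chain atom slab with a drilled rectangular cavity.

    The atom lattice spacing is adjusted per axis so that the drill planes
    sit exactly one atom radius plus one probe radius outside the nominal
    cavity box — the region accessible to probe centres is then exactly
    ``wx x wy x depth`` (up to the between-atom clearance wobble).  With
    ``open_top`` False a solid lid seals the cavity below the surface: an
    occluded-cavity fixture (its free space shrinks by one erosion margin at
    top and bottom, reflected in the returned truth).  The truth record
    carries ``wall_core``/``wall_shell`` residue sets: face atoms within 4.0 Å of the free
    cavity box / all atoms within 5.5 Å of it — the unambiguous and the maximal lining
    sets for the default 4.5 Å contact cutoff.
    """
    wx, wy, depth = cavity_dims
    erode = _R_ATOM + probe
    # snap: per-axis lattice spacing such that the drill boundary is a plane
    hx, hy, dz = wx / 2.0 + erode, wy / 2.0 + erode, depth + erode
    kx = max(int(round(hx / spacing)), 2)
    ky = max(int(round(hy / spacing)), 2)
    kz = max(int(round(dz / spacing)), 2)
    sx, sy, sz = hx / kx, hy / ky, dz / kz
    n_x, n_y = kx + 3, ky + 3
    n_z = kz + 3
    eps = 1e-6

    if open_top:
        cav_lo = np.array([-wx / 2.0, -wy / 2.0, -depth])
        cav_hi = np.array([wx / 2.0, wy / 2.0, 0.0])
    else:   # lid at z=0 seals the top; free space eroded from both ends
        cav_lo = np.array([-wx / 2.0, -wy / 2.0, -depth])
        cav_hi = np.array([wx / 2.0, wy / 2.0, -erode])
    rows, wall_core, wall_shell = [], [], []
    resnum = 0
    z_levels = [-k * sz for k in range(n_z + 1)]
    if not open_top:
        z_levels += [sz, 2 * sz]
    for i in range(-n_x, n_x + 1):
        for j in range(-n_y, n_y + 1):
            for z in z_levels:
                x, y = i * sx, j * sy
                in_drill = (abs(x) < hx - eps and abs(y) < hy - eps
                            and z > -dz + eps)
                if not open_top:
                    in_drill = in_drill and z < -eps
                if in_drill:
                    continue
                resnum += 1
                rows.append(("A", resnum, "ALA", "CA", "C", np.array([x, y, z])))
                pt = np.array([x, y, z])
                d = _box_distance(pt, cav_lo, cav_hi)
                if d <= 3.6 and _faces_box(pt, cav_lo, cav_hi):
                    wall_core.append(("A", resnum))
                if d <= 5.5:
                    wall_shell.append(("A", resnum))
    model = _rows_to_model(rows, symmetry_order=1, source_id="synthetic-slab")
    free = cav_hi - cav_lo
    truth = {
        "volume": float(np.prod(free)),
        "depth": float(-cav_lo[2]),
        "cavity_lo": cav_lo, "cavity_hi": cav_hi,
        "outer_boundary_z": 0.0,
        "wall_core": wall_core, "wall_shell": wall_shell,
        "accessibility": "solvent_accessible" if open_top else "occluded",
    }
    return model, truth


def _rows_to_model(rows, symmetry_order: int, source_id: str) -> StructureModel:
    cols = list(zip(*rows))
    n = len(rows)
    return StructureModel(
        chain_ids=np.array(cols[0], dtype=object),
        residue_numbers=np.array(cols[1], dtype=int),
        residue_names=np.array(cols[2], dtype=object),
        atom_names=np.array(cols[3], dtype=object),
        elements=np.array(cols[4], dtype=object),
        positions=np.array([list(p) for p in cols[5]], dtype=float),
        occupancies=np.ones(n),
        is_hetero=np.zeros(n, bool),
        is_hydrogen=np.zeros(n, bool),
        symmetry_order=symmetry_order,
        source_id=source_id,
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class MsaSpec:
    """Plan for a synthetic alignment.

    ``core_columns`` are ungapped-in-reference columns; ``conservation`` (per
    column or scalar, in [0, 1]) is the probability mass on the column's
    consensus residue, the remainder spread over the column's class-target
    mixture (or uniformly over the 20 amino acids).  ``covarying_pairs`` are
    (i, j, strength) with column indices into the core region: with
    probability ``strength`` a sequence's residues at i and j jointly follow
    one of two hidden states, otherwise they are drawn independently.
    ``loops`` insert alignment blocks of per-sequence variable-length runs
    after a given core column.
    """

    n_sequences: int = 500
    core_columns: int = 100
    conservation: float | np.ndarray = 0.5
    class_targets: dict | list | None = None   # single dict or per-column list
    covarying_pairs: list = field(default_factory=list)
    gap_fraction: float | np.ndarray = 0.0
    loops: list = field(default_factory=list)
    # each loop: {"after": core_col(1-based), "max_len": int, "ref_len": int,
    #             "dist": ("fixed", k) | ("poisson", lam, offset) | ("choice", [...])}
    seed: int = 0

    def __post_init__(self) -> None:
        cons = np.broadcast_to(np.asarray(self.conservation, float),
                               (self.core_columns,)).copy()
        if np.any((cons < 0) | (cons > 1)):
            raise SpecError("conservation must lie in [0, 1]")
        self.conservation = cons
        self.gap_fraction = np.broadcast_to(np.asarray(self.gap_fraction, float),
                                            (self.core_columns,)).copy()
        for i, j, s in self.covarying_pairs:
            if i == j:
                raise SpecError("covarying pair with i == j")
            if not 0 <= s <= 1:
                raise SpecError("coupling strength must lie in [0, 1]")


def _column_distribution(rng: np.random.Generator, conservation: float,
                         class_target: dict | None) -> np.ndarray:
    """Probability vector over the 20 amino acids for one column."""
    if class_target is not None:
        base = np.zeros(20)
        for cls, frac in class_target.items():
            members = [AA_ORDER.index(a) for a in HEATMAP_CLASSES[cls]]
            for a in members:
                base[a] += frac / len(members)
        if base.sum() <= 0:
            raise SpecError("class targets sum to zero")
        base = base / base.sum()
    else:
        base = np.full(20, 1.0 / 20.0)
    consensus = int(rng.choice(20, p=base)) if base.max() < 1 else int(base.argmax())
    p = (1.0 - conservation) * base
    p[consensus] += conservation
    return p / p.sum()


def simulate_msa(spec: MsaSpec) -> tuple[AnnotatedAlignment, dict]:
    """Draw an alignment following the plan; returns (alignment, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.core_columns
    targets: list = [None] * L
    if isinstance(spec.class_targets, dict):
        targets = [spec.class_targets] * L
    elif isinstance(spec.class_targets, list):
        if len(spec.class_targets) != L:
            raise SpecError("class_targets list length must equal core_columns")
        targets = spec.class_targets

    dists = [_column_distribution(rng, spec.conservation[c], targets[c])
             for c in range(L)]
    core = np.empty((n, L), dtype=np.int8)
    for c in range(L):
        core[:, c] = rng.choice(20, size=n, p=dists[c])

    # planted covariation: two-state joint mixture overrides
    pair_states = {}
    for (i, j, strength) in spec.covarying_pairs:
        ci, cj = i - 1, j - 1
        state_res = rng.choice(20, size=(2, 2), replace=False)   # (state, col)
        hidden = rng.integers(0, 2, size=n)
        follow = rng.random(n) < strength
        core[follow, ci] = state_res[hidden[follow], 0]
        core[follow, cj] = state_res[hidden[follow], 1]
        pair_states[(i, j)] = state_res.tolist()

    gaps = rng.random((n, L)) < spec.gap_fraction[None, :]
    gaps[0, :] = False          # the reference row stays ungapped in the core

    # assemble with loop blocks
    loop_sorted = sorted(spec.loops, key=lambda d: d["after"])
    blocks = []
    ref_loop_lengths = {}
    seq_loop_lengths = {}
    prev = 0
    aa = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
    for li, loop in enumerate(loop_sorted):
        after = int(loop["after"])
        blocks.append(("core", prev, after))
        blocks.append(("loop", li))
        prev = after
    blocks.append(("core", prev, L))

    def draw_lengths(loop) -> np.ndarray:
        kind = loop["dist"][0]
        if kind == "fixed":
            return np.full(n, int(loop["dist"][1]))
        if kind == "poisson":
            lam, offset = loop["dist"][1], (loop["dist"][2] if len(loop["dist"]) > 2 else 0)
            return rng.poisson(lam, size=n) + offset
        if kind == "choice":
            return rng.choice(np.asarray(loop["dist"][1], int), size=n)
        raise SpecError(f"unknown loop length distribution {kind!r}")

    parts = [[] for _ in range(n)]
    for blk in blocks:
        if blk[0] == "core":
            _, a, b = blk
            for s in range(n):
                chars = aa[core[s, a:b]].tobytes().decode()
                if spec.gap_fraction.any():
                    chars = "".join(GAP if gaps[s, c] else ch
                                    for ch, c in zip(chars, range(a, b)))
                parts[s].append(chars)
        else:
            loop = loop_sorted[blk[1]]
            lengths = draw_lengths(loop)
            lengths[0] = int(loop.get("ref_len", lengths[0]))
            width = max(int(loop["max_len"]), int(lengths.max()))
            name = loop.get("name", f"loop{blk[1]}")
            ref_loop_lengths[name] = int(lengths[0])
            seq_loop_lengths[name] = lengths.copy()
            for s in range(n):
                k = min(int(lengths[s]), width)
                fill = aa[rng.integers(0, 20, size=k)].tobytes().decode()
                parts[s].append(fill + GAP * (width - k))

    ids = ["REF"] + [f"seq{i:05d}" for i in range(1, n)]
    rows = ["".join(p) for p in parts]
    aln = AnnotatedAlignment(ids=ids, rows=rows, reference_id="REF")
    truth = {
        "column_distributions": np.array(dists),
        "conservation": spec.conservation.copy(),
        "class_targets": targets,
        "covarying_pairs": [(i, j, s) for i, j, s in spec.covarying_pairs],
        "pair_states": pair_states,
        "gap_fraction": spec.gap_fraction.copy(),
        "ref_loop_lengths": ref_loop_lengths,
        "seq_loop_lengths": seq_loop_lengths,
        "core_columns": L,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(n_leaves: int, named_clades: dict | None = None,
                  seed: int = 0) -> tuple[Tree, dict]:
    """Random rooted binary tree containing the named clades as true
    monophyletic groups.

    ``named_clades`` maps a clade name to a leaf count; clade leaves are
    labelled ``<name>_<k>``, the remainder ``t<k>``.  Branch lengths are
    exponential(1).
    """
    named_clades = named_clades or {}
    total = sum(named_clades.values())
    if total > n_leaves:
        raise SpecError(f"clade sizes sum to {total} > n_leaves={n_leaves}")
    for nm, size in named_clades.items():
        if size < 1:
            raise SpecError(f"clade {nm!r} must have >= 1 leaf")
    rng = np.random.default_rng(seed)

    def join_random(units: list) -> str:
        units = list(units)
        while len(units) > 1:
            i, j = sorted(rng.choice(len(units), size=2, replace=False))
            b = units.pop(j)
            a = units.pop(i)
            la, lb = rng.exponential(1.0), rng.exponential(1.0)
            units.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
        return units[0]

    truth_clades = {}
    units = []
    for nm, size in named_clades.items():
        leaves = [f"{nm}_{k}" for k in range(size)]
        truth_clades[nm] = set(leaves)
        units.append(join_random(leaves))
    n_rest = n_leaves - total
    units.extend(f"t{k}" for k in range(n_rest))
    if len(units) == 1:
        newick = units[0] + ";"
    else:
        newick = join_random(units) + ";"
    tree = read_newick(newick)
    return tree, {"clades": truth_clades, "n_leaves": n_leaves}
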