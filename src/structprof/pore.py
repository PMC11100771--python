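"""Ion-conduction pathway profiling for symmetric channels.

A deterministic re-implementation of the classic pore-radius profiler: at
each slice along the channel axis the pore centre is the point of maximal
clearance (distance to the nearest van der Waals surface), found by a
multi-start local search seeded on a fixed lattice around the previous
slice's centre.  No stochastic annealing is used, so profiles are bit-stable
across runs.  The same clearance objective, marched radially instead of
axially, traces the lateral conduits of a quadrivial pore (one central
extracellular pathway splitting into four intersubunit exits).

Diameters are 2x the clearance radius with radii from
:data:`structprof.geometry.VDW_RADII`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import RADII_VERSION, GeometryError, atom_radii
from .structio import StructureModel

log = logging.getLogger("structprof")

__all__ = ["AxisFrame", "PoreProfile", "find_symmetry_axis", "pore_profile",
           "gate_report", "lateral_conduits"]

# residue types counted by the hydrophobic-belt membrane heuristic
_HYDROPHOBIC_RES = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "PRO"}


@dataclass(frozen=True)
class AxisFrame:
    """A channel axis with an orthonormal in-plane basis and membrane planes.

    ``outer_boundary_z``/``inner_boundary_z`` are axis coordinates (Å along
    ``direction`` from ``origin``) of the extracellular and cytosolic
    membrane boundaries; outer > inner.
    """

    origin: np.ndarray
    direction: np.ndarray
    outer_boundary_z: float | None = None
    inner_boundary_z: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            d = d / np.linalg.norm(d)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        if (self.outer_boundary_z is not None and self.inner_boundary_z is not None
                and not self.outer_boundary_z > self.inner_boundary_z):
            raise GeometryError("outer_boundary_z must exceed inner_boundary_z")

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane basis (u, v)."""
        d = self.direction
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v

    def axial(self, points: np.ndarray) -> np.ndarray:
        """Axis coordinate(s) of points."""
        return (np.atleast_2d(points) - self.origin) @ self.direction

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """(u, v, axis) coordinates of points."""
        u, v = self.basis
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ u, rel @ v, rel @ self.direction])

    def from_frame(self, q: np.ndarray) -> np.ndarray:
        u, v = self.basis
        q = np.atleast_2d(q)
        return self.origin + np.outer(q[:, 0], u) + np.outer(q[:, 1], v) \
            + np.outer(q[:, 2], self.direction)


@dataclass
class PoreProfile:
    """Radius along a conduction path; ``axis_position`` strictly monotonic."""

    axis_position: np.ndarray   # Å along the path
    centers: np.ndarray         # (n, 3) world coordinates
    radius: np.ndarray          # Å, >= 0
    occluded: np.ndarray        # True where the slice had no positive clearance
    path_type: str = "central"  # or "lateral"

    def __post_init__(self) -> None:
        steps = np.diff(self.axis_position)
        if len(steps) and not (np.all(steps > 0) or np.all(steps < 0)):
            raise GeometryError("axis_position must be strictly monotonic")

    @property
    def min_radius(self) -> float:
        return float(self.radius.min())

    @property
    def min_diameter(self) -> float:
        return 2.0 * self.min_radius

    def min_in_window(self, center: float, half_width: float) -> tuple[float, float]:
        """(axis_position, radius) of the minimum within ±half_width of center."""
        mask = np.abs(self.axis_position - center) <= half_width
        if not mask.any():
            raise GeometryError(f"no profile samples within ±{half_width} of {center}")
        idx = np.flatnonzero(mask)[np.argmin(self.radius[mask])]
        return float(self.axis_position[idx]), float(self.radius[idx])

    def to_frame_df(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis_position": self.axis_position,
            "x": self.centers[:, 0], "y": self.centers[:, 1], "z": self.centers[:, 2],
            "radius": self.radius, "occluded": self.occluded,
        })


# ---------------------------------------------------------------------------
# Symmetry axis
# ---------------------------------------------------------------------------

def _membrane_band(model: StructureModel, axis_origin, axis_dir) -> tuple[float, float]:
    """Hydrophobic-belt heuristic for the membrane slab along the axis.

    Falls back to the 2nd/98th percentile of the atom extent when residue
    names carry no hydrophobicity information.
    """
    heavy = model.heavy()
    s = (heavy.positions - axis_origin) @ axis_dir
    hydro = np.isin(heavy.residue_names, list(_HYDROPHOBIC_RES)) & (heavy.elements == "C")
    if hydro.sum() >= 20 and hydro.mean() < 0.98:
        sh = np.sort(s[hydro])
        return float(np.percentile(sh, 98)), float(np.percentile(sh, 2))
    return float(np.percentile(s, 98)), float(np.percentile(s, 2))


def find_symmetry_axis(model: StructureModel,
                       outer_boundary_z: float | None = None,
                       inner_boundary_z: float | None = None,
                       refine: bool = True) -> AxisFrame:
    """Locate the n-fold symmetry axis of a multi-chain assembly.

    The axis passes through the assembly centroid; its direction is
    initialised from the plane of the chain centroids and refined by
    minimising the summed squared distance between each chain's Cα set,
    rotated by 2π/n about the axis, and the next chain's (chains ordered by
    angle about the axis).  Membrane boundary planes default to the
    hydrophobic-belt heuristic.
    """
    order = model.symmetry_order
    chains = model.chains
    if order < 2 or len(chains) < 2:
        raise GeometryError("need symmetry_order >= 2 and >= 2 chains")
    ca_sets = []
    for c in chains:
        resnums, coords = model.ca_coords(chain=c)
        ca_sets.append((list(map(int, resnums)), coords))
    shared = set(ca_sets[0][0])
    for rn, _ in ca_sets[1:]:
        shared &= set(rn)
    if not shared:
        raise GeometryError("chains share no residues; cannot pair symmetry mates")
    coords_per_chain = []
    for rn, coords in ca_sets:
        idx = {r: i for i, r in enumerate(rn)}
        coords_per_chain.append(coords[[idx[r] for r in sorted(shared)]])
    coords_per_chain = np.array(coords_per_chain)       # (m, k, 3)
    centroid = coords_per_chain.reshape(-1, 3).mean(axis=0)

    chain_cent = coords_per_chain.mean(axis=1)          # (m, 3)
    rel = chain_cent - chain_cent.mean(axis=0)
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    direction = vt[-1]                                  # plane normal
    if direction[2] < 0 or (direction[2] == 0 and direction[0] < 0):
        direction = -direction

    def objective(params: np.ndarray) -> float:
        dx, dy, ox, oy = params
        d = direction + dx * u0 + dy * v0
        d = d / np.linalg.norm(d)
        o = centroid + ox * u0 + oy * v0
        theta = 2.0 * np.pi / order
        K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        # order chains by angle about the axis
        u, v = AxisFrame(origin=o, direction=d).basis
        ang = np.arctan2((chain_cent - o) @ v, (chain_cent - o) @ u)
        perm = np.argsort(ang)
        total = 0.0
        for i in range(len(perm)):
            a = coords_per_chain[perm[i]] - o
            b = coords_per_chain[perm[(i + 1) % len(perm)]] - o
            total += np.mean(np.sum((a @ R.T - b) ** 2, axis=1))
        return total

    if refine:
        u0, v0 = AxisFrame(origin=centroid, direction=direction).basis
        res = minimize(objective, np.zeros(4), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
        dx, dy, ox, oy = res.x
        direction = direction + dx * u0 + dy * v0
        direction = direction / np.linalg.norm(direction)
        centroid = centroid + ox * u0 + oy * v0
        if direction[2] < 0 or (direction[2] == 0 and direction[0] < 0):
            direction = -direction

    if outer_boundary_z is None or inner_boundary_z is None:
        outer_h, inner_h = _membrane_band(model, centroid, direction)
        outer_boundary_z = outer_h if outer_boundary_z is None else outer_boundary_z
        inner_boundary_z = inner_h if inner_boundary_z is None else inner_boundary_z
    return AxisFrame(origin=centroid, direction=direction,
                     outer_boundary_z=outer_boundary_z,
                     inner_boundary_z=inner_boundary_z)


# ---------------------------------------------------------------------------
# Clearance machinery
# ---------------------------------------------------------------------------

class _Clearance:
    """Min distance-to-surface evaluator over (a subset of) atoms."""

    def __init__(self, model: StructureModel, include_hetero: bool = False):
        heavy = model.heavy(include_hetero=include_hetero)
        self.coords = heavy.positions
        self.radii = atom_radii(heavy)
        self.max_r = float(self.radii.max())

    def subset_window(self, axis: AxisFrame, s: float, half_width: float) -> "_Clearance":
        mask = np.abs(axis.axial(self.coords) - s) <= half_width
        sub = object.__new__(_Clearance)
        sub.coords = self.coords[mask]
        sub.radii = self.radii[mask]
        sub.max_r = self.max_r
        return sub

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        if self.coords.shape[0] == 0:
            return np.full(pts.shape[0], np.inf)
        d = np.sqrt(((pts[:, None, :] - self.coords[None, :, :]) ** 2).sum(axis=2))
        return (d - self.radii[None, :]).min(axis=1)


def _search_slice(clear: _Clearance, center0: np.ndarray, u: np.ndarray, v: np.ndarray,
                  wander_radius: float) -> tuple[np.ndarray, float]:
    """Best clearance point in the plane spanned by (u, v) through center0,
    within wander_radius; deterministic multi-start + Nelder-Mead polish."""
    angles = np.arange(8) * (np.pi / 4.0)
    offsets = [np.zeros(2)]
    for frac in (1.0 / 3.0, 2.0 / 3.0, 1.0):
        r = frac * wander_radius
        offsets.extend(np.column_stack([r * np.cos(angles), r * np.sin(angles)]))
    offsets = np.array(offsets)
    pts = center0 + offsets[:, :1] * u + offsets[:, 1:] * v
    vals = clear(pts)
    best_starts = offsets[np.argsort(vals)[::-1][:3]]

    def neg(xy: np.ndarray) -> float:
        rad = np.hypot(*xy)
        penalty = 1e3 * max(0.0, rad - wander_radius) ** 2
        p = center0 + xy[0] * u + xy[1] * v
        return -float(clear(p[None, :])[0]) + penalty

    best_xy, best_val = None, np.inf
    for x0 in best_starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 80})
        if res.fun < best_val:
            best_val, best_xy = res.fun, res.x
    point = center0 + best_xy[0] * u + best_xy[1] * v
    return point, -best_val


# ---------------------------------------------------------------------------
# Central profile
# ---------------------------------------------------------------------------

def pore_profile(model: StructureModel, axis: AxisFrame,
                 z_range: tuple[float, float] | None = None,
                 step: float = 0.25, wander_radius: float = 3.0,
                 include_hetero: bool = False) -> PoreProfile:
    """Radius of the central pathway along the axis.

    At each slice (spacing ``step``) the centre maximises the clearance to
    the nearest atom surface within ``wander_radius`` of the previous
    centre.  Occluded slices report radius 0 and are flagged.
    """
    log.info("pore_profile: radii table %s, step %.2f Å, wander %.1f Å",
             RADII_VERSION, step, wander_radius)
    clear = _Clearance(model, include_hetero=include_hetero)
    if z_range is None:
        if axis.outer_boundary_z is None or axis.inner_boundary_z is None:
            s_all = axis.axial(clear.coords)
            z_range = (float(s_all.min()), float(s_all.max()))
        else:
            z_range = (axis.inner_boundary_z, axis.outer_boundary_z)
    lo, hi = min(z_range), max(z_range)
    u, v = axis.basis
    slices = np.arange(hi, lo - 1e-9, -step)   # march extracellular -> cytosol
    centers = np.empty((len(slices), 3))
    radii = np.empty(len(slices))
    occluded = np.zeros(len(slices), bool)
    prev_xy = np.zeros(2)
    window = 12.0
    for i, s in enumerate(slices):
        sub = clear.subset_window(axis, s, window)
        center0 = axis.from_frame(np.array([[prev_xy[0], prev_xy[1], s]]))[0]
        point, val = _search_slice(sub, center0, u, v, wander_radius)
        if val >= window - sub.max_r:   # window may have clipped the true minimum
            point, val = _search_slice(clear, center0, u, v, wander_radius)
        centers[i] = point
        if val < 0:
            radii[i] = 0.0
            occluded[i] = True
        else:
            radii[i] = val
            q = axis.to_frame(point[None, :])[0]
            prev_xy = q[:2]
    order = np.argsort(slices)
    return PoreProfile(axis_position=slices[order], centers=centers[order],
                       radius=radii[order], occluded=occluded[order],
                       path_type="central")


def gate_report(profile: PoreProfile, model: StructureModel, gate_residues,
                axis: AxisFrame, half_width: float = 2.0) -> pd.DataFrame:
    """Per-gate-residue minimum diameter near the residue's side-chain slice.

    ``gate_residues`` is a list of residue numbers (all chains pooled — gates
    of a symmetric channel are rings).  The slice searched is ±``half_width``
    of the residue's side-chain centroid axis coordinate.
    """
    rows = []
    backbone = {"N", "CA", "C", "O", "OXT"}
    for resnum in gate_residues:
        mask = (model.residue_numbers == resnum) & ~model.is_hetero & ~model.is_hydrogen
        if not mask.any():
            raise GeometryError(f"gate residue {resnum} not found")
        side = mask & ~np.isin(model.atom_names, list(backbone))
        use = side if side.any() else mask
        centroid_s = float(axis.axial(model.positions[use]).mean())
        if not (profile.axis_position.min() - half_width <= centroid_s
                <= profile.axis_position.max() + half_width):
            raise GeometryError(f"gate residue {resnum} lies outside the profiled range")
        pos, rad = profile.min_in_window(centroid_s, half_width)
        name = model.residue_names[mask][0]
        rows.append({"residue": f"{name}{resnum}", "residue_number": resnum,
                     "slice_position": pos, "diameter": 2.0 * rad})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lateral conduits
# ---------------------------------------------------------------------------

def lateral_conduits(model: StructureModel, axis: AxisFrame, vestibule_z: float,
                     n: int | None = None, step: float = 0.5,
                     wander_radius: float = 2.0,
                     include_hetero: bool = False) -> list[PoreProfile]:
    """Trace the n symmetry-related lateral exits from the central vestibule.

    Each conduit is marched radially outward from the vestibule centre along
    a direction bisecting two adjacent subunits, re-optimising the centre in
    the transverse plane at every step.  A conduit is reported only if it
    reaches bulk solvent (escapes the protein's radial extent) without the
    clearance collapsing below zero.
    """
    n = n or model.symmetry_order
    clear = _Clearance(model, include_hetero=include_hetero)
    u, v = axis.basis
    center0 = axis.from_frame(np.array([[0.0, 0.0, vestibule_z]]))[0]
    start, r0 = _search_slice(clear, center0, u, v, wander_radius=3.0)
    if r0 <= 0:
        raise GeometryError(f"vestibule slice at z={vestibule_z} is occluded")

    # angular positions of the chains -> conduit directions bisect them
    chain_angles = []
    for c in model.chains:
        _, coords = model.ca_coords(chain=c)
        q = axis.to_frame(coords).mean(axis=0)
        chain_angles.append(np.arctan2(q[1], q[0]))
    chain_angles = np.sort(np.array(chain_angles))
    bis = [(chain_angles[i] + chain_angles[(i + 1) % len(chain_angles)]
            + (2 * np.pi if i + 1 == len(chain_angles) else 0)) / 2.0
           for i in range(len(chain_angles))][:n]

    q_all = axis.to_frame(clear.coords)
    r_escape = float(np.hypot(q_all[:, 0], q_all[:, 1]).max()) + 2.0

    conduits = []
    for angle in bis:
        radial = np.cos(angle) * u + np.sin(angle) * v
        trans = np.cross(axis.direction, radial)   # transverse in-plane basis
        plane_u, plane_v = axis.direction, trans
        path_pos, path_centers, path_radii, path_occ = [], [], [], []
        point = start.copy()
        arc = 0.0
        escaped = False
        q0 = axis.to_frame(start[None, :])[0]
        start_rad = np.hypot(q0[0], q0[1])
        for _ in range(int((r_escape - start_rad) / step) + 4):
            point = point + step * radial
            arc += step
            point, val = _search_slice(clear, point, plane_u, plane_v, wander_radius)
            path_pos.append(arc)
            path_centers.append(point)
            path_radii.append(max(val, 0.0))
            path_occ.append(val < 0)
            q = axis.to_frame(point[None, :])[0]
            if np.hypot(q[0], q[1]) >= r_escape - 1.0:
                escaped = val > 0
                break
            if val < 0:
                break
        if escaped and path_pos:
            conduits.append(PoreProfile(
                axis_position=np.array(path_pos), centers=np.array(path_centers),
                radius=np.array(path_radii), occluded=np.array(path_occ),
                path_type="lateral"))
    if not conduits:
        log.warning("lateral_conduits: no egress found from vestibule at z=%.1f",
                    vestibule_z)
    return conduits
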