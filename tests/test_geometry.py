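"""Superposition, distance matrices, SASA, interfaces, cross distances.

Oracles: an exhaustive rotation-grid search for the Kabsch step, closed-form
sphere/sphere-cap formulas for SASA, and brute-force O(n²) scans for contact
and neighbour searches.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import structprof as sp
from structprof.geometry import GeometryError, sphere_points, vdw_radius

rng = np.random.default_rng(7)


def random_rigid(seed=0):
    g = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(g.integers(2**31))).as_matrix()
    t = g.normal(scale=10.0, size=3)
    return R, t


# ---------------------------------------------------------------------------
# superpose
# ---------------------------------------------------------------------------

def test_superpose_identity():
    x = rng.normal(size=(12, 3))
    res = sp.superpose(x, x)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
    assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-6


def test_superpose_recovers_known_rotation_with_noise_vs_grid_oracle():
    """RMSD after Kabsch agrees with an exhaustive fine rotation-grid search."""
    x = rng.normal(scale=4.0, size=(10, 3))
    R_true, t_true = random_rigid(seed=3)
    y = x @ R_true.T + t_true + rng.normal(scale=0.1, size=(10, 3))
    res = sp.superpose(x, y)

    # oracle: greedy-refined grid over rotation space (coarse-to-fine),
    # searching the rotation that minimises RMSD after optimal translation
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    def rmsd_of(Rm):
        return np.sqrt(np.mean(np.sum((xc @ Rm.T - yc) ** 2, axis=1)))

    best = (np.inf, None)
    for rv in Rotation.create_group("O").as_rotvec():       # 24 starts
        center = rv
        step = 0.4
        for _ in range(40):
            cands = [center] + [center + step * d for d in
                                np.vstack([np.eye(3), -np.eye(3)])]
            vals = [(rmsd_of(Rotation.from_rotvec(c).as_matrix()), tuple(c))
                    for c in cands]
            vmin, cmin = min(vals)
            if np.allclose(cmin, center):
                step *= 0.5
            center = np.array(cmin)
        if vmin < best[0]:
            best = (vmin, center)
    assert res.rmsd == pytest.approx(best[0], abs=1e-3)


def test_superpose_argument_symmetry_and_rigid_invariance():
    x = rng.normal(size=(20, 3))
    y = x + rng.normal(scale=0.3, size=(20, 3))
    r1 = sp.superpose(x, y).rmsd
    r2 = sp.superpose(y, x).rmsd
    assert r1 == pytest.approx(r2, abs=1e-9)
    R, t = random_rigid(seed=11)
    r3 = sp.superpose(x @ R.T + t, y).rmsd
    assert r3 == pytest.approx(r1, abs=1e-9)


def test_superpose_errors():
    with pytest.raises(GeometryError):
        sp.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(GeometryError):
        sp.superpose(line, line)


# ---------------------------------------------------------------------------
# rmsd_matrix / distance difference
# ---------------------------------------------------------------------------

def test_rmsd_matrix_identical_models_and_symmetry(bundle):
    model, _ = bundle
    sub = sp.select(model, chains=["A"])
    mat = sp.rmsd_matrix([sub, sub, sub])
    assert np.allclose(mat, 0.0, atol=1e-9)

    R, t = random_rigid(seed=5)
    moved = sub.transformed(R, t)
    mat2 = sp.rmsd_matrix([sub, moved])
    assert mat2[0, 1] == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(mat2, mat2.T)


def test_distance_difference_zero_and_rigid_invariance(bundle):
    model, _ = bundle
    sub = sp.select(model, chains=["A"])
    ddm = sp.distance_difference(sub, sub)
    assert np.allclose(ddm.values, 0.0)
    assert np.allclose(ddm.values, ddm.values.T)
    R, t = random_rigid(seed=13)
    ddm2 = sp.distance_difference(sub, sub.transformed(R, t))
    assert np.allclose(ddm2.values, 0.0, atol=1e-9)


def test_distance_difference_flags_translated_helix():
    """Moving one (minority) helix gives its rows the largest mean change."""
    n = 40
    coords = np.zeros((n, 3))
    coords[:, 2] = np.arange(n) * 1.5
    coords[32:, 0] = 8.0
    model_a = _chain_model(coords)
    coords_b = coords.copy()
    coords_b[32:, 0] += 2.0          # translate the short second helix
    model_b = _chain_model(coords_b)
    ddm = sp.distance_difference(model_a, model_b)
    moved = ddm.per_residue_score[32:]
    untouched = ddm.per_residue_score[:32]
    assert moved.min() > untouched.max()


def _chain_model(coords, chain="A"):
    n = len(coords)
    return sp.StructureModel(
        chain_ids=np.array([chain] * n, dtype=object),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        positions=np.asarray(coords, float),
        occupancies=np.ones(n),
        is_hetero=np.zeros(n, bool),
        is_hydrogen=np.zeros(n, bool),
    )


# ---------------------------------------------------------------------------
# contact map
# ---------------------------------------------------------------------------

def test_contact_map_cutoff_boundary():
    coords = np.array([[0.0, 0, 0], [7.9, 0, 0], [100.0, 0, 0], [108.1, 0, 0]])
    cm = sp.contact_map(_chain_model(coords), cutoff=8.0)
    assert cm.contacts[0, 1] and cm.contacts[1, 0]
    assert not cm.contacts[2, 3]           # 8.1 Å > cutoff
    assert not cm.contacts.diagonal().any()


def test_contact_map_matches_brute_force_oracle():
    coords = rng.normal(scale=8.0, size=(50, 3))
    model = _chain_model(coords)
    cm = sp.contact_map(model, cutoff=8.0, min_sequence_separation=3)
    for i in range(50):
        for j in range(50):
            d = np.linalg.norm(coords[i] - coords[j])
            expected = (d <= 8.0) and abs(i - j) >= 3
            assert cm.contacts[i, j] == expected


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_sasa_isolated_atom_closed_form():
    model = _chain_model(np.zeros((1, 3)))
    res = sp.sasa(model)
    r = vdw_radius("C") + 1.4
    assert res.total == pytest.approx(4 * np.pi * r**2, rel=0.01)


def test_sasa_far_separated_atoms_additive():
    model = _chain_model(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
    res = sp.sasa(model)
    r = vdw_radius("C") + 1.4
    assert res.total == pytest.approx(2 * 4 * np.pi * r**2, rel=0.01)
    assert np.all(res.atom_areas >= 0)
    assert res.residue_areas.sum() == pytest.approx(res.total, abs=1e-9)


@pytest.mark.parametrize("d", [1.5, 3.0, 4.5])
def test_sasa_two_overlapping_spheres_matches_cap_formula(d):
    """Two equal spheres at distance d: exposed area per sphere is
    4πR² − 2πR·h with cap height h = R − d/2 (R = vdW + probe)."""
    model = _chain_model(np.array([[0.0, 0, 0], [d, 0, 0]]))
    res = sp.sasa(model, point_density=1920)
    R = vdw_radius("C") + 1.4
    h = R - d / 2.0
    expected = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
    assert res.total == pytest.approx(expected, rel=0.02)


def test_sasa_rigid_motion_invariance_and_monotonicity():
    coords = rng.normal(scale=3.0, size=(20, 3))
    model = _chain_model(coords)
    t1 = sp.sasa(model, point_density=480).total
    R, t = random_rigid(seed=2)
    t2 = sp.sasa(model.transformed(R, t), point_density=480).total
    # the lattice is fixed in space, so rotation invariance holds only to
    # sampling accuracy; repeating the same input is bit-identical
    assert t1 == pytest.approx(t2, rel=0.01)
    assert sp.sasa(model, point_density=480).total == t1
    # adding a nearby atom cannot increase any existing atom's area
    crowded = _chain_model(np.vstack([coords, coords[0] + [2.0, 0, 0]]))
    a1 = sp.sasa(model, point_density=480).atom_areas
    a2 = sp.sasa(crowded, point_density=480).atom_areas[:20]
    assert np.all(a2 <= a1 + 1e-9)


# ---------------------------------------------------------------------------
# buried interface area
# ---------------------------------------------------------------------------

def test_buried_area_zero_for_separated_chains():
    a = _chain_model(rng.normal(scale=2.0, size=(8, 3)), chain="A")
    b = _chain_model(rng.normal(scale=2.0, size=(8, 3)) + 100.0, chain="B")
    both = _concat(a, b)
    res = sp.buried_area_per_subunit(both, "A", point_density=480)
    assert res["total"] == pytest.approx(0.0, abs=1e-6)


def test_buried_area_two_helix_dimer_vs_high_density_oracle():
    """Buried area equals the direct SASA difference at 4x point density."""
    za = np.arange(12) * 1.5
    a = np.column_stack([np.zeros(12), np.zeros(12), za])
    b = np.column_stack([np.full(12, 4.5), np.zeros(12), za])
    dimer = _concat(_chain_model(a, "A"), _chain_model(b, "B"))
    res = sp.buried_area_per_subunit(dimer, "A", point_density=960)
    alone = sp.sasa(_chain_model(a, "A"), point_density=3840)
    chain_a_in_complex = sum(
        ar for (c, r, _), ar in zip(
            sp.sasa(dimer, point_density=3840).residue_keys,
            sp.sasa(dimer, point_density=3840).residue_areas) if c == "A")
    oracle = alone.total - chain_a_in_complex
    assert res["total"] > 0
    assert res["total"] == pytest.approx(oracle, rel=0.03)


def test_buried_area_region_split_and_overlap_error(bundle):
    model, _ = bundle
    res = sp.buried_area_per_subunit(
        model, "A", regions={"wall": (1, 75), "body": (1001, 4000)},
        point_density=240)
    assert res["total"] > 0
    assert res["regions"]["wall"] + res["regions"]["body"] == \
        pytest.approx(res["total"], rel=0.01)
    with pytest.raises(GeometryError):
        sp.buried_area_per_subunit(model, "A",
                                   regions={"a": (1, 50), "b": (40, 80)})


def _concat(a, b):
    return sp.StructureModel(
        chain_ids=np.concatenate([a.chain_ids, b.chain_ids]),
        residue_numbers=np.concatenate([a.residue_numbers, b.residue_numbers]),
        residue_names=np.concatenate([a.residue_names, b.residue_names]),
        atom_names=np.concatenate([a.atom_names, b.atom_names]),
        elements=np.concatenate([a.elements, b.elements]),
        positions=np.vstack([a.positions, b.positions]),
        occupancies=np.concatenate([a.occupancies, b.occupancies]),
        is_hetero=np.concatenate([a.is_hetero, b.is_hetero]),
        is_hydrogen=np.concatenate([a.is_hydrogen, b.is_hydrogen]),
        symmetry_order=a.symmetry_order,
    )


# ---------------------------------------------------------------------------
# cross distances and neighbours
# ---------------------------------------------------------------------------

def test_cross_distance_on_circle_of_radius_5():
    coords, chains = [], []
    for k, c in enumerate("ABCD"):
        ang = k * np.pi / 2
        coords.append([5 * np.cos(ang), 5 * np.sin(ang), 0.0])
        chains.append(c)
    model = sp.StructureModel(
        chain_ids=np.array(chains, dtype=object),
        residue_numbers=np.full(4, 10),
        residue_names=np.array(["ILE"] * 4, dtype=object),
        atom_names=np.array(["CA"] * 4, dtype=object),
        elements=np.array(["C"] * 4, dtype=object),
        positions=np.array(coords),
        occupancies=np.ones(4), is_hetero=np.zeros(4, bool),
        is_hydrogen=np.zeros(4, bool), symmetry_order=4)
    assert sp.cross_distance(model, 10, mode="opposing") == pytest.approx(10.0, abs=1e-9)
    assert sp.cross_distance(model, 10, mode="adjacent") == \
        pytest.approx(5 * np.sqrt(2), abs=1e-6)


def test_cross_distance_recovers_bundle_truth(bundle, open_bundle):
    for (model, truth) in (bundle, open_bundle):
        res = truth["gate_residues"][0]
        d = sp.cross_distance(model, res)
        assert d == pytest.approx(truth["gate_opposing_ca_distance"], abs=0.05)


def test_neighbor_residues_brute_force_oracle():
    coords = rng.normal(scale=6.0, size=(200, 3))
    model = _chain_model(coords)
    query = coords[:3]
    got = sp.neighbor_residues(model, query, cutoff=5.0)
    expected = set()
    for i, c in enumerate(coords):
        if np.min(np.linalg.norm(query - c, axis=1)) <= 5.0:
            expected.add(("A", i + 1))
    assert set(got) == expected
    # cutoff below the smallest gap but a self-query still hits its own residue
    tiny = sp.neighbor_residues(model, query + 500.0, cutoff=0.5)
    assert len(tiny) == 0


def test_neighbor_residues_empty_query_error(bundle):
    model, _ = bundle
    with pytest.raises(GeometryError):
        sp.neighbor_residues(model, np.zeros((0, 3)), cutoff=4.0)
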