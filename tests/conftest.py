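"""Shared fixtures: synthetic channels, cavity slabs, and alignments.

Everything is generated at session scope with fixed seeds so the suite needs
no data files and stays deterministic.
"""

import numpy as np
import pytest

import structprof as sp
from structprof.pore import AxisFrame


@pytest.fixture(scope="session")
def bundle():
    """Default closed-gate C4 bundle (gate diameter 2.5 Å) with truth."""
    return sp.build_bundle(sp.BundleSpec())


@pytest.fixture(scope="session")
def open_bundle():
    """Open-gate state of the same bundle (gate diameter 3.2 Å)."""
    return sp.build_bundle(sp.BundleSpec(gate_radius=1.6, ca_offset=2.6))


@pytest.fixture(scope="session")
def bundle_axis(bundle):
    _, truth = bundle
    return AxisFrame(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                     outer_boundary_z=truth["outer_boundary_z"],
                     inner_boundary_z=truth["inner_boundary_z"])


@pytest.fixture(scope="session")
def pocket_bundle():
    """Bundle whose chain-A body carries a drilled ~600 Å^3, ~12 Å pocket."""
    return sp.build_bundle(sp.BundleSpec(pocket_size=(8.8, 5.8, 11.9),
                                         body_size=(21.0, 18.0, 18.0)))


@pytest.fixture(scope="session")
def slab():
    """Open 10x10x6 Å drilled cavity in a single-chain slab."""
    return sp.build_slab_with_cavity()


@pytest.fixture(scope="session")
def sealed_slab():
    return sp.build_slab_with_cavity(open_top=False)


@pytest.fixture(scope="session")
def slab_axis():
    return AxisFrame(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                     outer_boundary_z=0.0, inner_boundary_z=-12.0)


@pytest.fixture(scope="session")
def slab_pocket(slab, slab_axis):
    model, _ = slab
    pockets = sp.detect_pockets(model, slab_axis)
    assert pockets, "slab fixture must contain a detectable pocket"
    return pockets[0]


@pytest.fixture(scope="session")
def coupled_msa():
    """1000 x 200 alignment with 10 planted covarying pairs."""
    pairs = [(10 * k + 1, 10 * k + 6, 0.9) for k in range(10)]
    spec = sp.MsaSpec(n_sequences=1000, core_columns=200, conservation=0.3,
                      covarying_pairs=pairs, seed=41)
    aln, truth = sp.simulate_msa(spec)
    return aln, truth


@pytest.fixture(scope="session")
def slab_mc_volume(slab):
    """10^6-point Monte-Carlo estimate of the slab cavity's probe-accessible
    volume (all sub-surface free space of the slab is the cavity)."""
    from structprof.geometry import atom_radii
    model, _ = slab
    heavy = model.heavy()
    radii = atom_radii(heavy) + 1.4
    g = np.random.default_rng(23)
    lo = np.array([-9.0, -9.0, -10.0])
    hi = np.array([9.0, 9.0, 0.0])
    n = 1_000_000
    kept = 0
    for _ in range(10):
        pts = g.uniform(lo, hi, size=(n // 10, 3))
        for start in range(0, heavy.n_atoms, 600):
            sub = heavy.positions[start:start + 600]
            r = radii[start:start + 600]
            d2 = ((pts[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
            pts = pts[~(d2 < (r ** 2)[None, :]).any(axis=1)]
        kept += len(pts)
    return float(np.prod(hi - lo)) * kept / n


@pytest.fixture(scope="session")
def steel_dwass_null_fwer():
    """Fraction of 10^4 null replicates (3 i.i.d. normal groups of 10) where
    any pair is declared significant at the 0.05 level."""
    from scipy import stats as sps
    from structprof.stats import pairwise_rank_statistics
    g = np.random.default_rng(101)
    k, n = 3, 10
    q_crit = sps.studentized_range.ppf(0.95, k, np.inf)
    reps = 10_000
    reject = 0
    for _ in range(reps):
        data = g.normal(size=(k, n))
        gs = sp.GroupedSamples(groups={str(i): data[i] for i in range(k)})
        tmax = max(abs(t) for _, _, t in pairwise_rank_statistics(gs))
        if tmax * np.sqrt(2.0) > q_crit:
            reject += 1
    return reject / reps
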