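"""Pairwise, bonded and neighbor-search force correctness."""

import numpy as np
import pytest

from vesidrop import _kernels
from vesidrop.configuration import Configuration
from vesidrop.engine import OverlappingBeadsError, pairwise_force
from vesidrop.forcefield import (BondedParams, C, ForceField, H, S, W,
                                 LIPID_BONDS, lipid_topology)


def _pair_cfg(r, species=(W, W), box=10.0):
    box = np.full(3, float(box))
    pos = np.array([box / 2 - [r / 2, 0, 0], box / 2 + [r / 2, 0, 0]])
    return Configuration(box=box, positions=pos,
                         velocities=np.zeros((2, 3)),
                         species=np.array(species, dtype=np.int8))


@pytest.mark.parametrize("r,species,expected", [
    (0.5, (W, W), 12.5),   # linear law at half range, f = 25
    (1.2, (W, W), 0.0),    # beyond the cutoff
    (0.9, (W, S), 7.0),    # 70 * (1 - 0.9)
    (0.5, (H, C), 25.0),   # 50 * 0.5
])
def test_conservative_pair_magnitudes(ff, r, species, expected):
    """Conservative force magnitude follows f_ij (1 - r/d)."""
    cfg = _pair_cfg(r, species)
    f = pairwise_force(cfg, ff, 0, 1, parts="c")
    assert np.linalg.norm(f) == pytest.approx(expected, abs=1e-12)
    if expected > 0:
        # repulsive: force on bead 0 points away from bead 1
        assert f[0] < 0


def test_coincident_beads_rejected(ff):
    cfg = _pair_cfg(0.5)
    cfg.positions[1] = cfg.positions[0]
    with pytest.raises(OverlappingBeadsError):
        pairwise_force(cfg, ff, 0, 1)


def test_force_cutoff_exact_on_random_configurations(ff):
    """Any pair separated by r >= d contributes exactly zero force."""
    rng = np.random.default_rng(7)
    box = np.array([6.0, 6.0, 6.0])
    for trial in range(5):
        pos = rng.uniform(0, 6, (40, 3))
        species = rng.integers(0, 4, 40).astype(np.int8)
        vel = rng.normal(0, 1, (40, 3))
        f = np.zeros((40, 3))
        _kernels.nonbonded_forces_bruteforce(
            pos, vel, species, ff.f, box, ff.gamma,
            ff.sigma / np.sqrt(ff.dt), 5, trial, f)
        # remove a bead with no neighbors inside the cutoff: its force must
        # be zero and the others unchanged
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        dist = np.linalg.norm(d, axis=2) + np.eye(40)
        lonely = np.flatnonzero((dist >= 1.0).all(axis=1))
        for i in lonely:
            assert np.all(f[i] == 0.0)


@pytest.mark.parametrize("n,boxes", [(50, (5.0, 5.0, 5.0)),
                                     (500, (6.0, 7.0, 8.0))])
def test_cell_list_matches_bruteforce(ff, n, boxes):
    """Cell-list forces equal the all-pairs O(N^2) oracle exactly."""
    rng = np.random.default_rng(n)
    box = np.array(boxes)
    pos = rng.uniform(0, 1, (n, 3)) * box
    vel = rng.normal(0, 1, (n, 3))
    species = rng.integers(0, 4, n).astype(np.int8)
    f1 = np.zeros((n, 3))
    f2 = np.zeros((n, 3))
    sigma_dt = ff.sigma / np.sqrt(ff.dt)
    v1, o1 = _kernels.nonbonded_forces(
        pos, vel, species, ff.f, box, ff.gamma, sigma_dt, 42, 3, f1)
    v2, o2 = _kernels.nonbonded_forces_bruteforce(
        pos, vel, species, ff.f, box, ff.gamma, sigma_dt, 42, 3, f2)
    assert not o1 and not o2
    np.testing.assert_allclose(f1, f2, atol=1e-10)
    assert v1 == pytest.approx(v2, rel=1e-12)


def test_random_force_pair_antisymmetric_and_seeded():
    """The hash RNG is symmetric in the pair and reproducible."""
    u1 = _kernels.pair_uniform(9, 100, 3, 17)
    u2 = _kernels.pair_uniform(9, 100, 17, 3)
    assert u1 == u2
    assert 0.0 <= u1 < 1.0
    assert _kernels.pair_uniform(9, 101, 3, 17) != u1
    assert _kernels.pair_uniform(8, 100, 3, 17) != u1


def test_bond_force_at_rest_and_stretched():
    bonded = BondedParams()
    box = np.full(3, 10.0)
    bonds = np.array([[0, 1]], np.int32)
    angles = np.empty((0, 3), np.int32)
    for stretch, expect in [(0.0, 0.0), (0.1, 0.1 * bonded.k_bond)]:
        pos = np.array([[5.0, 5.0, 5.0],
                        [5.0 + bonded.l0 + stretch, 5.0, 5.0]])
        f = np.zeros((2, 3))
        _kernels.bonded_forces(pos, box, bonds, angles, bonded.k_bond,
                               bonded.l0, bonded.k_angle, bonded.theta0, f)
        assert np.linalg.norm(f[0]) == pytest.approx(expect, abs=1e-12)
        np.testing.assert_allclose(f[0], -f[1], atol=1e-14)


def test_straight_trimer_has_zero_bending_force():
    bonded = BondedParams()
    box = np.full(3, 10.0)
    pos = np.array([[4.5, 5.0, 5.0], [5.0, 5.0, 5.0], [5.5, 5.0, 5.0]])
    f = np.zeros((3, 3))
    _kernels.bonded_forces(pos, box, np.empty((0, 2), np.int32),
                           np.array([[0, 1, 2]], np.int32), 0.0, 0.5,
                           bonded.k_angle, bonded.theta0, f)
    assert np.abs(f).max() < 1e-10


def test_bonded_forces_sum_to_zero_per_molecule():
    """Newton's third law: a lipid's internal forces cancel."""
    rng = np.random.default_rng(11)
    species, bonds, angles = lipid_topology(1)
    pos = np.full((15, 3), 5.0) + rng.normal(0, 0.3, (15, 3))
    f = np.zeros((15, 3))
    b = BondedParams()
    _kernels.bonded_forces(pos, np.full(3, 20.0), bonds, angles,
                           b.k_bond, b.l0, b.k_angle, b.theta0, f)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)


def test_bonded_energy_decreases_toward_rest_geometry():
    """Following the bonded force downhill lowers the bonded energy."""
    rng = np.random.default_rng(13)
    _, bonds, angles = lipid_topology(1)
    b = BondedParams()
    box = np.full(3, 20.0)
    pos = np.full((15, 3), 10.0) + rng.normal(0, 0.25, (15, 3))
    f = np.zeros((15, 3))
    e0, _ = _kernels.bonded_forces(pos, box, bonds, angles, b.k_bond, b.l0,
                                   b.k_angle, b.theta0, f)
    step = 1e-4 / max(np.linalg.norm(f, axis=1).max(), 1.0)
    f2 = np.zeros((15, 3))
    e1, _ = _kernels.bonded_forces(pos + step * f, box, bonds, angles,
                                   b.k_bond, b.l0, b.k_angle, b.theta0, f2)
    assert e1 < e0


def test_lipid_topology_is_connected_15_beads():
    """3 H + 2 x 6 C beads, one connected bonded graph per lipid."""
    import networkx as nx
    species, bonds, angles = lipid_topology(3)
    assert len(species) == 45
    assert np.sum(species == H) == 9 and np.sum(species == C) == 36
    g = nx.Graph()
    g.add_nodes_from(range(15))
    g.add_edges_from(LIPID_BONDS.tolist())
    assert nx.is_connected(g)
    # replicated copies reference their own bead ranges
    assert bonds[:14].max() < 15 <= bonds[14:28].min()
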