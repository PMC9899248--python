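"""Builders and exact bead bookkeeping."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from vesidrop.assembly import (AssemblyError, FULL_SCALE_N_LIPIDS,
                               SolutionSpec, VesicleSpec, build_droplet,
                               build_vesicle, droplet_initial_radius,
                               fill_and_bookkeep, full_scale_census,
                               leaflet_split, reduced_vesicle_spec)
from vesidrop.forcefield import ForceField, H, S, W


class TestFullScaleBookkeeping:
    """Census arithmetic of the full-scale system (no simulation)."""

    def test_total_bead_count(self):
        census = full_scale_census(n_solute=5400)
        assert census["lipid_beads"] == 10_100 * 15 == 151_500
        assert census["interior_W"] == 90_400
        assert census["exterior_W"] + census["S"] == 1_350_000
        assert census["total"] == 1_591_900

    @pytest.mark.parametrize("n_s,phi", [(5400, 0.004), (8100, 0.006),
                                         (12180, 0.009)])
    def test_solute_mole_fractions(self, n_s, phi):
        census = full_scale_census(n_solute=n_s)
        assert census["phi_S"] == pytest.approx(phi, abs=2.5e-5)

    def test_mole_fraction_is_exact_ratio(self):
        # N_S = 8100 in a 1,350,000-bead exterior solution: exactly 0.006
        spec = SolutionSpec(n_solute=8100, n_water_ex=1_350_000 - 8100)
        assert spec.phi_S == 8100 / 1_350_000 == 0.006

    def test_leaflet_reshuffling_conserves_total(self):
        spec = VesicleSpec(n_outer=5963, n_inner=FULL_SCALE_N_LIPIDS - 5963)
        assert spec.n_inner == 4137
        assert spec.n_lipids == 10_100

    def test_zero_solute_gives_zero_mole_fraction(self):
        assert full_scale_census(0)["phi_S"] == 0.0


class TestDroplet:

    def test_initial_radius_formula(self):
        # (N / 4 pi)^(1/3) at density 3/d^3
        assert droplet_initial_radius(5400) == pytest.approx(
            (5400 / (4 * np.pi)) ** (1 / 3), rel=1e-12)

    def test_single_bead_droplet_degenerates(self):
        cfg = build_droplet(1, seed=1)
        assert cfg.n_beads == 1
        assert droplet_initial_radius(1) > 0

    def test_zero_solute_rejected(self):
        with pytest.raises(AssemblyError):
            build_droplet(0)

    def test_droplet_does_not_fit_small_box(self):
        with pytest.raises(AssemblyError, match="clearance"):
            build_droplet(5400, box=np.full(3, 10.0))

    def test_exact_count_and_density(self):
        n = 900
        cfg = build_droplet(n, seed=4)
        assert cfg.n_beads == n
        assert np.all(cfg.species == S)
        r = droplet_initial_radius(n)
        center = cfg.box / 2
        # lattice sites are inside r; jitter can add up to ~0.3 d
        assert np.linalg.norm(cfg.positions - center, axis=1).max() <= r + 0.35


@pytest.fixture(scope="module")
def built():
    spec = reduced_vesicle_spec(800)
    cfg, meta = build_vesicle(spec, seed=7, relax_steps=150)
    return spec, cfg, meta


class TestVesicle:

    def test_bead_census(self, built):
        spec, cfg, meta = built
        assert cfg.n_beads == 15 * spec.n_lipids + meta["n_water_in"]
        counts = cfg.species_counts()
        assert counts["H"] == 3 * spec.n_lipids
        assert counts["C"] == 12 * spec.n_lipids
        assert counts["W"] == meta["n_water_in"]

    def test_no_overlaps_below_030(self, built):
        _, cfg, _ = built
        d, _ = cKDTree(cfg.positions, boxsize=cfg.box).query(
            cfg.positions, k=2)
        assert d[:, 1].min() >= 0.3

    def test_leaflet_orientation(self, built):
        """Inner heads face the lumen; outer heads face the exterior."""
        spec, cfg, meta = built
        center = meta["center"]
        r = np.linalg.norm(cfg.positions - center, axis=1)
        hmask = cfg.species == H
        lip = cfg.molecule
        outer_heads = hmask & (lip < spec.n_outer) & (lip >= 0)
        inner_heads = hmask & (lip >= spec.n_outer)
        chains = cfg.species == 1
        assert r[outer_heads].mean() > r[chains].mean() > r[inner_heads].mean()

    def test_overfilled_leaflet_rejected(self):
        with pytest.raises(AssemblyError, match="overfilled"):
            build_vesicle(VesicleSpec(n_outer=4000, n_inner=500,
                                      outer_diameter=16.0), relax_steps=0)

    def test_reduced_spec_scales(self):
        """Reduced vesicles keep the full-scale per-lipid areas."""
        for n in (600, 1000, 2000):
            spec = reduced_vesicle_spec(n)
            assert spec.n_lipids == pytest.approx(n, abs=2)
            r_out = spec.outer_diameter / 2
            apl = 4 * np.pi * r_out ** 2 / spec.n_outer
            assert 0.9 < apl < 1.4

    def test_full_scale_split_near_symmetric_reference(self):
        n_out, n_in = leaflet_split(10_100, 46.6)
        assert n_out == pytest.approx(5963, abs=60)
        assert n_out + n_in == 10_100


class TestFill:

    def test_census_conservation_and_density(self):
        drop = build_droplet(400, seed=9, box=np.full(3, 12.0))
        cfg, sol, census = fill_and_bookkeep(drop, seed=9)
        assert census["total"] == 15 * 0 + census["interior_W"] \
            + census["exterior_W"] + census["S"]
        assert census["S"] == 400
        assert abs(cfg.density - 3.0) / 3.0 < 0.01
        assert sol.phi_S == 400 / (400 + census["exterior_W"])
        assert sol.zeta(ForceField()) == pytest.approx(0.357, abs=5e-4)

    def test_box_too_small_rejected(self):
        drop = build_droplet(900, seed=2, box=np.full(3, 12.0))
        # droplet alone already exceeds the requested global density
        with pytest.raises(AssemblyError):
            fill_and_bookkeep(drop, rho=0.3, seed=2)
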