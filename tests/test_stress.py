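"""Stress-profile calculus: oracles, partitions, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesidrop import _kernels
from vesidrop.assembly import _jittered_lattice
from vesidrop.configuration import Configuration
from vesidrop.engine import DPDSimulation
from vesidrop.fixtures import (make_injected_radial_profile,
                               make_thermo_fixture)
from vesidrop.forcefield import ForceField, W
from vesidrop.stress import (AxisymStressMap, IntegrationBox,
                             PlanarStressProfile, RadialStressProfile,
                             StressError, axisym_stress_map,
                             planar_stress_profile, radial_stress_profile,
                             segment_and_interface_tensions,
                             tensions_from_profile)


class TestRadial:

    def test_ideal_gas_stress_vanishes_identically(self):
        """No forces, no velocities: s(r) = 0 in every shell."""
        fx = make_thermo_fixture("ideal_gas", n=1200, box=(10, 10, 10),
                                 seed=1)
        fx.config.velocities[:] = 0.0
        prof = radial_stress_profile(fx.config, ff=fx.truth["forcefield"],
                                     center=fx.config.box / 2)
        assert np.all(prof.s == 0.0)
        assert np.all(prof.P_N == 0.0)

    def test_thermal_ideal_gas_tension_near_zero(self):
        """With thermal velocities the integrated tension stays at noise.

        Shells with r > 2 d hold enough beads for the kinetic noise floor
        to be meaningful; the innermost shells are dominated by single-
        bead statistics and are excluded from the integral.
        """
        frames = [make_thermo_fixture("ideal_gas", n=2000, box=(10, 10, 10),
                                      seed=s).config for s in range(20)]
        ffz = ForceField(f=np.zeros((4, 4)))
        prof = radial_stress_profile(frames, ff=ffz, center=frames[0].box / 2)
        sigma = float(prof.s[prof.r > 2.0].sum() * prof.bin_width)
        assert abs(sigma) < 0.35

    def test_tangential_frozen_pair_oracle(self):
        """A tangential pair's virial lands in P_T of its shell; P_N ~ 0."""
        center = np.full(3, 8.0)
        R, half = 5.0, 0.25
        pos = np.array([center + [R, half, 0], center + [R, -half, 0]])
        cfg = Configuration(box=np.full(3, 16.0), positions=pos,
                            velocities=np.zeros((2, 3)),
                            species=np.full(2, W, np.int8))
        prof = radial_stress_profile(cfg, ff=ForceField(), center=center,
                                     bin_width=0.5, include_kinetic=False)
        nb = len(prof.r)
        vol = 4 / 3 * np.pi * (((np.arange(nb) + 1) * 0.5) ** 3
                               - (np.arange(nb) * 0.5) ** 3)
        # hand value: pair virial 25*(1-0.5)*0.5 = 6.25, split as T = vir/2
        assert (prof.P_T * vol).sum() == pytest.approx(3.125, rel=0.01)
        assert abs((prof.P_N * vol).sum()) < 0.05

    def test_center_drift_detected(self):
        fx = make_thermo_fixture("ideal_gas", n=500, box=(10, 10, 10), seed=2)
        cfg = fx.config
        # pretend these beads are a "membrane" far from the claimed center
        cfg.molecule[:] = 0
        with pytest.raises(StressError, match="drift"):
            radial_stress_profile(cfg, ff=fx.truth["forcefield"],
                                  center=cfg.box / 2 + 5.0)


class TestTensionPartition:

    def test_injected_two_lobe_profile(self):
        """Two unit-area lobes split by R_mid give Sigma_il = Sigma_ol = 1."""
        fx = make_injected_radial_profile(
            [(8.0, 10.0, 0.5), (10.0, 12.0, 0.5)], r_mid=10.0)
        rep = tensions_from_profile(fx.points["profile"])
        assert rep.Sigma_il == pytest.approx(fx.truth["Sigma_il"], abs=1e-12)
        assert rep.Sigma_ol == pytest.approx(fx.truth["Sigma_ol"], abs=1e-12)
        assert rep.Sigma == pytest.approx(fx.truth["Sigma"], abs=1e-12)

    def test_zero_profile_gives_zero_tensions(self):
        fx = make_injected_radial_profile([], r_mid=6.0)
        rep = tensions_from_profile(fx.points["profile"])
        assert rep.Sigma == rep.Sigma_ol == rep.Sigma_il == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_partition_is_exact_for_random_profiles(self, seed):
        """Sigma_il + Sigma_ol - Sigma == 0 to machine precision, always."""
        rng = np.random.default_rng(seed)
        nbins = rng.integers(20, 120)
        prof = RadialStressProfile(
            r=(np.arange(nbins) + 0.5) * 0.2,
            P_N=rng.normal(0, 5, nbins), P_T=rng.normal(0, 5, nbins),
            rho_C=rng.uniform(0, 1, nbins), bin_width=0.2,
            center=np.zeros(3))
        rep = tensions_from_profile(prof)
        assert rep.Sigma_il + rep.Sigma_ol - rep.Sigma == 0.0

    def test_no_chain_peak_is_an_error(self):
        prof = RadialStressProfile(
            r=np.arange(10) + 0.5, P_N=np.ones(10), P_T=np.zeros(10),
            rho_C=np.zeros(10), bin_width=1.0, center=np.zeros(3))
        with pytest.raises(StressError, match="peak"):
            tensions_from_profile(prof)

    def test_r_mid_at_chain_density_peak(self):
        fx = make_injected_radial_profile([(2.0, 4.0, 1.0)], r_mid=7.0)
        prof = fx.points["profile"]
        assert abs(prof.r_mid() - 7.0) <= prof.bin_width


class TestPlanar:

    def test_homogeneous_thermal_box_tension_near_zero(self):
        rng = np.random.default_rng(31)
        box = np.array([8.0, 8.0, 8.0])
        n = 1536
        frames = []
        cfg = Configuration(
            box=box, positions=_jittered_lattice(n, rng, np.zeros(3), box),
            velocities=rng.normal(0, 1, (n, 3)),
            species=np.full(n, W, np.int8))
        sim = DPDSimulation(cfg, ForceField(), seed=31)
        sim.run(300)
        sim.run(300, frame_every=50,
                frame_callback=lambda c, s: frames.append(c.copy()))
        prof = planar_stress_profile(frames, ff=ForceField(), axis=2)
        assert abs(prof.tension_per_interface()) < 0.25

    def test_injected_rectangle_integrates_to_height_times_width(self):
        nb = 100
        s = np.zeros(nb)
        s[40:60] = 1.5  # height 1.5 over 20 bins of width 0.2 -> 6.0
        prof = PlanarStressProfile(
            z=(np.arange(nb) + 0.5) * 0.2, P_N=s, P_T=np.zeros(nb),
            bin_width=0.2, axis=2, n_interfaces=1)
        assert prof.tension_per_interface() == pytest.approx(6.0, abs=1e-12)

    def test_binned_virial_matches_direct_total(self):
        """Sum over slabs of (P_N + 2 P_T) V equals the all-pairs virial."""
        rng = np.random.default_rng(17)
        box = np.array([8.0, 8.0, 8.0])
        n = 1500
        pos = _jittered_lattice(n, rng, np.zeros(3), box)
        vel = rng.normal(0, 1, (n, 3))
        cfg = Configuration(box=box, positions=pos, velocities=vel,
                            species=np.full(n, W, np.int8))
        ff = ForceField()
        prof = planar_stress_profile(cfg, ff=ff, axis=2)
        f = np.zeros((n, 3))
        vir, _ = _kernels.nonbonded_forces(pos, vel, cfg.species, ff.f, box,
                                           0.0, 0.0, 0, 0, f)
        direct = vir + (vel ** 2).sum()
        slab_vol = box[0] * box[1] * prof.bin_width
        binned = ((prof.P_N + 2 * prof.P_T) * slab_vol).sum()
        assert binned == pytest.approx(direct, rel=1e-9)

    def test_wrapped_slab_rejected(self):
        from vesidrop.forcefield import S as S_CODE
        rng = np.random.default_rng(5)
        box = np.array([6.0, 6.0, 12.0])
        n = 600
        pos = _jittered_lattice(n, rng, np.zeros(3), box)
        # put the "slab" across the periodic boundary
        species = np.where((pos[:, 2] < 2.0) | (pos[:, 2] > 10.0),
                           S_CODE, W).astype(np.int8)
        cfg = Configuration(box=box, positions=pos,
                            velocities=np.zeros((n, 3)), species=species)
        with pytest.raises(StressError, match="periodic"):
            planar_stress_profile(cfg, ff=ForceField(), axis=2)


class TestAxisym:

    def test_ideal_gas_map_vanishes(self):
        fx = make_thermo_fixture("ideal_gas", n=800, box=(12, 12, 12), seed=4)
        fx.config.velocities[:] = 0.0
        amap = axisym_stress_map(fx.config, ff=fx.truth["forcefield"])
        assert np.all(amap.s == 0.0)

    def test_frozen_axial_pair_oracle(self):
        """P_yy integrated over cells equals the one-pair virial f dy."""
        box = np.full(3, 16.0)
        pos = np.array([[8.6, 8.25, 8.0], [8.6, 7.75, 8.0]])
        cfg = Configuration(box=box, positions=pos,
                            velocities=np.zeros((2, 3)),
                            species=np.full(2, W, np.int8))
        amap = axisym_stress_map(cfg, ff=ForceField(), include_kinetic=False)
        rr = np.arange(len(amap.r))
        vol = np.pi * (((rr + 1) * amap.cell) ** 2
                       - (rr * amap.cell) ** 2) * amap.cell
        assert (amap.P_yy * vol[:, None]).sum() == pytest.approx(6.25,
                                                                 rel=1e-6)

    def test_nonaxisymmetric_state_refused(self):
        fx = make_thermo_fixture("ideal_gas", n=100, box=(12, 12, 12), seed=6)
        with pytest.raises(StressError, match="axisymmetric"):
            axisym_stress_map(fx.config, ff=fx.truth["forcefield"],
                              circularity=0.5)

    @pytest.fixture()
    def ribbon_map(self):
        nr, ny = 8, 16
        r = (np.arange(nr) + 0.5)
        y = (np.arange(ny) - ny / 2 + 0.5)
        s = np.zeros((nr, ny))
        ir = (r >= 2) & (r < 5)
        iy = (y >= -2) & (y < 1)
        s[np.ix_(ir, iy)] = 0.7  # height 0.7, thickness 3 along y
        return AxisymStressMap(r=r, y=y, P_yy=s, P_trans=np.zeros_like(s),
                               counts=np.ones_like(s), cell=1.0,
                               axis_point=(0, 0), y0=0.0)

    def test_ribbon_tension_is_height_times_thickness(self, ribbon_map):
        st_ = segment_and_interface_tensions(
            ribbon_map, {"ab": IntegrationBox(2, 5, -4, 4, "y")})
        assert st_.Sigma_ab == pytest.approx(0.7 * 3.0, abs=1e-12)

    def test_overlapping_boxes_rejected(self, ribbon_map):
        with pytest.raises(StressError, match="overlap"):
            segment_and_interface_tensions(
                ribbon_map, {"ab": IntegrationBox(2, 5, -4, 4, "y"),
                             "ag": IntegrationBox(4, 6, -4, 4, "y")})

    def test_missing_segment_rejected(self, ribbon_map):
        ribbon_map.counts[:] = 0.0
        with pytest.raises(StressError, match="missing"):
            segment_and_interface_tensions(
                ribbon_map, {"bg": IntegrationBox(2, 5, -4, 4, "y")})
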