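"""Deflation bookkeeping, tensionless-volume search, engulfment control."""

import numpy as np
import pytest

from vesidrop.assembly import (build_droplet, build_vesicle,
                               fill_and_bookkeep, reduced_vesicle_spec)
from vesidrop.fixtures import make_thermo_fixture
from vesidrop.forcefield import ForceField
from vesidrop.geometry import GeometryError
from vesidrop.protocols import (ProtocolError, ProtocolSchedule,
                                VolumeState, deflate_to,
                                find_tensionless_volume, place_droplet_near,
                                run_engulfment)


@pytest.fixture(scope="module")
def filled_vesicle():
    spec = reduced_vesicle_spec(800)
    cfg, meta = build_vesicle(spec, seed=21, relax_steps=150)
    filled, sol, census = fill_and_bookkeep(
        cfg, seed=21,
        exclude_spheres=[(meta["center"], meta["r_head_out"] + 0.5)],
        n_water_in=meta["n_water_in"])
    return filled, meta, census


class TestVolumeState:

    def test_nu_is_an_exact_integer_ratio(self):
        state = VolumeState(n_water_in=54_240, n_water_isp=90_400)
        assert state.nu == 54_240 / 90_400 == 0.6

    @pytest.mark.parametrize("n_in", [0, 90_401])
    def test_invalid_volume_rejected(self, n_in):
        with pytest.raises(ProtocolError):
            VolumeState(n_water_in=n_in, n_water_isp=90_400)

    def test_full_scale_removal_counts(self):
        """Deflation step counts at full scale are exact bead numbers."""
        isp = 90_400
        assert round((1.0 - 0.9) * isp) == 9_040
        assert round(0.6 * isp) == 54_240  # interior waters left at nu=0.6


class TestDeflation:

    def test_counts_conserved_and_target_reached(self, filled_vesicle):
        cfg, meta, _ = filled_vesicle
        cfg = cfg.copy()
        n_in = meta["n_water_in"]
        state = VolumeState(n_water_in=n_in, n_water_isp=n_in)
        before = cfg.species_counts()
        n_before = cfg.n_beads
        new_state = deflate_to(cfg, 0.8, state, seed=1)
        assert cfg.species_counts() == before
        assert cfg.n_beads == n_before
        assert abs(new_state.nu - 0.8) <= 1.0 / n_in

    def test_noop_at_current_volume(self, filled_vesicle):
        cfg, meta, _ = filled_vesicle
        cfg = cfg.copy()
        n_in = meta["n_water_in"]
        state = VolumeState(n_water_in=n_in, n_water_isp=n_in)
        pos_before = cfg.positions.copy()
        same = deflate_to(cfg, state.nu, state, seed=2)
        assert same.n_water_in == n_in
        np.testing.assert_array_equal(cfg.positions, pos_before)

    def test_inflation_rejected(self, filled_vesicle):
        cfg, meta, _ = filled_vesicle
        n_in = meta["n_water_in"]
        state = VolumeState(n_water_in=n_in - 50, n_water_isp=n_in)
        with pytest.raises(ProtocolError):
            deflate_to(cfg.copy(), 1.0, state, seed=3)

    def test_porous_membrane_aborts(self):
        """A leaky (singly connected) water phase refuses deflation."""
        fx = make_thermo_fixture("ideal_gas", n=2000, box=(10, 10, 10),
                                 seed=5)
        cfg = fx.config
        cfg.molecule[:25] = 0  # token membrane fragment, no closed shell
        state = VolumeState(n_water_in=500, n_water_isp=500)
        with pytest.raises(GeometryError):
            deflate_to(cfg, 0.8, state, seed=5)


class TestTensionlessSearch:

    def test_synthetic_table_zero_crossing(self):
        """Interpolated crossing of an injected Sigma(nu) table."""
        table = [(0.90, -0.60), (0.94, -0.22), (0.96, 0.09), (1.00, 0.70)]
        res = find_tensionless_volume(table)
        assert res.crossed_zero
        assert res.nu0 == pytest.approx(0.9542, abs=0.01)

    def test_bisection_on_callable(self):
        res = find_tensionless_volume(lambda nu: 12.0 * (nu - 0.95),
                                      nu_range=(0.8, 1.0), tolerance=0.01)
        assert res.crossed_zero
        assert res.nu0 == pytest.approx(0.95, abs=0.005)
        assert len(res.table) >= 3

    def test_monotone_positive_flags_no_crossing(self):
        res = find_tensionless_volume([(0.9, 0.5), (0.95, 0.3), (1.0, 0.2)])
        assert not res.crossed_zero
        assert res.nu0 == 1.0  # argmin |Sigma|


class TestEngulfmentRun:

    def test_zero_adhesion_control_never_wets(self):
        """With membrane-solute repulsion the droplet stays free."""
        spec = reduced_vesicle_spec(600)
        cfg, meta = build_vesicle(spec, seed=31, relax_steps=120,
                                  box=np.full(3, 24.0))
        droplet = build_droplet(250, seed=31, box=cfg.box)
        couple, drop_c, r_drop = place_droplet_near(cfg, meta, droplet,
                                                    gap=2.5)
        couple, _, _ = fill_and_bookkeep(
            couple, seed=31,
            exclude_spheres=[(meta["center"], meta["r_head_out"] + 0.5),
                             (drop_c, r_drop + 0.4)],
            n_water_in=meta["n_water_in"])
        ff = ForceField()
        for i in (0, 1):  # H, C strongly repel S
            ff.f[i, 3] = ff.f[3, i] = 200.0
        schedule = ProtocolSchedule(steps_per_stage=400, max_stages=1,
                                    seed=31)
        state = VolumeState(n_water_in=meta["n_water_in"],
                            n_water_isp=meta["n_water_in"])
        run = run_engulfment(couple, state, schedule, ff=ff)
        # the droplet may diffuse and brush the membrane, but it never
        # wets it: the head-droplet contact area stays at grazing level
        # (a wetting droplet of this size spreads over tens of d^2)
        assert run.reports[-1].state in ("free", "partial-open-neck")
        assert run.reports[-1].area_contact <= 5.0
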