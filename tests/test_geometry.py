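"""Morphology: droplet shape, contact lines, angles, classification."""

import numpy as np
import pytest

from vesidrop.assembly import RHO, _jittered_lattice
from vesidrop.configuration import Configuration
from vesidrop.fixtures import (make_engulfment_state, make_loop,
                               make_mock_couple, make_nested_shells)
from vesidrop.forcefield import S, W
from vesidrop.geometry import (AXISYM_CIRCULARITY, GeometryError,
                               classify_state, extract_contact_line,
                               interior_exterior_water, loop_descriptors,
                               measure_contact_angles, measure_droplet_shape,
                               order_loop)


def _uniform_sphere_cfg(radius, box_edge=24.0, seed=0):
    rng = np.random.default_rng(seed)
    box = np.full(3, box_edge)
    center = box / 2

    def inside(p):
        return np.linalg.norm(p - center, axis=1) < radius

    n = int(round(RHO * 4 / 3 * np.pi * radius ** 3))
    pts = _jittered_lattice(n, rng, center - radius, center + radius,
                            inside=inside)
    return Configuration(box=box, positions=pts,
                         velocities=np.zeros((n, 3)),
                         species=np.full(n, S, np.int8))


class TestDropletShape:

    def test_uniform_sphere_diameter_and_asphericity(self):
        """A constructed radius-7 S sphere measures D = 14 d, asphericity 0."""
        cfg = _uniform_sphere_cfg(7.0)
        shape = measure_droplet_shape(cfg)
        assert shape.diameter == pytest.approx(14.0, rel=0.05)
        assert shape.asphericity < 0.002

    def test_no_solute_cluster_is_an_error(self):
        cfg = _uniform_sphere_cfg(3.0)
        cfg.species[:] = W
        with pytest.raises(GeometryError):
            measure_droplet_shape(cfg)


class TestContactLineLoops:

    def test_circle_circularity_and_radius(self):
        fx = make_loop("circle", radius=10.0)
        pts = fx.points["loop"]
        length, circ, centroid, _ = loop_descriptors(pts[order_loop(pts)])
        assert circ == pytest.approx(1.0, abs=5e-3)
        assert length == pytest.approx(fx.truth["perimeter"], rel=5e-3)
        assert np.linalg.norm(pts - centroid, axis=1).mean() == \
            pytest.approx(10.0, rel=1e-3)

    def test_ellipse_matches_elliptic_integral_oracle(self):
        """2:1 ellipse: circularity from the E(e) perimeter, ~ 0.84."""
        fx = make_loop("ellipse", a=10.0, b=5.0)
        pts = fx.points["loop"]
        length, circ, _, _ = loop_descriptors(pts[order_loop(pts)])
        assert length == pytest.approx(fx.truth["perimeter"], rel=5e-3)
        assert circ == pytest.approx(fx.truth["circularity"], abs=5e-3)
        assert circ < AXISYM_CIRCULARITY  # flagged nonaxisymmetric

    def test_tight_lipped_loop_far_below_threshold(self):
        """Stadium (two straight segments + caps): circularity << 0.95."""
        fx = make_loop("stadium", L=16.0, r=2.0)
        pts = fx.points["loop"]
        _, circ, _, _ = loop_descriptors(pts[order_loop(pts)])
        assert circ == pytest.approx(fx.truth["circularity"], abs=0.02)
        assert circ < 0.6

    @pytest.mark.parametrize("angle", [0.4, 1.7, 2.9])
    def test_circularity_invariant_under_rotation_and_scaling(self, angle):
        fx = make_loop("ellipse", a=8.0, b=5.0, seed=2)
        pts = fx.points["loop"]
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]) @ \
            np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        ref = loop_descriptors(pts[order_loop(pts)])[1]
        moved = 3.7 * pts @ rot.T + np.array([5.0, -2.0, 9.0])
        got = loop_descriptors(moved[order_loop(moved)])[1]
        assert got == pytest.approx(ref, abs=1e-9)

    def test_extract_contact_line_from_bead_sets(self):
        """Head beads flanked by alpha and beta phases form the loop."""
        t = np.linspace(0, 2 * np.pi, 160, endpoint=False)
        ring = np.column_stack([10 * np.cos(t), 10 * np.sin(t),
                                np.zeros(160)])
        alpha = ring * 0.97 + [0, 0, -0.4]
        beta = ring * 1.03 + [0, 0, 0.4]
        geo = extract_contact_line(ring, alpha, beta)
        assert geo.axisymmetric
        assert geo.R_co == pytest.approx(10.0, abs=0.1)
        assert geo.L_cl == pytest.approx(2 * np.pi * 10, rel=0.02)

    def test_closed_neck_indicator_when_no_beta_contact(self):
        ring = np.column_stack([np.linspace(0, 1, 20), np.zeros(20),
                                np.zeros(20)])
        alpha = ring + [0, 0.3, 0]
        beta = ring + [0, 30.0, 0]  # far: no head touches both phases
        geo = extract_contact_line(ring, alpha, beta)
        assert geo.closed_neck


class TestContactAngles:

    GRID_THETA = (30, 60, 90, 120, 150)
    GRID_PSI = (0, 20, 40, 60, 80)

    def test_recovery_within_two_degrees_across_grid(self):
        """Mock couples over the angle grid recover within 2 deg / 0.2 d."""
        worst = 0.0
        tested = 0
        for th in self.GRID_THETA:
            for ps in self.GRID_PSI:
                if th - ps <= 2.0:  # geometrically inconsistent corner
                    with pytest.raises(GeometryError):
                        make_mock_couple(th, ps, R_co=8.0, noise=0.1, seed=3)
                    continue
                fx = make_mock_couple(th, ps, R_co=8.0, noise=0.1, seed=3)
                geo = measure_contact_angles(fx.points)
                err = max(abs(geo.theta_alpha_star - th),
                          abs(geo.psi_co - ps))
                worst = max(worst, err)
                assert err <= 2.0, (th, ps, err)
                assert geo.R_co == pytest.approx(8.0, abs=0.2)
                tested += 1
        assert tested >= 15
        assert worst <= 2.0

    def test_noise_free_recovery_is_nearly_exact(self):
        fx = make_mock_couple(90.0, 45.0, R_co=8.0, noise=0.0, seed=1)
        geo = measure_contact_angles(fx.points)
        assert geo.theta_alpha_star == pytest.approx(90.0, abs=0.5)
        assert geo.psi_co == pytest.approx(45.0, abs=0.5)
        assert geo.R_co == pytest.approx(8.0, abs=0.05)

    def test_flat_membrane_hemispherical_droplet_is_90_degrees(self):
        """psi = 0 and a hemispherical cap: theta* = 90 by symmetry."""
        fx = make_mock_couple(90.0, 0.0, R_co=8.0, noise=0.05, seed=5)
        geo = measure_contact_angles(fx.points)
        assert geo.theta_alpha_star == pytest.approx(90.0, abs=1.5)
        assert geo.psi_co == pytest.approx(0.0, abs=1.5)

    def test_underpopulated_window_is_an_error(self):
        fx = make_mock_couple(90.0, 40.0, R_co=8.0, noise=0.1, seed=2,
                              density=0.05)
        with pytest.raises(GeometryError):
            measure_contact_angles(fx.points)

    def test_missing_surface_is_an_error(self):
        fx = make_mock_couple(90.0, 40.0, R_co=8.0, seed=2)
        with pytest.raises(GeometryError, match="missing"):
            measure_contact_angles({"ab": fx.points["ab"]})


class TestClassification:

    def test_nested_shells_classified_as_fission(self):
        fx = make_nested_shells(seed=4)
        rep = classify_state(fx.config)
        assert rep.state == fx.truth["state"] == "fission"
        assert rep.n_membrane_components == 2

    def test_distant_droplet_is_free(self):
        fx = make_engulfment_state("free", seed=5)
        rep = classify_state(fx.config)
        assert rep.state == "free"
        assert rep.area_contact == 0.0

    def test_wrapped_droplet_is_complete_closed_neck(self):
        """Zero solute-exterior contacts define the closed neck."""
        fx = make_engulfment_state("complete", seed=6)
        rep = classify_state(fx.config)
        assert rep.state == "complete-closed-neck"
        assert rep.area_interface == 0.0
        assert rep.area_contact > 0.0

    def test_pore_detected_as_connected_water(self):
        """Without a closed membrane the water phase is one component."""
        rng = np.random.default_rng(9)
        box = np.full(3, 10.0)
        n = 2000
        pos = _jittered_lattice(n, rng, np.zeros(3), box)
        species = np.full(n, W, np.int8)
        mol = np.full(n, -1, np.int32)
        mol[:30] = 0  # a token "membrane" that cannot separate anything
        cfg = Configuration(box=box, positions=pos,
                            velocities=np.zeros((n, 3)), species=species,
                            molecule=mol)
        with pytest.raises(GeometryError, match="pore"):
            interior_exterior_water(cfg)
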