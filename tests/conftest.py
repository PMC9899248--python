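"""Shared fixtures.

The expensive DPD runs (pure-water box, phase-separated slab, equilibrated
droplet) are session-scoped and shared between the unit tests and the
acceptance checks, so each simulation runs once per session.
"""

import numpy as np
import pytest

from vesidrop.assembly import _jittered_lattice, build_droplet, \
    droplet_initial_radius, fill_and_bookkeep
from vesidrop.configuration import Configuration
from vesidrop.engine import DPDSimulation, measure_thermo
from vesidrop.forcefield import ForceField, W
from vesidrop.fixtures import make_planar_slab
from vesidrop.geometry import measure_droplet_shape
from vesidrop.stress import planar_stress_profile


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def water_box_result():
    """Pure-W box at bulk density: thermostat temperature and pressure.

    3,000 beads in a (10 d)^3 box, 2,000 equilibration steps, 8,000
    sampled production steps.
    """
    rng = np.random.default_rng(101)
    box = np.array([10.0, 10.0, 10.0])
    n = 3000
    pos = _jittered_lattice(n, rng, np.zeros(3), box)
    vel = rng.normal(0.0, 1.0, (n, 3))
    vel -= vel.mean(axis=0)
    cfg = Configuration(box=box, positions=pos, velocities=vel,
                        species=np.full(n, W, dtype=np.int8))
    sim = DPDSimulation(cfg, ForceField(), seed=101)
    sim.run(2000)
    sim.series = type(sim.series)()
    sim.run(8000, sample_every=10)
    thermo = measure_thermo(sim)
    return {"thermo": thermo, "sim": sim}


@pytest.fixture(scope="session")
def slab_result():
    """Planar W/S slab: per-interface tension at solubility 0.357.

    10 d slab in a 16 x 16 x 32 d^3 box (24,576 beads), 3,000
    equilibration steps, 3,600 production steps with frames every 24.
    """
    fx = make_planar_slab(thickness=10.0, box=(16.0, 16.0, 32.0), seed=202)
    field = ForceField()
    sim = DPDSimulation(fx.config, field, seed=202)
    sim.run(3000)
    frames = []
    sim.run(3600, frame_every=24,
            frame_callback=lambda c, s: frames.append(c.copy()))
    prof = planar_stress_profile(frames, ff=field, axis=fx.truth["axis"])
    return {"fixture": fx, "profile": prof,
            "tension": prof.tension_per_interface(),
            "sem": prof.tension_sem()}


@pytest.fixture(scope="session")
def droplet_result():
    """Equilibrated 5,400-S-bead droplet in a (30 d)^3 water box.

    2,500 equilibration steps, then the diameter (half-maximum of the
    radial S density) averaged over 8 frames spanning 1,600 steps.
    """
    field = ForceField()
    drop = build_droplet(5400, seed=303, box=np.full(3, 30.0))
    r0 = droplet_initial_radius(5400)
    cfg, _, census = fill_and_bookkeep(
        drop, seed=303, exclude_spheres=[(drop.box / 2, r0 + 0.4)])
    rng = np.random.default_rng(303)
    cfg.velocities[:] = rng.normal(0.0, 1.0, (cfg.n_beads, 3))
    cfg.velocities -= cfg.velocities.mean(axis=0)
    sim = DPDSimulation(cfg, field, seed=303)
    sim.run(2500)
    diameters = []
    shapes = []

    def grab(c, s):
        shape = measure_droplet_shape(c)
        diameters.append(shape.diameter)
        shapes.append(shape)

    sim.run(1600, frame_every=200, frame_callback=grab)
    return {"census": census, "diameters": diameters,
            "diameter": float(np.mean(diameters)), "shapes": shapes}
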